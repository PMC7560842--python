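"""Readers and writers for traces, peak lists, configs and reports.

Traces are two-column CSV (time_s, current_pA) with an optional true_state
column for synthetic data; peak lists are Sparky-style whitespace-delimited
text with columns ``Assignment w1 w2 Height`` where w1 is the 13C shift and
w2 the 1H shift.  All writers emit a format-version comment header.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .gating import CurrentTrace
from .peaks import Peak, PeakList, StateFingerprint

__all__ = [
    "read_trace",
    "write_trace",
    "read_peaklist",
    "write_peaklist",
    "read_fingerprint",
    "write_report",
]

TRACE_VERSIONS = ("kcsalink-trace v1",)
PEAKLIST_VERSIONS = ("kcsalink-peaklist v1",)
#: relative jitter tolerance on the sample clock
TIME_JITTER_S = 1e-6


def write_trace(trace: CurrentTrace, path: str) -> None:
    path = pathlib.Path(path)
    t = trace.times()
    cols = {"time_s": t, "current_pA": trace.samples}
    if trace.true_state_path is not None:
        cols["true_state"] = trace.true_state_path
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# {TRACE_VERSIONS[-1]}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trace(path: str) -> CurrentTrace:
    """Read a trace CSV; the sampling rate is inferred from the time grid.

    The grid must be uniform and increasing: the median time step defines the
    rate, and any step deviating from it by more than 1 microsecond is
    rejected as a non-uniform clock.
    """
    path = pathlib.Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            version = first.lstrip("# ").strip()
            if version not in TRACE_VERSIONS:
                raise ValueError(f"unsupported trace format version: {version!r}")
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if "time_s" not in df or "current_pA" not in df:
        raise ValueError("trace CSV needs columns time_s, current_pA")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError("time grid must be strictly increasing")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > TIME_JITTER_S):
        raise ValueError("non-uniform time grid (jitter exceeds 1 us)")
    fs = 1.0 / step
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    state = None
    if "true_state" in df:
        state = df["true_state"].to_numpy(dtype=int)
    return CurrentTrace(
        sampling_rate=fs,
        samples=df["current_pA"].to_numpy(dtype=float),
        true_state_path=state,
    )


def write_peaklist(plist: PeakList, path: str) -> None:
    """Sparky-dialect writer: fixed-width columns, canonical formatting, so a
    second write of a read-back list is byte-identical."""
    lines = [f"# {PEAKLIST_VERSIONS[-1]}", f"{'Assignment':>17s} {'w1':>8s} {'w2':>8s} {'Height':>12s}"]
    for p in plist:
        label = p.label if p.label else "?"
        lines.append(f"{label:>17s} {p.shift_c:8.3f} {p.shift_h:8.3f} {p.height:12.3f}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_peaklist(path: str) -> PeakList:
    """Read a Sparky-style list: ``Assignment w1(13C) w2(1H) Height``.

    Comment (#) and blank lines are skipped; a malformed data line is
    reported with its line number.
    """
    peaks = []
    text = pathlib.Path(path).read_text().splitlines()
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0].lower() == "assignment":
            continue
        if len(fields) < 4:
            raise ValueError(
                f"{path}:{lineno}: expected 'Assignment w1 w2 Height', got {raw!r}"
            )
        try:
            w1, w2, height = (float(x) for x in fields[1:4])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric field in {raw!r}") from None
        peaks.append(Peak(shift_h=w2, shift_c=w1, height=height, label=fields[0]))
    return PeakList(peaks)


def read_fingerprint(path: str) -> StateFingerprint:
    """YAML fingerprint: ``positions: {state: {reporter: [h_ppm, c_ppm]}}``
    plus optional ``tolerance_h`` / ``tolerance_c``."""
    data = yaml.safe_load(pathlib.Path(path).read_text())
    positions = {
        state: {rep: tuple(float(v) for v in pos) for rep, pos in reps.items()}
        for state, reps in data["positions"].items()
    }
    kwargs = {}
    for key in ("tolerance_h", "tolerance_c"):
        if key in data:
            kwargs[key] = float(data[key])
    return StateFingerprint(positions=positions, **kwargs)


def write_report(report: dict, path: str) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    payload = {"format": "kcsalink-report v1", **report}
    pathlib.Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
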