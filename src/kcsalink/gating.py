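"""Single-channel trace analysis.

All-points histogram with two-Gaussian deconvolution into conductive and
nonconductive fractions, half-amplitude-threshold idealization into a dwell
sequence, burst segmentation by a critical gap time, and dwell-time
statistics including a two-state exchange-rate estimate ``kex = 1/tau_open +
1/tau_closed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CurrentTrace",
    "DwellSequence",
    "BurstPartition",
    "HistogramFit",
    "all_points_histogram",
    "fit_two_gaussians",
    "idealize_trace",
    "segment_bursts",
    "dwell_statistics",
    "exchange_rate_from_dwells",
    "analyze_trace",
]

CONDUCTIVE = "conductive"
NONCONDUCTIVE = "nonconductive"


@dataclass
class CurrentTrace:
    """A sampled single-channel current record.

    samples are in pA; ``true_state_path`` carries per-sample state labels for
    synthetic traces and is None for measured data.  ``conditions`` holds
    free-form recording metadata (voltage_mv, kcl_mm, pH pair, ...).
    """

    sampling_rate: float
    samples: np.ndarray
    true_state_path: np.ndarray | None = None
    seed: int | None = None
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.samples.size == 0 or not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be non-empty and finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class DwellSequence:
    """Alternating (label, duration) idealization of a trace.

    ``start_times`` gives the onset of each dwell in seconds from the start of
    the record, so dwells can be mapped back onto sample indices.
    """

    labels: list
    durations: np.ndarray
    dead_time: float
    start_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be > 0")
        for a, b in zip(self.labels, self.labels[1:]):
            if a == b:
                raise ValueError("dwell labels must alternate")
        if self.start_times is None:
            self.start_times = np.concatenate([[0.0], np.cumsum(self.durations)[:-1]])
        else:
            self.start_times = np.asarray(self.start_times, dtype=float)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class BurstPartition:
    """Bursts (lists of within-burst dwell indices) and inter-burst gaps."""

    dwells: DwellSequence
    bursts: list  # list of lists of indices into dwells
    gap_indices: list  # indices of inter-burst nonconductive dwells
    t_crit: float

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def burst_dwells(self):
        """Yield (label, duration) over all within-burst dwells."""
        for burst in self.bursts:
            for i in burst:
                yield self.dwells.labels[i], self.dwells.durations[i]


@dataclass
class HistogramFit:
    """Two-Gaussian deconvolution of an all-points histogram."""

    bin_edges: np.ndarray
    counts: np.ndarray
    means: np.ndarray          # pA, [nonconductive, conductive]
    sds: np.ndarray            # pA
    areas: np.ndarray          # component areas (sample counts)
    f_conductive: float
    f_nonconductive: float
    f_conductive_sd: float
    covar: np.ndarray | None
    unimodal: bool
    redchi: float

    def __post_init__(self) -> None:
        if not math.isclose(self.f_conductive + self.f_nonconductive, 1.0,
                            abs_tol=1e-9):
            raise ValueError("fractions must sum to 1")


def all_points_histogram(
    trace: CurrentTrace, n_bins: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of every current sample; equal-width bins over [min, max]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    samples = trace.samples
    lo, hi = float(samples.min()), float(samples.max())
    if lo == hi:
        warnings.warn("constant trace: all samples fall in a single bin",
                      stacklevel=2)
        hi = lo + 1.0
    counts, edges = np.histogram(samples, bins=n_bins, range=(lo, hi))
    return edges, counts


def _init_two_means(centers: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    """Initial component means: the tallest bin and the tallest bin at least a
    quarter of the range away from it."""
    i0 = int(np.argmax(counts))
    span = centers[-1] - centers[0]
    far = np.abs(centers - centers[i0]) > span / 4
    if not far.any():
        return float(centers[i0]), float(centers[i0] + span / 2)
    masked = np.where(far, counts, -1)
    i1 = int(np.argmax(masked))
    return float(centers[i0]), float(centers[i1])


def fit_two_gaussians(
    edges: np.ndarray,
    counts: np.ndarray,
    n_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> HistogramFit:
    """Weighted least-squares fit of two Gaussians to histogram counts.

    Fractions are component areas normalized to sum to 1 (areas equal
    occupancy probabilities); the one-sd error on the conductive fraction is
    propagated from the fit covariance.  The component with mean nearer 0 pA
    is labeled nonconductive (the closed level is the baseline).  If the two
    means collapse within one component sd the result is flagged unimodal.
    """
    edges = np.asarray(edges, dtype=float)
    counts = np.asarray(counts, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 2:
        raise ValueError("need at least 2 occupied bins to deconvolve")
    width = edges[1] - edges[0]
    weights = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    rng = rng or np.random.default_rng(0)

    model = GaussianModel(prefix="g1_") + GaussianModel(prefix="g2_")
    m1, m2 = _init_two_means(centers, counts)
    sigma0 = max((centers[-1] - centers[0]) / 10.0, width)
    total = counts.sum() * width

    result = None
    for attempt in range(n_restarts + 1):
        jitter = 0.0 if attempt == 0 else rng.normal(0, sigma0, size=2)
        params = model.make_params(
            g1_center=m1 + (jitter[0] if attempt else 0.0),
            g1_sigma=sigma0,
            g1_amplitude=total / 2,
            g2_center=m2 + (jitter[1] if attempt else 0.0),
            g2_sigma=sigma0,
            g2_amplitude=total / 2,
        )
        for p in ("g1_sigma", "g2_sigma"):
            params[p].set(min=width / 10)
        for p in ("g1_amplitude", "g2_amplitude"):
            params[p].set(min=0.0)
        result = model.fit(counts, params, x=centers, weights=weights)
        if result.success:
            break
    if result is None or not result.success:
        raise RuntimeError(
            f"two-Gaussian fit failed after {n_restarts} restarts; "
            f"last residual: {result.chisqr if result else 'n/a'}"
        )

    p = result.params
    comp = sorted(
        ("g1_", "g2_"), key=lambda pre: abs(p[pre + "center"].value)
    )  # nearer 0 pA first -> nonconductive
    means = np.array([p[pre + "center"].value for pre in comp])
    sds = np.array([p[pre + "sigma"].value for pre in comp])
    areas = np.array([p[pre + "amplitude"].value for pre in comp]) / width
    a_nc, a_c = areas
    s = a_nc + a_c
    f_c = float(a_c / s)

    # delta-method error on f_c = a_c/(a_nc + a_c) from the amplitude covariance
    f_sd = float("nan")
    if result.covar is not None:
        names = result.var_names
        i_nc = names.index(comp[0] + "amplitude")
        i_c = names.index(comp[1] + "amplitude")
        g = np.zeros(len(names))
        g[i_c] = a_nc / s**2 * width  # d f / d amplitude params (scaled by width)
        g[i_nc] = -a_c / s**2 * width
        # amplitudes entered areas via /width, so gradient wrt raw params:
        g[i_c] = a_nc / s**2 / width
        g[i_nc] = -a_c / s**2 / width
        f_sd = float(np.sqrt(g @ result.covar @ g))

    # collapsed fit: overlapping means, or one component carrying ~no area
    unimodal = (abs(means[1] - means[0]) < max(sds)) or (
        min(f_c, 1.0 - f_c) < 1e-3
    )
    return HistogramFit(
        bin_edges=edges,
        counts=counts,
        means=means,
        sds=sds,
        areas=areas,
        f_conductive=f_c,
        f_nonconductive=1.0 - f_c,
        f_conductive_sd=f_sd,
        covar=result.covar,
        unimodal=bool(unimodal),
        redchi=float(result.redchi),
    )


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean array -> (values, lengths)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def idealize_trace(
    trace: CurrentTrace,
    levels: tuple[float, float],
    threshold_frac: float = 0.5,
    lowpass_hz: float | None = 1000.0,
    dead_time: float | None = None,
) -> DwellSequence:
    """Half-amplitude-threshold idealization into alternating dwells.

    The trace is optionally Gaussian low-pass filtered (default cutoff
    1 kHz), thresholded at ``threshold_frac`` of the way between the two
    level means, run-length encoded, and dwells shorter than the dead time
    (default two sample intervals) are merged into their neighbors.  The
    level farther from 0 pA is the conductive one.
    """
    mu1, mu2 = float(levels[0]), float(levels[1])
    if mu1 == mu2:
        raise ValueError("level means must be distinct")
    fs = trace.sampling_rate
    if dead_time is None:
        dead_time = 2.0 / fs
    x = trace.samples
    # robust noise estimate from first differences (state changes are sparse)
    noise_sd = 1.4826 * np.median(np.abs(np.diff(x))) / np.sqrt(2)
    if abs(mu1 - mu2) < noise_sd:
        raise ValueError(
            f"level separation {abs(mu1 - mu2):.3g} pA below noise sd "
            f"{noise_sd:.3g} pA; re-fit the histogram before idealizing"
        )
    if lowpass_hz:
        sigma = fs * np.sqrt(np.log(2)) / (2 * np.pi * lowpass_hz)
        if sigma > 0.3:
            x = gaussian_filter1d(x, sigma)

    nonconductive_level, conductive_level = sorted((mu1, mu2), key=abs)
    thr = nonconductive_level + threshold_frac * (
        conductive_level - nonconductive_level
    )
    if conductive_level > nonconductive_level:
        is_open = x > thr
    else:
        is_open = x < thr

    values, lengths = _runs(is_open.astype(np.int8))
    lengths = lengths.astype(float)
    # merge runs below the dead time into their neighbors until stable
    min_len = dead_time * fs
    while values.size > 1:
        short = np.flatnonzero(lengths < min_len)
        if short.size == 0:
            break
        i = int(short[np.argmin(lengths[short])])
        if i == 0:
            lengths[1] += lengths[0]
            values, lengths = values[1:], lengths[1:]
        elif i == values.size - 1:
            lengths[-2] += lengths[-1]
            values, lengths = values[:-1], lengths[:-1]
        else:
            lengths[i - 1] += lengths[i] + lengths[i + 1]
            keep = np.ones(values.size, dtype=bool)
            keep[i:i + 2] = False
            values, lengths = values[keep], lengths[keep]

    labels = [CONDUCTIVE if v else NONCONDUCTIVE for v in values]
    durations = lengths / fs
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return DwellSequence(
        labels=labels, durations=durations, dead_time=dead_time, start_times=starts
    )


def segment_bursts(dwells: DwellSequence, t_crit: float = 0.1) -> BurstPartition:
    """Split a dwell sequence into bursts at nonconductive gaps >= t_crit."""
    if t_crit <= dwells.dead_time:
        raise ValueError("t_crit must exceed the dead time")
    bursts: list[list[int]] = []
    gaps: list[int] = []
    current: list[int] = []
    for i, (label, dur) in enumerate(zip(dwells.labels, dwells.durations)):
        if label == NONCONDUCTIVE and dur >= t_crit:
            if current:
                bursts.append(current)
                current = []
            gaps.append(i)
        else:
            current.append(i)
    if current:
        bursts.append(current)
    # a "burst" must contain at least one conductive dwell
    bursts = [b for b in bursts if any(dwells.labels[i] == CONDUCTIVE for i in b)]
    return BurstPartition(dwells=dwells, bursts=bursts, gap_indices=gaps,
                          t_crit=t_crit)


def dwell_statistics(partition: BurstPartition) -> tuple[float, float, float]:
    """Mean within-burst dwell times and intra-burst open probability.

    Returns ``(tau_open, tau_closed, p_o_burst)`` in seconds/seconds/fraction,
    with ``p_o_burst = tau_open / (tau_open + tau_closed)``.
    """
    opens = [d for lab, d in partition.burst_dwells() if lab == CONDUCTIVE]
    closes = [d for lab, d in partition.burst_dwells() if lab == NONCONDUCTIVE]
    if not opens or not closes:
        missing = NONCONDUCTIVE if opens else CONDUCTIVE
        raise ValueError(f"no within-burst {missing} dwell; statistic undefined")
    tau_open = float(np.mean(opens))
    tau_closed = float(np.mean(closes))
    return tau_open, tau_closed, tau_open / (tau_open + tau_closed)


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1))


def exchange_rate_from_dwells(
    tau_open: float, tau_closed: float
) -> tuple[float, float]:
    """Two-state exchange rate from mean dwell times.

    ``kex = 1/tau_open + 1/tau_closed``; returns (raw, rounded to 2
    significant figures).  An infinite dwell contributes 0 to the rate.
    """
    if tau_open <= 0 or tau_closed <= 0:
        raise ValueError("dwell times must be > 0")
    kex = (0.0 if math.isinf(tau_open) else 1.0 / tau_open) + (
        0.0 if math.isinf(tau_closed) else 1.0 / tau_closed
    )
    return kex, _round_sig(kex, 2)


def analyze_trace(
    trace: CurrentTrace,
    n_bins: int = 25,
    t_crit: float = 0.1,
    lowpass_hz: float | None = 1000.0,
) -> dict:
    """Full single-trace analysis pipeline.

    All-points histogram -> two-Gaussian deconvolution -> idealization at the
    fitted level means -> burst segmentation -> within-burst dwell statistics
    and a second deconvolution restricted to within-burst samples (the
    intra-burst conductive fraction).  Returns a plain dict of results.
    """
    edges, counts = all_points_histogram(trace, n_bins)
    fit = fit_two_gaussians(edges, counts)
    dwells = idealize_trace(
        trace, (fit.means[0], fit.means[1]), lowpass_hz=lowpass_hz
    )
    partition = segment_bursts(dwells, t_crit=t_crit)
    report: dict = {
        "histogram_fit": fit,
        "dwells": dwells,
        "bursts": partition,
        "f_conductive_allpoints": fit.f_conductive,
    }
    # intra-burst all-points histogram
    fs = trace.sampling_rate
    mask = np.zeros(trace.samples.size, dtype=bool)
    for burst in partition.bursts:
        i0 = int(round(dwells.start_times[burst[0]] * fs))
        last = burst[-1]
        i1 = int(round((dwells.start_times[last] + dwells.durations[last]) * fs))
        mask[i0:i1] = True
    if mask.any():
        sub = CurrentTrace(sampling_rate=fs, samples=trace.samples[mask])
        e2, c2 = all_points_histogram(sub, n_bins)
        try:
            fit_burst = fit_two_gaussians(e2, c2)
            report["histogram_fit_burst"] = fit_burst
            report["f_conductive_burst"] = fit_burst.f_conductive
        except (ValueError, RuntimeError):
            report["histogram_fit_burst"] = None
    try:
        tau_o, tau_c, p_o = dwell_statistics(partition)
        kex_raw, kex_2sf = exchange_rate_from_dwells(tau_o, tau_c)
        report.update(
            tau_open=tau_o, tau_closed=tau_c, p_o_burst=p_o,
            kex_raw=kex_raw, kex_2sf=kex_2sf,
        )
    except ValueError:
        report.update(tau_open=None, tau_closed=None, p_o_burst=None)
    return report
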