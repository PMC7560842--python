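"""Synthetic data generators emulating the study conditions.

Single-channel records are produced by exact-jump simulation of a
continuous-time Markov chain over the three conformational states P
(permeable/conductive), C (closed HBC gate) and I (inactivated SF gate),
with the I<->C edge absent: both nonconductive states exchange with P only.
Millisecond P<->C flicker inside bursts is nested in second-scale P<->I
burst/inter-burst transitions.  Peak lists place one peak per reporter per
state with height proportional to population.

The default wild-type-like parameter set: open level -10 pA at -200 mV with
1.5 pA Gaussian noise (conventions for a ~100 pS channel at this voltage,
not measured values), intra-burst conductive fraction 0.84, P<->C exchange
rate 160 s^-1, P<->I exchange rate 1.4 s^-1, sampled at 40 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .gating import CurrentTrace
from .peaks import KCSA_FINGERPRINT, Peak, PeakList, Conditions, StateFingerprint

__all__ = [
    "GatingScheme",
    "ThermoModel",
    "stationary_distribution",
    "simulate_gating_trace",
    "generate_peaklist",
    "generate_temperature_series",
]

GAS_CONSTANT = 8.31446  # J / mol / K


@dataclass
class GatingScheme:
    """CTMC over conformational states with per-state conductance levels.

    ``q[i, j]`` (i != j) is the transition rate i->j in s^-1; rows sum to 0.
    """

    states: tuple
    conductance_pa: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.conductance_pa = np.asarray(self.conductance_pa, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        n = len(self.states)
        if self.q.shape != (n, n) or self.conductance_pa.size != n:
            raise ValueError("scheme dimensions disagree")
        off = self.q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(self.q.sum(axis=1)) > 1e-12 * max(1.0, np.abs(off).max())):
            raise ValueError("generator rows must sum to 0")

    @classmethod
    def three_state(
        cls,
        p_conductive_intra: float = 0.84,
        kex_pc: float = 160.0,
        k_pi: float = 0.4,
        k_ip: float = 1.0,
        open_level_pa: float = -10.0,
    ) -> "GatingScheme":
        """I <-> P <-> C chain (no direct I<->C edge).

        ``p_conductive_intra`` is the stationary weight of P within {P, C};
        because the chain satisfies detailed balance, the conditional
        distribution over {P, C} is unchanged by adding the P<->I leg, so the
        intra-burst conductive fraction equals this value exactly.  The
        default P<->I rates sum to the slow exchange rate 1.4 s^-1.
        """
        if not (0 < p_conductive_intra < 1):
            raise ValueError("p_conductive_intra must be in (0, 1)")
        k_pc = (1 - p_conductive_intra) * kex_pc
        k_cp = p_conductive_intra * kex_pc
        q = np.array(
            [
                [-(k_pc + k_pi), k_pc, k_pi],
                [k_cp, -k_cp, 0.0],
                [k_ip, 0.0, -k_ip],
            ]
        )
        return cls(states=("P", "C", "I"),
                   conductance_pa=np.array([open_level_pa, 0.0, 0.0]), q=q)

    @classmethod
    def two_state(
        cls,
        p_conductive: float,
        kex: float = 160.0,
        open_level_pa: float = -10.0,
    ) -> "GatingScheme":
        """P <-> C flicker only (no slow inactivated leg)."""
        k_pc = (1 - p_conductive) * kex
        k_cp = p_conductive * kex
        q = np.array([[-k_pc, k_pc], [k_cp, -k_cp]])
        return cls(states=("P", "C"),
                   conductance_pa=np.array([open_level_pa, 0.0]), q=q)

    @classmethod
    def wild_type_like(cls) -> "GatingScheme":
        return cls.three_state()


def stationary_distribution(q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0, sum(pi) = 1, pi >= 0.

    Raises on reducible chains (including absorbing states), where the
    stationary distribution is not unique or not strictly positive.
    """
    q = np.asarray(q, dtype=float)
    ns = null_space(q.T)
    if ns.shape[1] != 1:
        raise ValueError("reducible chain: stationary distribution not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-12):
        raise ValueError("invalid generator: negative stationary weight")
    pi = np.clip(pi, 0.0, None)
    if np.any(pi < 1e-15):
        raise ValueError("reducible chain: a state is unreachable")
    return pi / pi.sum()


def sample_state_path(
    scheme: GatingScheme,
    duration: float,
    rng: np.random.Generator,
    start_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-jump (Gillespie) simulation of the CTMC.

    Returns ``(jump_times, states)`` where ``states[k]`` is occupied from
    ``jump_times[k]`` to ``jump_times[k+1]`` (or ``duration`` for the last).
    The start state is drawn from the stationary distribution unless given.
    """
    q = scheme.q
    n = q.shape[0]
    exit_rates = -np.diag(q)
    if start_state is None:
        pi = stationary_distribution(q)
        state = int(rng.choice(n, p=pi))
    else:
        state = int(start_state)
    t = 0.0
    times = [0.0]
    states = [state]
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            break  # absorbing under all-zero rates: stays put
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs = probs / rate
        state = int(rng.choice(n, p=probs))
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=int)


def simulate_gating_trace(
    scheme: GatingScheme,
    duration: float,
    fs: float = 40000.0,
    noise_sd: float = 1.5,
    seed: int | None = None,
    start_state: int | None = None,
) -> CurrentTrace:
    """Noisy sampled current record with the true per-sample state path.

    The continuous-time state path is sampled onto the ``fs`` grid (no
    missed-event correction: events shorter than a sample simply vanish, a
    property the analysis stage must tolerate), and independent Gaussian
    noise of sd ``noise_sd`` pA is added to the per-state conductance level.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n_samples = int(round(duration * fs))
    if n_samples < 100:
        raise ValueError("duration * fs must be >= 100 samples")
    rng = np.random.default_rng(seed)
    times, states = sample_state_path(scheme, duration, rng, start_state)
    grid = np.arange(n_samples) / fs
    idx = np.searchsorted(times, grid, side="right") - 1
    path = states[idx]
    current = scheme.conductance_pa[path]
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=n_samples)
    return CurrentTrace(
        sampling_rate=fs,
        samples=current,
        true_state_path=path,
        seed=seed,
        conditions={"voltage_mv": -200.0, "kcl_mm": 100.0},
    )


def generate_peaklist(
    populations: dict,
    fingerprint: StateFingerprint = KCSA_FINGERPRINT,
    height_scale: float = 100.0,
    noise_frac: float = 0.05,
    seed: int | None = None,
    detection_floor: float = 0.02,
) -> PeakList:
    """One peak per reporter per detectable state, height ~ population.

    States with population below ``detection_floor`` are omitted, emulating
    minor states invisible in the spectra.  Heights get multiplicative
    Gaussian noise of relative sd ``noise_frac``.
    """
    pops = {s: float(p) for s, p in populations.items()}
    if any(p < 0 for p in pops.values()):
        raise ValueError("populations must be >= 0")
    if abs(sum(pops.values()) - 1.0) > 1e-9:
        raise ValueError("populations must sum to 1")
    rng = np.random.default_rng(seed)
    peaks = []
    for state in sorted(pops):
        if pops[state] < detection_floor:
            continue
        rep_map = fingerprint.positions.get(state, {})
        for rep in sorted(rep_map):
            h_ppm, c_ppm = rep_map[rep]
            height = height_scale * pops[state]
            if noise_frac > 0:
                height *= max(0.0, 1.0 + rng.normal(0.0, noise_frac))
            peaks.append(
                Peak(
                    shift_h=h_ppm,
                    shift_c=c_ppm,
                    height=height,
                    label=f"{rep}-{state}",
                )
            )
    return PeakList(peaks)


@dataclass
class ThermoModel:
    """van 't Hoff temperature dependence of the C <-> P equilibrium.

    ``ln(p_C/p_P) = -dH/(R T) + dS/R`` with dH in kJ/mol and dS in J/mol/K.
    ``p_I`` is held temperature-independent (the I-state trend is not
    modeled; the generator only needs a monotone C/P series).
    """

    dh_kj_mol: float
    ds_j_mol_k: float
    p_i: float = 0.0

    @classmethod
    def from_reference(
        cls, p_c_ref: float, t_ref_c: float, dh_kj_mol: float, p_i: float = 0.0
    ) -> "ThermoModel":
        """Anchor dS so that p_C/(p_P+p_C) = p_c_ref at t_ref_c."""
        t = t_ref_c + 273.15
        ratio = p_c_ref / (1 - p_c_ref)
        ds = GAS_CONSTANT * (np.log(ratio) + dh_kj_mol * 1e3 / (GAS_CONSTANT * t))
        return cls(dh_kj_mol=dh_kj_mol, ds_j_mol_k=ds, p_i=p_i)

    def populations(self, temperature_c: float) -> dict:
        t = temperature_c + 273.15
        ratio = np.exp(
            -self.dh_kj_mol * 1e3 / (GAS_CONSTANT * t) + self.ds_j_mol_k / GAS_CONSTANT
        )
        p_c_cond = ratio / (1 + ratio)  # C fraction within {P, C}
        avail = 1.0 - self.p_i
        pops = {"P": avail * (1 - p_c_cond), "C": avail * p_c_cond, "I": self.p_i}
        if not all(0 < p < 1 for s, p in pops.items() if s != "I"):
            raise ValueError(
                f"populations leave (0,1) at {temperature_c} C: {pops}"
            )
        return pops


def generate_temperature_series(
    thermo: ThermoModel,
    temperatures_c,
    fingerprint: StateFingerprint = KCSA_FINGERPRINT,
    pH: float = 3.0,
    noise_frac: float = 0.05,
    seed: int | None = None,
) -> list:
    """Peak lists at several temperatures, populations from the van 't Hoff law."""
    temperatures_c = list(temperatures_c)
    if len(temperatures_c) < 2:
        raise ValueError("need >= 2 temperatures")
    rng = np.random.default_rng(seed)
    out = []
    for t_c in temperatures_c:
        pops = thermo.populations(t_c)
        plist = generate_peaklist(
            pops,
            fingerprint=fingerprint,
            noise_frac=noise_frac,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append((Conditions(pH=pH, temperature_c=t_c), plist))
    return out
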