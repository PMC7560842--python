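"""Single-channel analysis: histograms, deconvolution, idealization, bursts."""

import numpy as np
import pytest

from kcsalink import synth
from kcsalink.gating import (
    CONDUCTIVE,
    NONCONDUCTIVE,
    CurrentTrace,
    DwellSequence,
    all_points_histogram,
    dwell_statistics,
    exchange_rate_from_dwells,
    fit_two_gaussians,
    idealize_trace,
    segment_bursts,
)


def make_dwells(spec, dead_time=5e-5):
    """spec: list of (label, duration_s)."""
    labels = [s[0] for s in spec]
    durations = np.array([s[1] for s in spec])
    return DwellSequence(labels=labels, durations=durations, dead_time=dead_time)


class TestHistogram:
    def test_constant_trace_single_bin(self):
        tr = CurrentTrace(sampling_rate=1000.0, samples=np.ones(1000))
        with pytest.warns(UserWarning, match="constant"):
            edges, counts = all_points_histogram(tr, 10)
        assert counts.sum() == 1000
        assert np.count_nonzero(counts) == 1

    def test_counts_conserved(self, rng):
        tr = CurrentTrace(sampling_rate=1000.0, samples=rng.normal(size=5000))
        _, counts = all_points_histogram(tr, 25)
        assert counts.sum() == 5000

    def test_bimodal_two_level_trace(self, rng):
        n = 100_000
        state = rng.random(n) < 0.84
        x = np.where(state, -10.0, 0.0) + rng.normal(0, 1.5, n)
        tr = CurrentTrace(sampling_rate=40000.0, samples=x)
        edges, counts = all_points_histogram(tr, 25)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # one mode near each conductance level
        lower = centers < -5.0
        assert abs(centers[lower][np.argmax(counts[lower])] - (-10.0)) < 1.0
        assert abs(centers[~lower][np.argmax(counts[~lower])] - 0.0) < 1.0


class TestTwoGaussianFit:
    def fit_mixture(self, f_cond, rng, n=100_000, sep=10.0, sd=1.5):
        state = rng.random(n) < f_cond
        x = np.where(state, -sep, 0.0) + rng.normal(0, sd, n)
        tr = CurrentTrace(sampling_rate=40000.0, samples=x)
        edges, counts = all_points_histogram(tr, 25)
        return fit_two_gaussians(edges, counts)

    def test_recovers_84_16_split(self, rng):
        fit = self.fit_mixture(0.84, rng)
        assert fit.f_conductive == pytest.approx(0.84, abs=0.01)
        assert fit.f_conductive + fit.f_nonconductive == pytest.approx(1.0)
        assert np.all(fit.sds > 0)
        # conductive component is the one farther from 0 pA
        assert abs(fit.means[1]) > abs(fit.means[0])

    def test_symmetric_mixture_within_one_sd(self, rng):
        fit = self.fit_mixture(0.5, rng)
        assert abs(fit.f_conductive - 0.5) <= max(fit.f_conductive_sd, 0.01)

    def test_single_gaussian_flagged_unimodal(self, rng):
        x = rng.normal(-5.0, 1.5, 50_000)
        tr = CurrentTrace(sampling_rate=40000.0, samples=x)
        edges, counts = all_points_histogram(tr, 25)
        fit = fit_two_gaussians(edges, counts)
        assert fit.unimodal

    def test_fraction_estimates_unbiased(self):
        """Median recovery error < 0.02 across seeds and true fractions."""
        for truth in (0.16, 0.45, 0.70):
            errs = []
            for seed in range(8):
                rng = np.random.default_rng(1000 + seed)
                fit = self.fit_mixture(truth, rng, n=50_000)
                errs.append(fit.f_conductive - truth)
            assert abs(np.median(errs)) < 0.02


def square_wave_trace(fs=40000.0, period_s=0.02, duration=1.0, noise_sd=0.0,
                      seed=0):
    """Alternating 10 ms at 0 pA / 10 ms at -10 pA."""
    n = int(duration * fs)
    half_period = int(round(period_s / 2 * fs))
    is_open = (np.arange(n) // half_period) % 2 == 1
    x = np.where(is_open, -10.0, 0.0)
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return CurrentTrace(sampling_rate=fs, samples=x)


class TestIdealize:
    def test_noiseless_square_wave(self):
        tr = square_wave_trace()
        dw = idealize_trace(tr, (0.0, -10.0), lowpass_hz=None)
        assert len(dw) == 100
        assert np.allclose(dw.durations, 0.01)
        assert dw.labels[0] == NONCONDUCTIVE and dw.labels[1] == CONDUCTIVE

    def test_noisy_square_wave_dwell_count(self):
        tr = square_wave_trace(noise_sd=2.0, seed=3)  # 20% of amplitude
        dw = idealize_trace(tr, (0.0, -10.0))
        assert abs(len(dw) - 100) <= 5

    def test_subdeadtime_blip_merged(self):
        fs = 40000.0
        x = np.zeros(4000)
        x[2000:2003] = -10.0  # 3-sample blip
        tr = CurrentTrace(sampling_rate=fs, samples=x)
        dw = idealize_trace(tr, (0.0, -10.0), lowpass_hz=None,
                            dead_time=4 / fs)
        assert len(dw) == 1
        assert dw.labels[0] == NONCONDUCTIVE

    def test_overlapping_levels_rejected(self, rng):
        tr = CurrentTrace(sampling_rate=40000.0,
                          samples=rng.normal(0, 3.0, 10_000))
        with pytest.raises(ValueError, match="separation"):
            idealize_trace(tr, (0.0, -1.0), lowpass_hz=None)


class TestBursts:
    def test_long_gap_splits_bursts(self):
        dw = make_dwells([
            (CONDUCTIVE, 5e-3), (NONCONDUCTIVE, 20e-3), (CONDUCTIVE, 5e-3),
            (NONCONDUCTIVE, 2.0), (CONDUCTIVE, 5e-3),
        ])
        part = segment_bursts(dw, t_crit=0.1)
        assert part.n_bursts == 2
        assert part.gap_indices == [3]

    def test_all_short_gaps_single_burst(self):
        dw = make_dwells([(CONDUCTIVE, 5e-3), (NONCONDUCTIVE, 20e-3),
                          (CONDUCTIVE, 5e-3)])
        part = segment_bursts(dw, t_crit=0.1)
        assert part.n_bursts == 1
        assert len(part.bursts[0]) == 3

    def test_no_conductive_dwell_zero_bursts(self):
        dw = DwellSequence(labels=[NONCONDUCTIVE], durations=[5.0],
                           dead_time=5e-5)
        assert segment_bursts(dw, t_crit=0.1).n_bursts == 0

    def test_invariant_to_flanking_gaps(self):
        core = [(CONDUCTIVE, 5e-3), (NONCONDUCTIVE, 20e-3), (CONDUCTIVE, 5e-3)]
        plain = segment_bursts(make_dwells(core), t_crit=0.1)
        padded = segment_bursts(
            make_dwells([(NONCONDUCTIVE, 3.0)] + core + [(NONCONDUCTIVE, 4.0)]),
            t_crit=0.1,
        )
        assert plain.n_bursts == padded.n_bursts
        assert [len(b) for b in plain.bursts] == [len(b) for b in padded.bursts]

    def test_burst_count_tracks_inactivation_rate(self, wt_scheme):
        """Number of bursts ~ Poisson(duration * pi_P * k_PI)."""
        duration = 200.0
        rng = np.random.default_rng(42)
        times, states = synth.sample_state_path(wt_scheme, duration, rng)
        durations = np.diff(np.append(times, duration))
        labels = [CONDUCTIVE if s == 0 else NONCONDUCTIVE for s in states]
        # collapse consecutive same-label dwells (C and I both nonconductive)
        seq = []
        for lab, dur in zip(labels, durations):
            if seq and seq[-1][0] == lab:
                seq[-1] = (lab, seq[-1][1] + dur)
            else:
                seq.append((lab, dur))
        part = segment_bursts(make_dwells(seq), t_crit=0.1)
        pi = synth.stationary_distribution(wt_scheme.q)
        k_pi = wt_scheme.q[0, 2]
        expected = duration * pi[0] * k_pi
        assert abs(part.n_bursts - expected) <= 3 * np.sqrt(expected) + 2


class TestDwellStatistics:
    def test_arithmetic(self):
        dw = make_dwells([
            (CONDUCTIVE, 0.010), (NONCONDUCTIVE, 0.030), (CONDUCTIVE, 0.010),
            (NONCONDUCTIVE, 0.030), (CONDUCTIVE, 0.010),
        ])
        tau_o, tau_c, p_o = dwell_statistics(segment_bursts(dw, t_crit=0.1))
        assert tau_o == pytest.approx(0.010)
        assert tau_c == pytest.approx(0.030)
        assert p_o == pytest.approx(0.25)

    def test_printed_dwell_times_give_po(self):
        tau_o, tau_c = 7.9e-3, 27.0e-3
        assert tau_o / (tau_o + tau_c) == pytest.approx(0.226, abs=0.001)

    def test_missing_label_rejected(self):
        dw = make_dwells([(CONDUCTIVE, 0.01)])
        with pytest.raises(ValueError, match="undefined"):
            dwell_statistics(segment_bursts(dw, t_crit=0.1))


class TestExchangeRateFromDwells:
    def test_printed_dwells_round_to_160(self):
        raw, rounded = exchange_rate_from_dwells(7.9e-3, 27.0e-3)
        assert raw == pytest.approx(163.6, abs=0.05)
        assert rounded == 160.0

    def test_equal_dwells(self):
        raw, rounded = exchange_rate_from_dwells(0.010, 0.010)
        assert raw == pytest.approx(200.0)
        assert rounded == 200.0

    def test_infinite_closed_dwell_limit(self):
        raw, _ = exchange_rate_from_dwells(0.010, float("inf"))
        assert raw == pytest.approx(100.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            exchange_rate_from_dwells(0.0, 0.01)


def test_round_trip_recovers_generator_dwell_times():
    """simulate -> idealize -> dwell statistics recovers the CTMC means
    within 10% given enough dwells."""
    scheme = synth.GatingScheme.two_state(p_conductive=0.5, kex=160.0)
    true_tau = 1.0 / scheme.q[0, 1]  # symmetric: 12.5 ms both ways
    trace = synth.simulate_gating_trace(scheme, duration=30.0, noise_sd=1.5,
                                        seed=11)
    dw = idealize_trace(trace, (-10.0, 0.0))
    part = segment_bursts(dw, t_crit=0.2)
    tau_o, tau_c, p_o = dwell_statistics(part)
    assert len(dw) >= 500
    assert tau_o == pytest.approx(true_tau, rel=0.10)
    assert tau_c == pytest.approx(true_tau, rel=0.10)
    assert p_o == pytest.approx(0.5, abs=0.05)


def test_po_burst_agrees_with_histogram_fraction():
    """Dwell-based and histogram-based conductive fractions agree on clean
    two-state traces."""
    scheme = synth.GatingScheme.two_state(p_conductive=0.7, kex=160.0)
    trace = synth.simulate_gating_trace(scheme, duration=30.0, noise_sd=0.5,
                                        seed=5)
    edges, counts = all_points_histogram(trace, 25)
    fit = fit_two_gaussians(edges, counts)
    dw = idealize_trace(trace, tuple(fit.means))
    _, _, p_o = dwell_statistics(segment_bursts(dw, t_crit=0.2))
    assert abs(p_o - fit.f_conductive) < 0.05
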