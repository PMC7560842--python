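# Methods

## Chemical-exchange model

Transverse magnetization of a nucleus exchanging between n conformational
states evolves under the Bloch–McConnell equations, dM/dt = L·M with

```
L[j,j] = i·ω_j − R2_j − Σ_m k_{j→m}        L[j,m] = k_{m→j}  (m ≠ j)
```

ω_j is the angular resonance offset of state j (ppm converted with
γ(¹³C)/γ(¹H) = 0.251450 and γ(¹⁵N)/γ(¹H) = 0.101329; a change in the sixth
digit moves Δω by < 0.01 %). For a two-state model specified by a single
exchange rate, stationarity fixes the microscopic rates as
k_{A→B} = p_B·k_ex and k_{B→A} = p_A·k_ex. Model validation enforces
populations summing to 1 (1e-12), non-negative rates, and detailed flux
balance (1e-9, relative to the gross flux for numerically large rates).

Eigen-decomposition of L gives modes (λ_k, a_k) where the signal from an
equilibrium start p is s(t) = Σ_k a_k·exp(λ_k t), a_k = (Σ_j V_jk)(V⁻¹p)_k,
and Σ_k a_k = 1. The **major component** is the mode with the largest
|Re a_k| — what a spectroscopist reads off as the dominant resonance — and
the exchange broadening is R_ex = −Re λ_major − R2(majority state).
Intrinsic R2 defaults to 0 so R_ex is purely the exchange contribution.
Eigenvalues within 1e-9 of each other are treated as degenerate; the tie
goes to the slower-decaying mode and the result is flagged.

Known limits used as oracles: slow exchange (Δω ≫ k_ex) gives
R_ex → p_minor·k_ex (the major line decays by leaving it), fast exchange
(k_ex ≫ Δω) gives R_ex → p_A·p_B·Δω²/k_ex; both hold within 2 % at 20×
separation. Regime labels use a factor-2 convention: slow if k_ex < Δω/2,
fast if k_ex > 2Δω, intermediate between, and Δω = 0 is "fast" (one
resonance at any rate).

Line shapes are analytic sums of complex Lorentzians,
S(f) = 2·Re Σ_k a_k/(−λ_k + i·2πf), which integrates to the total starting
magnetization. Lorentzian tails fall off as 1/f², so quantitative
integration needs a span of order 10²–10³ half-widths; `recommended_axis`
pads by 300 half-widths and resolves the narrowest line at ≥ 8 points per
half-width (capped at 2×10⁶ grid points). A narrower user axis triggers a
warning carrying a truncation estimate from the endpoint intensities.
Frequencies are handled in Hz internally; ppm appears only at I/O
boundaries.

## Single-channel analysis

All-points histograms use 25 equal-width bins spanning [min, max] by
default. Deconvolution fits the sum of two Gaussians to bin counts by
weighted least squares (Poisson weights 1/√max(count, 1), lmfit backend);
initial means are the tallest bin and the tallest bin at least a quarter of
the range away, with up to three jittered restarts. Conductive and
nonconductive **fractions are component areas** normalized to sum to one —
areas equal occupancy probabilities, heights do not — and the one-σ error
on the conductive fraction comes from the amplitude covariance by the delta
method. The component with mean nearer 0 pA is the nonconductive
(baseline) one; at the negative recording voltage the conductive level is
the larger |current|. Fits whose means collapse within one component σ, or
where one component carries < 10⁻³ of the area, are flagged unimodal.

Idealization is half-amplitude thresholding between the two level means
after an optional Gaussian low-pass (default cutoff 1 kHz, σ chosen for
−3 dB at the cutoff), with dwells shorter than the dead time (default two
sample intervals) merged into their neighbors, shortest first. This is the
simplest scheme that reproduces dwell statistics at the simulated
signal-to-noise; it is not a hidden-Markov idealizer, and events shorter
than the filter rise time (~0.3 ms at 1 kHz) are missed — at the default
kinetics that biases mean dwells by a few percent, within the 10 %
round-trip tolerance the tests enforce.

Bursts are terminated by nonconductive dwells ≥ t_crit. The default
t_crit = 100 ms sits between the millisecond intra-burst closures (~27 ms)
and the 1–10 s inter-burst gaps; it is user-overridable and the partition
is idempotent and invariant to flanking gaps. Dwell statistics are
arithmetic means over within-burst dwells only;
P_o(burst) = τ_open/(τ_open + τ_closed), and the two-state exchange rate is
k_ex = 1/τ_open + 1/τ_closed, reported both raw and rounded to two
significant figures. The histogram route and the dwell route estimate the
conductive fraction independently and are *not* forced to agree (heavy
noise, filtering and sub-conductance behavior can separate them); on clean
synthetic two-state traces they agree within ±0.05.

## Peak quantification

Assignment matches each peak to fingerprint (¹H, ¹³C) positions within a
rectangular tolerance box (defaults 0.03 ppm ¹H, 0.2 ppm ¹³C, typical
methyl-TROSY resolution), choosing the nearest tolerance-normalized
position; a peak inside two states' boxes raises an ambiguity error rather
than guessing. State fractions are per-reporter height ratios over the
normalization set (P/(P+C) or P/(P+C+I)), averaged over reporters with
equal weight; per-reporter values are retained. Heights, not volumes, are
used, so exchange-broadened states are under-weighted at equal integral —
this bias is deliberate (it mirrors intensity-based quantification) and is
noted in reports rather than corrected.

The shipped fingerprint positions for Val76γ1 and Leu59δ1 are synthetic
plausible methyl-region values (the experimental shift tables are not
public); they are separated far beyond the tolerances, and any real
fingerprint can be supplied as YAML.

## Structure contacts

Coordinates are read with gemmi (first model; altlocs resolved to highest
occupancy, ties alphabetically; author residue numbering kept). The
tetramer is built from the file's biological-assembly operators (identity
with a warning if absent); rotations must be orthonormal within 1e-3 on the
determinant. Cβ–Cβ distances support intra-subunit, inter-subunit-minimum
and overall-minimum pairing — exposed explicitly because published contact
clusters can include both intra- and inter-subunit pairs. Distances are
reported to 0.1 Å with full precision retained internally. The default
chain is the one with the most residues in the KcsA transmembrane range
22–124 (the channel chain in antibody-complex crystals is not chain A).

Mutation predictions use Zamyatnin (1972) mean residue volumes and only the
sign of the change: bulkier + contact tighter in the open structure →
`toward_C`; bulkier but not tighter → `none`; smaller at a tight open
contact → `toward_open`. Limitation: Ile and Leu share a mean volume in
this table, so β-branching isomerizations (L→I) register as "no volume
change" even though they can perturb packing.

## Synthetic generators

Gating uses exact-jump (Gillespie) CTMC simulation over I↔P↔C with no
direct I↔C edge — both nonconductive states route through P. The chain is
linear, hence detailed-balanced, so adding the slow P↔I leg leaves the
conditional P/C weights untouched: the generator's intra-burst conductive
fraction is exactly the two-state stationary weight, and the NMR and
electrophysiology generators share one population set by construction.
Defaults: intra-burst conductive fraction 0.84, k_ex(P↔C) = 160 s⁻¹
(k_{P→C} = 25.6, k_{C→P} = 134.4 s⁻¹), P↔I rates k_{P→I} = 0.4 and
k_{I→P} = 1.0 s⁻¹ (sum 1.4 s⁻¹, giving ~1 s inter-burst gaps and
second-scale bursts), open level −10 pA, noise σ = 1.5 pA, 40 kHz sampling.
The open level and noise are conventions for a ~100 pS channel at −200 mV.
The state path is sampled onto the grid with **no missed-event
correction** — brief events simply vanish below the sampling/filtering
resolution, which the analysis stage must tolerate, as with real recordings.
Starting states are drawn from the stationary distribution (computed by
null-space of Qᵀ, with reducible chains rejected), so occupancy estimates
are unbiased at any duration.

Peak lists carry one peak per reporter per state with height ∝ population,
multiplicative Gaussian height noise (default 5 %), and a detection floor
of 0.02 below which a state's peaks are omitted, emulating minor states
invisible in spectra. Temperature series follow a van 't Hoff law for the
P↔C equilibrium, ln(p_C/p_P) = −ΔH/(RT) + ΔS/R with ΔH for the P→C
direction (ΔH < 0 makes the C population fall with rising temperature);
ΔS can be anchored by a reference population at a reference temperature.
The I population is held fixed across temperature — the generator needs a
monotone C/P trend, not a calibrated three-state thermodynamic model, and
no thermodynamic parameters are claimed to match any measurement.

What the generators do *not* emulate: sub-conductance levels, modal gating
(high-P_o/flicker/low-P_o modes), baseline drift, capacitive transients,
filter ringing, and correlated noise. Passing tests therefore demonstrate
the correctness of the analysis chain under idealized three-state
statistics, not robustness to every artifact of real bilayer recordings.

## Test problem sizes

Stochastic checks use: 10⁵-sample (2.5 s at 40 kHz) traces × 20 seeds per
true fraction for deconvolution recovery (median error ≤ 0.02); 20 s traces
for the four-variant cross-modality correlation (median R² > 0.9 over 20
seeds); ten 60 s replicate state paths for stationarity (3 Monte-Carlo σ)
plus 20×25 s paths for dwell exponentiality (KS, α = 0.01 on the median);
30 s traces for dwell-time round trips (10 %). These sizes put Monte-Carlo
error comfortably inside each tolerance while keeping the suite fast.

## Degenerate inputs and tie-breaks

Constant traces histogram into a single bin with a warning; idealization
refuses level pairs closer than the estimated noise σ (robust MAD of first
differences); burst partitions with no conductive dwell are empty; dwell
statistics with a missing label raise rather than return NaN; equal-|Re a|
eigen modes resolve to the slower decay; fast-exchange classification at
Δω = 0 is by convention. File readers validate monotone uniform time grids
(1 µs jitter tolerance), report malformed peak-list lines with line
numbers, and all writers emit a format-version header that readers check.
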