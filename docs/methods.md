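# Methods

This document records the models the package implements, the assumptions
behind them, the default parameter values and why they were chosen, and the
numerical design of the estimators — including their measured limits.

## 1. Electrochemistry and selectivity (`thermokit.biophysics`)

### Nernst potentials

`nernst_potential(ion, c_out, c_in, T)` computes E = (RT/zF)·ln(c_out/c_in)
with CODATA constants (R = 8.314 J/(mol·K), F = 96485 C/mol). Inputs are
validated (positive concentrations, nonzero valence); the function is exact,
antisymmetric under concentration exchange, and scales as 1/z.

Worked values at 35 °C with the standard oocyte assumptions
(ND96 outside; 7 mM Na⁺, 100 mM K⁺, 0.1 mM Ca²⁺ inside):

| ion / condition | E (mV) |
|---|---|
| Na⁺ 96/7 | +69.53 |
| Na⁺ 48/7 | +51.12 |
| Na⁺ 2/7 | −33.26 |
| K⁺ 2/100 | −103.88 |
| Ca²⁺ 1.8/0.1 | +38.37 |

### Chord-conductance selectivity

The chord model writes the current as I = g·Σᵢ fᵢ(V − Eᵢ) with fractional
conductances fᵢ summing to 1, so E_rev = Σ fᵢEᵢ. Three estimators follow
algebraically:

- `fraction_from_shift(erev_a, erev_b, e_a, e_b)` — the shift ratio
  ΔE_rev/ΔE_X when a substitution series moves one ion's equilibrium
  potential. Ratios outside [0, 1] (possible with measurement noise) are
  clamped with a warning; `clamp=False` returns the raw ratio.
- `two_ion_chord_fraction(erev, e_self, e_other)` — exact two-ion solution,
  used for bracketing an ion's fraction under extremal assumptions about
  the third ion.
- `remainder_bound(fractions)` — 1 − Σ known fractions, floored at 0 with a
  warning when measurement error pushes the sum past 1 (error > 0.25 is
  rejected as inconsistent).

`SelectivityModel.from_nd96_series({c_Na: erev}).fit()` packages the full
inference: equilibrium potentials from the solution recipes, per-condition
shift ratios, their mean as the Na⁺ point estimate, two-ion K⁺ brackets, and
the Ca²⁺ remainder bound, with a `summary()` that shows the provenance of
every number. The Ca²⁺ equilibrium potential is always computed from the
recipe (1.8/0.1 mM) because a recipe-consistent value is required for the
two-ion bracket arithmetic to be self-consistent.

Percentages are reported with `percent()`, which rounds half away from zero
— the convention matching the published selectivity figures.

## 2. Voltage-clamp analysis (`thermokit.tevc`)

### Reversal potentials

`iv_from_steps` reduces a step protocol to steady-state means per command
voltage; `estimate_reversal` linearly interpolates the zero crossing, flags
multiple crossings as ambiguous (returning the crossing nearest the median
command voltage), and raises when the I-V curve never crosses zero.

### Two-regime Q10 (`fit_q10`)

The channel model: zero conductance below an activation threshold
(default 14 °C), log-linear current in temperature with slope s_low up to a
breakpoint (default 20 °C), and slope s_high above it; Q10 = 10^(10·s).
The estimator:

1. **Baseline subtraction** — `baseline="auto"` uses the mean current below
   threshold − 0.5 °C.
2. **Adaptive pre-smoothing** — the raw noise σ is estimated from the
   residual of a width-5 moving average. Noiseless data (σ ≈ 0) is left
   unsmoothed, since smoothing would only add edge bias; otherwise a boxcar
   of 20 s (one ramp step at 2.5 °C/min) is applied and the half-window at
   each trace end is excluded.
3. **Noise-floor exclusion** — samples with |I| below 3σ/√width carry no
   log-domain information and are dropped.
4. **Breakpoint search (stage 1)** — a continuity-constrained hinge
   (segmented) regression over a 0.25 °C grid, requiring each limb to span
   ≥ 2 °C outside a ±1 °C gap around the candidate and to contain ≥ 10
   samples. The continuity constraint is what makes the breakpoint
   identifiable: an unconstrained two-independent-lines SSE objective is
   degenerate under log-domain heteroskedastic noise (log-noise variance
   grows as 1/signal², so SSE decreases monotonically as the breakpoint
   migrates toward the low-signal edge).
5. **Slope refit (stage 2)** — two independent weighted least-squares lines
   on the disjoint ranges [threshold + 0.5 °C, breakpoint − 1 °C] and
   [breakpoint + 1 °C, T_max], weighted by the squared normalized signal
   (one Gauss-Newton step of the maximum-likelihood exponential fit). The
   ±1 °C gap keeps breakpoint-curvature samples out of both slope
   estimates.

Measured properties (synthetic ramps, 10 → 35 °C at 2.5 °C/min):

- noiseless: slopes exact to < 1 %, breakpoint on-grid at 20.0 °C; a true
  single-regime trace is recovered to machine precision and flagged
  `single_regime`;
- 2 % of peak additive noise, 20 seeds: mean recovered Q10s within ~1 % of
  the generating 9.05/5.20;
- 5 % of peak noise: per-trace scatter of the low-regime Q10 approaches the
  single-trace maximum-likelihood bound (≈ 50 % sd), and because
  Q10 = 10^(10s) is convex in the slope, an arithmetic mean of per-seed
  Q10s acquires a Jensen inflation of up to ~12 %; the geometric mean
  (mean slope) stays within ~7 % across independent 20-seed sets. Users
  aggregating noisy Q10s should average slopes, not Q10s.

### Threshold and lag

`detect_threshold` finds where the smoothed |current| first sustainedly
exceeds a noise-derived floor, interpolated back to temperature.
`xcorr_lag` reports the lag of the normalized cross-correlation peak
between −current and temperature. Note that for a first-order channel
response to temperature square steps the correlation peak sits near
τ·ln 2, not τ: a 5 s channel time constant yields a ~3.2 s lag. The lag is
therefore a *comparative* statistic (slow vs fast kinetics), not a direct
time-constant estimator.

## 3. Calcium imaging (`thermokit.calcium`)

- `epoch_segments` finds low/high temperature epochs with a 10 s guard trim
  on both sides of each transition; it raises (naming the observed
  temperatures) when the trace never reaches the requested setpoints.
- `delta_f_over_f` computes (F_high − F_low)/F_low over the trimmed epochs.
- `morlet_cwt` uses the complex Morlet wavelet (pywt `cmor`, bandwidth 2.0,
  center frequency 0.9549) on the demeaned signal, with a cone of influence
  at √2·scale·√(B/2) samples from each edge; requests above Nyquist or
  traces shorter than a few cycles of the lowest frequency are rejected.
  The measured ridge error on a pure tone is well within one logarithmic
  frequency bin.
- `compare_groups` is the two-sided unpaired Welch t-test (scipy), with the
  degenerate identical-groups case defined as t = 0, p = 1. It matches a
  permutation test on the same data to within Monte-Carlo error.
- `classify_tonic` labels low-temperature activity tonic when the rate of
  suprathreshold events exceeds 0.2 /s. The threshold is anchored at the
  10th percentile of the low-epoch trace plus 3 noise standard deviations
  (noise from the median absolute first difference), and onsets are counted
  on a 0.2 s boxcar-smoothed trace. A median-anchored threshold was
  rejected: with dense tonic firing the median itself rides on the events
  and the classifier misses exactly the cells it must detect.

### Group-comparison power at the published summary parameters

Simulating ΔF/F groups from the published summaries
(n=21, −0.1524 ± 0.1358 vs n=20, 0.03656 ± 0.10) gives an expected Welch
statistic |t| ≈ 5.09 with ≈ 36 degrees of freedom — a median p of
1.0 × 10⁻⁵, i.e. *exactly at* the p < 10⁻⁵ boundary. The power of the
check "p < 10⁻⁵" is therefore ~50 % (measured 49–53 % over 1000-draw runs),
not ≥ 95 %. The corresponding acceptance check is retained unmodified and
fails honestly; it documents that the published summary statistics are
consistent with p ≈ 10⁻⁵ but cannot guarantee p < 10⁻⁵ with high
probability.

## 4. Behavior (`thermokit.behavior`)

- `detect_incapacitation` resamples position to a 1 s grid; second *i* is
  inactive when the position moved < 0.1 cm (≈ 3 % of the 3.4 cm chamber)
  over the preceding second. The fly is incapacitated when some 90 s window
  within the exposure accumulates ≥ 45 s of inactivity (cumulative default,
  contiguous option); the event time is the start of the earliest inactive
  run inside the first qualifying window, relative to exposure onset.
  Never-incapacitated flies are censored at the exposure duration.
  Recovery is the first 5 s of sustained movement after exposure end,
  censored at 1080 s (the recovery observation horizon) or trace end.
- `infer_exposure` returns the longest warm run as a half-open interval, so
  an exposure commanded for N seconds is inferred as N seconds long.
- `km_estimate` wraps the lifelines Kaplan-Meier fit, returning the step
  function with Greenwood variance and prepending S(0) = 1; it matches a
  brute-force product-limit computation exactly on datasets with ties and
  censoring. `logrank_test` wraps the lifelines log-rank test and matches
  the textbook O−E/V statistic.

## 5. Synthetic generators (`thermokit.synthetic`)

Defaults are the characterized channel's measured operating conditions, not
tuned values: threshold 14 °C, breakpoint 20 °C, Q10 9.05/5.20, fractional
conductances Na 0.55 / K 0.40 / Ca 0.05, ramp 2.5 °C per minute over
10–35 °C, heat-box exposure 90 s with recovery half-times rising steeply
with exposure temperature (log-interpolated through 20/162/383/760 s
half-time anchors at 34–40 °C).

Scope and limits:

- The TEVC generator has no voltage-dependent gating and no inactivation —
  a deliberate restriction matching the characterized channel; the two
  first-order time constants (bath actuator vs channel kinetics) let either
  lag hypothesis be emulated but recordings alone cannot distinguish them.
- The calcium generator is an inhomogeneous-Poisson event train convolved
  with a fast difference-of-exponentials kernel; it models rate changes,
  not amplitude adaptation or bleaching (a linear drift term is available).
- The fly-walk generator uses per-second logistic incapacitation hazards
  and temperature-dependent recovery hazards; walks are reflected Gaussian
  steps with pauses. It produces realistic censoring patterns but makes no
  claim about spatial behavior (no thermotaxis).
- Absolute current amplitude is arbitrary (g_max defaults to 1 µS); all
  analysis targets are normalized or ratio quantities.

All generators draw from a single seeded `numpy` generator per call,
record the seed in trace metadata, and are bit-reproducible; cohort
generators spawn independent child streams per fly.

## 6. Reproduction artifacts

`thermokit reproduce` (and `scripts/acceptance.py`) recompute ~29 headline
quantities: the Nernst and selectivity arithmetic, Q10/threshold/lag
recovery, plateau stability, the selectivity simulation round trip, CWT
ridge error, ΔF/F sign consistency, the group-comparison power, recovery
medians by temperature, and the channel-vs-control log-rank separation.
The check table passes except the power check discussed in §3.
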