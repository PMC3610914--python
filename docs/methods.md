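# Methods

This note documents the models and procedures implemented in `calcosc`,
the parameters that matter, and the design decisions taken where the
underlying experimental method is ambiguous.

## 1. The oscillation statistic

A recording is a per-neuron fluorescence series F(t) in arbitrary units,
uniformly sampled (default Δt = 1 s, matching 1 frame/s confocal XYT
scanning).  The statistic is deliberately simple — a semi-quantitative
threshold rule, not spike inference:

**Baseline.**  F₀(t) is the arithmetic mean of two running minima: the
minimum of F over the trailing window [t−w, t] and over the leading
window [t, t+w], w = 10 s, both inclusive of t and truncated at the trace
edges.  The phrase "mean of the minimum values ±10 s of t" admits a
second reading — the mean of the k smallest samples in the full ±10 s
window — which we deliberately did *not* implement; the two-sided-minima
reading matches the plural ("values") with the two sides of ±.  The
alternative would produce a slightly higher baseline and lower ratios and
must not be substituted silently; it remains an open question of the
method.  Edge truncation (use whatever samples exist) was chosen over
discarding 10 s per edge, which would bias frequency downward in 2-minute
analysis windows.

**Normalization.**  The ratio F/F₀ is dimensionless and exactly invariant
under rescaling of the raw trace by any positive constant — detector gain
cannot affect any downstream result (property-tested).

**Events.**  Each maximal run of samples with F/F₀ strictly above 1.2
(strict, per the defining inequality) is one calcium oscillation.  At
1 Hz sampling a single-sample dip below threshold would otherwise split
one transient into two, so two runs separated by a sub-threshold gap
shorter than `min_gap` (default 2 s) are merged.  The event's amplitude
is its maximum ratio; ties are broken toward the earliest sample
(`argmax`).

**Summaries.**  frequency = n_events / duration (Hz); amplitude = the
arithmetic mean of event peak ratios.  A trace with no events has
frequency 0 and *missing* amplitude (`NA` in outputs); such traces are
excluded pairwise from amplitude statistics, since "amplitude of no
events" has no value.  Group summaries report mean ± SD across neurons
(SD, not SEM — outputs are labelled accordingly; a single neuron yields
SD `NA`).

## 2. Statistical comparisons

The experimental design is within-neuron: 120 s pre-drug window, 60 s
wash-in (excluded), 120 s post-drug window.

- **Frequency**: Wilcoxon signed-rank on (post − pre).  Zero differences
  are dropped (Wilcoxon's original rule) and counted in the result.  For
  n ≤ 25 retained pairs the p-value is computed from the *exact
  conditional* null distribution — a dynamic program over all 2ⁿ sign
  assignments of the observed average ranks.  This matters because
  frequencies are event counts: ties in |difference| are the norm, and
  the tabulated no-tie distribution (what common libraries call "exact")
  is then only approximate.  Above n = 25 the normal approximation is
  used.  Two-sided p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped at 1.
- **Amplitude**: paired t-test on (post − pre) with n − 1 df after
  pairwise deletion of missing amplitudes; fewer than 2 complete pairs is
  an explicit error.  A non-zero mean difference with exactly zero spread
  is degenerate and reported as p = 0 with a warning flag.
- **Dose ladders**: Friedman chi-square over ≥ 3 conditions measured on
  the same neurons (complete blocks), average ranks for ties.  A matrix
  whose rows are all completely tied carries no rank information and is
  reported as statistic 0, p = 1 with a warning.
- All tests are two-sided; no multiple-testing correction is applied
  across a dose ladder (per-dose flags are reported as in the underlying
  experimental design).  This is a known limitation, not an oversight.

## 3. The synthetic recording model

Each simulated neuron is

F(t) = f_base·(1 + a·sin(2πt/T + φ)) + Σ_k p_k·g(t − t_k) + ε(t),

clipped below at a small positive floor, with

- **Transient kernel** g: double exponential,
  g(s) ∝ (1 − e^(−s/τᵣ))·e^(−s/τ_d), normalized so its continuous
  maximum is 1; τᵣ = 2 s, τ_d = 6 s.  Standard indicator kinetics; the
  kernel peaks at τᵣ·ln(1 + τ_d/τᵣ) ≈ 2.8 s after onset and is zero at
  onset.
- **Event process**: homogeneous Poisson candidates thinned by a dead
  time (refractory 15 s): spontaneous oscillations are quasi-periodic,
  and at ~0.04 Hz a pure Poisson process would produce unrealistic
  pile-ups that the ±10 s baseline could not separate.  Inter-event
  statistics beyond this cannot be constrained by the available
  descriptions; a renewal process is the minimal choice.
- **Stationarity**: the pre-drug process is sampled from a 30 s burn-in
  (≈ 5 decay constants) before the recording starts, so transients
  already in progress at t = 0 contribute their tails exactly as ongoing
  activity does at every later window boundary.  Without this the first
  analysis window is systematically poorer in events than the second,
  which a paired test happily "detects" under the null.
- **Drift**: slow multiplicative sinusoid (default 3 % of f_base, period
  150 s) with an independent uniform random phase per neuron.  A phase
  common to all neurons would be a coherent pre-vs-post artifact that the
  paired t-test flags under the null (observed rejection ≈ 40 % before
  this choice; ≈ 4 % after, at the nominal 5 %).
- **Noise**: additive Gaussian, default 2 % of f_base — keeps baseline
  F/F₀ fluctuations far below the 1.2 threshold (false events from noise
  alone are practically impossible at this SNR).
- **Seeding**: one master seed per experiment; per-neuron streams derive
  from `SeedSequence(entropy=(seed, neuron_index))` with four children
  (pre onsets, post onsets, noise, drift phase).  Every output is a pure
  function of (preset, protocol, seed); identical commands give
  byte-identical tables.

## 4. Calibration of the baseline condition

The undrugged preset (`baseline_d5`) is defined by what the *pipeline*
should measure on it: mean frequency 0.042 Hz and mean amplitude 2.01
F/F₀.  Analytic initializers get close:

- candidate rate λ = μ/(1 − μ·r) inverts the non-paralyzable dead-time
  relation (μ = 0.042 Hz, r = 15 s → λ ≈ 0.114 Hz);
- `calibrate_peak` bisects the kernel peak so one noiseless, drift-free
  transient is detected at exactly the target amplitude (the ±10 s
  minimum baseline partially tracks the transient, so the detected ratio
  is not 1 + p/f_base; for amplitude 2.01 at f_base = 100 the required
  peak is ≈ 134, not 101).

Measured through the full simulate → split-phases → analyze pipeline,
however, both metrics deviate by a few percent: analysis windows gain
events whose onset precedes the window but whose peak falls inside it
(≈ +5 % frequency); the running-minimum baseline rides on neighbouring
transient tails (≈ −2 % amplitude at a 24 s mean interval); and
edge-truncated events are detected with reduced peaks (≈ −1 %).  Each
target is therefore refined against a fixed-seed reference cohort of 600
neurons measured through the exact pipeline: bracketing bisection on the
rate (detected counts are integers, so the residual is a fine step
function on which secant iteration can stall), then secant iteration on
the peak under the calibrated rate's crowding statistics.  The
calibration is deterministic, runs once at preset load (~3 s, cached per
process), and its residual generalization error across independent seeds
is ≈ ±0.001 Hz and ≈ ±0.005 F/F₀ — an order of magnitude inside the
reported dispersions (±0.006 Hz, ±0.07).

## 5. Drug model

Pharmacology is phenomenological: each drug action is a Hill multiplier
m(c) = 1 ∓ E·cʰ/(c₅₀ʰ + cʰ) applied to the event rate, the transient
peak, or both; multiple drugs compose multiplicatively.  Parameters were
chosen once, by desk calculation, to reproduce the qualitative orderings
of the modelled experiments and are shipped in `presets.cfg`:

| action           | target     | c₅₀ (µM) | h   | E    | direction  |
|------------------|------------|----------|-----|------|------------|
| ketamine (peak)  | peak_df    | 100      | 1.5 | 0.70 | inhibit    |
| ketamine (rate)  | event_rate | 300      | 2   | 1.00 | inhibit    |
| MK-801           | both       | 10       | 1   | 0.80 | inhibit    |
| NMDA (peak)      | peak_df    | 150      | 2   | 2.50 | potentiate |
| NMDA (rate)      | event_rate | 600      | 3   | 16   | potentiate |

The split into separate peak and rate actions with different midpoints
and slopes encodes the observed dissociations: ketamine depresses
amplitude from ~30 µM but frequency only from ~300 µM; NMDA at 100 µM
raises amplitude with no significant frequency change, while its steep
high-concentration rate action lets 1 mM NMDA overcome the ≈ 12-fold
rate suppression of 1 mM ketamine (0.0826 × 14.2 ≈ 1.17, i.e. slightly
*above* the pre-drug level, as required for full reversal).  The
ketamine-peak ceiling E = 0.70 keeps residual events detectable
(amplitude ≈ 1.36 > 1.2) up to 1 mM.  Complete abolition at 3 mM cannot
be produced by any bounded Hill multiplier, so that preset carries an
explicit `rate_override = 0`.

## 6. What the generator does and does not emulate

It emulates: sparse quasi-periodic transients at realistic rate and size,
baseline drift, shot-like noise, truncation of ongoing activity at
recording and window boundaries, dose-dependent multiplicative drug
action, and paired pre/post designs with a discarded wash-in.

It does not emulate: biophysical Ca²⁺ handling (receptor kinetics, ER/
mitochondrial exchange), bursting or network-correlated activity across
neurons, amplitude variability between events of one neuron beyond what
baseline interactions induce, indicator saturation or photobleaching
trends, motion artifacts, or ROI segmentation errors.  Passing tests
therefore validate the *analysis pipeline* and the *statistical
machinery* under controlled conditions; they do not certify performance
on real recordings with correlated noise or non-stationary kinetics.

## 7. Numerical and format choices

- Baseline windows are converted to samples by rounding w/Δt; a
  half-window below one sample is rejected.
- Uniform sampling is validated on read to 10⁻⁶ s; violations are
  reported with file line numbers.
- Floats are written with 6 significant digits; `NA` is the only
  missing-value token.
- `calibrate_peak` tolerance is 10⁻³ in amplitude; unreachable targets
  (≤ threshold, or beyond the baseline-tracking ceiling of ≈ 8 F/F₀)
  raise.
- Traces must be finite and strictly positive; violations name the
  offending sample.

## 8. Problem sizes used by the test-suite

Cohort checks use 15 neurons × 300 s recordings, the scale of one
perfusion experiment: calibration recovery over 10 master seeds,
direction-of-effect over 50 simulated experiments per condition,
complete-abolition over 50 seeds, and the null type-I error over 400
experiments (bounded by 5 % + 3 binomial SE).  Oracle suites cover the
baseline against a naive double-loop on 100 random traces, the exact
Wilcoxon against full sign enumeration (all patterns at n = 5 and 10,
plus tied-rank spot checks), and the Friedman statistic against a
hand-ranked example.
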