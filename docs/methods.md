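# Methods

This note documents the models, conventions and numerical choices behind
`nnrf`, what the synthetic-data generator does and does not emulate, and
the known limitations of the measurement procedure.

## The measurement model

A single trial is modelled as

    x(t) = β · w(t − s) + ε(t),       |s| ≤ 100 ms,

where *w* is the fixed n-NRF template, *β* the trial's response magnitude,
*s* its latency shift, and *ε* background EEG.  The estimator is a
two-step plug-in:

1. **Woody alignment** searches integer-sample shifts
   *s ∈ [−100, +100] ms* exhaustively and maximises the Pearson
   correlation between the template and the epoch segment on the
   half-open fit window [400, 700) ms.  Correlation (scale-invariant) is
   the default criterion; a raw-covariance criterion is available
   (`WoodyConfig.criterion`).  Ties are broken towards the smallest
   |shift|, then the negative one — implemented by searching in the order
   0, −1, +1, −2, +2, … and keeping the first strict maximum.
2. **Projection** is least squares without intercept on the aligned
   segment: β̂ = ⟨x_ŝ, w⟩ / ⟨w, w⟩.  No intercept is fitted because epochs
   are baseline-corrected first; adding any component orthogonal to the
   template leaves β̂ unchanged.

A template derived from reference data (`derive_template`) is the
iterative Woody average: start from the plain fit-window average,
re-align every epoch to the current template, re-average, and repeat
until the maximum sample change falls below 1e-8 of the template RMS (at
most 20 iterations; non-convergence is flagged on the result, which is
still returned).  The final template is rescaled so that the mean
projection magnitude over the reference epochs is exactly 1.0; the factor
is stored as `norm_constant` so externally supplied templates can be used
unnormalised knowingly.

### Latency resolution and the selection bias of the search

Two structural properties of this estimator matter when interpreting
results, and both are pinned down by tests:

- **Latency resolution.**  The template is band-limited to roughly 30 Hz,
  so its autocorrelation is flat at the millisecond scale: the correlation
  gap between adjacent 1 ms shifts is ~1e-4.  Sample-exact shift recovery
  therefore requires very high SNR (empirically, exact recovery across the
  full ±100 ms range needs an in-window amplitude SNR near 100; at SNR 5
  the latency error is a few milliseconds, bounded by ~8 ms in the suite).
  This is a property of any smooth evoked waveform, not of the search.
- **Magnitude inflation for weak responses.**  Because the search picks
  the best-correlating shift, for trials whose evoked content is small
  relative to background EEG it partially aligns to noise, inflating the
  magnitude (≈ +0.2 on the dimensionless scale for control-strength
  responses at 10 µV RMS background).  With the search disabled the
  projection is unbiased; strong (noxious-strength) responses anchor the
  alignment and are recovered without practical bias.  Group means of weak
  control responses should therefore be read as upper bounds.  Note that
  empirically reported control-response means produced by the same
  procedure embed the same effect, so comparisons between studies using
  the identical pipeline remain like-for-like.
- **Sign consistency.**  Correlation-maximising alignment assumes the
  response has the template's polarity; trials with genuinely negative
  magnitudes are aligned to whatever shift correlates positively and are
  not recovered at their generative value.  Exactness tests therefore use
  cohorts whose true magnitudes are all positive.

## Preprocessing conventions

- **Resampling** is polyphase rational-ratio resampling with anti-alias
  filtering; output length is ⌈n·to/from⌉ and equal rates are an identity.
- **FIR design**: one Hamming-windowed sinc band-pass covering both
  cutoffs (−6 dB points at 0.5 and 33.75 Hz), with the tap count from the
  Hamming rule order ≈ 3.3/(Δf/fs) using the smaller transition bandwidth
  (1 Hz), rounded up to an odd, type-I length.  The optional 50 Hz notch
  is a separate band-stop stage.  Filters are applied in a single
  linear-phase pass with group-delay compensation (odd symmetric taps,
  `same` convolution), so the output is zero-phase; the contract is the
  gain at the −6 dB points, not a specific order.  Filtering applies to
  continuous records; pre-cut 2 s epochs are shorter than the filter and
  are treated as already filtered (the synthetic generator produces
  band-limited noise for exactly this reason, below).
- **Epoching** uses a half-open window [−pre, +post) so a (−500, +1000) ms
  window at 2000 Hz has exactly 3000 samples with sample 1000 at t = 0;
  annotations that do not leave room raise an error naming the annotation.
- **Baseline correction** subtracts the mean of all samples with t < 0.
- **Rejection** is assessed on filtered, baseline-corrected epochs over
  −500…+1000 ms with strict inequalities: reason `amplitude` when any
  |sample| > 150 µV (a sample at exactly 150 µV is retained), reason
  `baseline_range` when the pre-stimulus max−min exceeds 100 µV; amplitude
  takes precedence when both apply.  Rejection only sets flags — every
  epoch stays accounted for — and re-application is idempotent.  Visual
  artifact screening is inherently manual and is honoured as pre-set
  `manual` flags rather than automated.

## Outcome-neutral cluster permutation test

Per timepoint, a paired t across participants of (post − pre); samples
with |t| above the 97.5th percentile of t(n−1) form clusters as maximal
runs of contiguous same-sign suprathreshold samples (two-sided forming
threshold, sign-pure clusters, since both polarities are of interest).
The null flips each participant's (pre, post) assignment independently
(sign-flip of the difference; sums of squares are flip-invariant, which
makes the permutation fully vectorisable) and records the maximum
absolute cluster mass per permutation — one null for both signs, which
controls the family-wise error across clusters.  p-values carry the +1
correction, p = (1 + #{null ≥ |mass|})/(1 + B), so no p is exactly zero;
a relative tolerance of 1e-12 on the comparison keeps exact permutation
ties (e.g. the identity pattern) counted despite float round-off.  The
pre-stimulus window is paired to the post-stimulus window by index offset,
not time-reversed.

## Replication statistics

- **Discrimination**: paired one-tailed t (lance > control), pairs matched
  by participant id, participants missing either stimulus dropped with a
  reported count; the two-sided 95% CI of the mean difference is reported
  alongside the one-sided p.
- **Equivalence**: the mean magnitude with a 90% BCa bootstrap CI
  (bias-correction z₀ from the fraction of bootstrap statistics below the
  observed value, acceleration from the jackknife skewness formula;
  degenerate data returns a point interval).  The verdict is `equivalent`
  only when the entire CI lies inside (0.8, 1.2); otherwise equivalence is
  `not demonstrated` — never "non-equivalent".
- **Age correlation**: magnitude and PMA are residualised on site
  indicator variables (least squares with intercept); the Pearson R of
  the residuals is tested one-sided with df = n − 2 − (#indicators).  The
  bootstrap resamples participants (not residuals, not trials) and the
  interval is reported one-sided as [5th-type percentile, 1.0]; the
  percentile method is the default with BCa available as a switch.
  Residual norms at numerical-noise scale are treated as exact
  confound absorption (partial R = 0).
- **Gating**: the age-correlation analysis runs only when the
  discrimination test confirms (p < .05) — without discrimination there is
  no basis to interpret the magnitude as noxious-evoked activity.  The
  pipeline records the gate decision in its manifest.

## Meta-analysis and planning

Inverse-variance pooling uses SE = sd/√n per site.  Common-effects weights
1/SE²; Q = Σwᵢ(xᵢ−x̄)² with a chi-squared test on k−1 df;
I² = max(0, (Q−df)/Q).  τ² is REML via the standard fixed-point iteration
on the score equation (DerSimonian–Laird start, non-negativity projection,
tolerance 1e-10, ≤100 iterations; cross-checked against an independent
REML implementation in the suite).  The random-effects CI applies the
Knapp–Hartung scaling q = Σwᵢ*(xᵢ−x̄*)²/(k−1) with a t(k−1) quantile; q is
floored at 1 by default (`kh_floor=False` gives the unfloored variant).
A site with sd = 0 has infinite weight and is rejected by name; k = 1
returns the site's own mean flagged degenerate.

Sample-size solvers return the smallest n whose criterion holds (and
fails at n−1, verified by tests): noncentral-t power for the paired
design; exact power for the Pearson correlation by numerically integrating
the exact sampling density of r under bivariate normality beyond the null
critical value (Fisher-z mode as a cross-check); AIPE solves the expected
full CI width 2·t·sd/√n ≤ target (with an optional assurance quantile on
the sd); TOST equivalence power is computed exactly by integrating over
the sampling distribution of s the probability that the sample mean lands
inside both one-sided rejection regions.  Recruitment inflation is a pure
ceiling of n·(1+fraction) with a 1e-9 float guard; protocols that round
further up to convenient recruitment figures are not modelled.

## The synthetic generator

Each trial draws a magnitude from a Normal distribution — Normal rather
than lognormal to match the use of t-tests and mean±sd summaries, with
negative draws permitted (projections can be negative in noise) — with a
per-site lance mean, a control mean, and separate lance/control sds (the
control sd defaults to the lance sd but the presets use values implied by
reported control CIs).  Below 37.0 weeks PMA the lance mean increases
linearly with PMA at the configured slope (default 0.1/week, which
produces site-adjusted age correlations around 0.2–0.4 at realistic
noise).  Latency shifts are uniform on ±100 ms, quantised to the sampling
grid so that noise-free trials are reconstructed exactly.  Background EEG
is Gaussian with PSD ∝ 1/f^α (α default 1.0), band-limited to 0.5–30 Hz —
the generator emulates *filtered* data, since the epoch-level pipeline
path does not re-filter — and scaled to a configurable RMS (default
20 µV).  Artifacts are ±400 µV raised-cosine deflections at random times
with the configured per-epoch probability.  The canonical template is a
deterministic difference of two raised-cosine lobes with its negative
extremum at 385 ms and positive extremum at 645 ms, zero outside
[300, 770] ms, defined in closed form so sampling at any rate ≥ 250 Hz is
consistent.

What the generator does **not** emulate: sleep-state structure and burst
suppression, genuinely distinct control-response morphology (the control
arm is a scaled-down copy of the same template, so control-condition
evoked activity is weaker than in real recordings), multi-channel
structure, ECG, or non-stationary noise.  Passing tests therefore show
that the pipeline recovers the structure this model encodes — they do not
certify performance on real neonatal EEG.

## Problem sizes and defaults in the suite

The test suite and demo run at a 500 Hz working rate (1000 Hz for
millisecond-grid latency tests), with cohorts of 8–200 participants,
1,000–4,000 permutations and 2,000–8,000 bootstrap resamples; the package
defaults follow the study conventions (2000 Hz, 10,000 permutations and
resamples).  The demo configuration pools two sites with 135 participants
at 10 µV RMS background — the scale at which both stimulus conditions
carry detectable evoked activity through the outcome-neutral gate — while
the generator's own defaults stay at 20 µV.

## Known limitations

- Magnitudes of weak responses are inflated by the latency search (above);
  the package reports what the procedure measures, not a deconvolved
  "true" amplitude.
- Millisecond-exact latency recovery is not achievable at moderate SNR for
  band-limited waveforms; treat per-trial shifts as ±few-ms estimates.
- The cluster permutation p is Monte-Carlo (exact only in the limit of all
  2ⁿ sign patterns); with the +1 correction it is conservative by ~1/B.
- The equivalence verdict depends on the bootstrap CI, which for very
  small n (< ~20) can undercover; the planning tools (AIPE, TOST) exist
  precisely to size such studies properly.
- EDF ingestion is out of scope; continuous data enter via arrays or the
  columnar TSV epoch format.
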