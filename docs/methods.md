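# Methods

This note documents the statistical procedures the package implements, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions that were genuinely open.

## Quantal mortality and the trimmed Spearman–Kärber estimator

The substrate is a series of exposure groups (dose in nM, or observation
time in hr at a fixed dose) with exposed and dead counts.  Replicate wells
at one concentration are pooled by summing counts before estimation: under
the binomial sampling model they are one group, and the estimator has no
use for the split.  All estimation happens on log10 of the axis values;
results are reported back-transformed (nM / hr).

**Monotone smoothing.** Observed dead fractions need not be monotone in
dose; the estimator first replaces them with the weighted least-squares
monotone (non-decreasing) fit, computed by pool-adjacent-violators with
group sizes as weights.  PAVA is written in-house (a left-to-right block
stack with weighted-mean merging) because it is the first stage of the
estimator under test; it is verified in the test suite against both an
exhaustive search over contiguous-block partitions and
`scipy.optimize.isotonic_regression`.

**Trimming.** With trim fraction α, the points where the smoothed curve
crosses α and 1−α are located by linear interpolation on the (x, p)
polyline (for a flat run exactly at the level, the lower crossing takes the
end of the run and the upper crossing its start) and become new endpoints;
the retained response is rescaled to p′ = (p − α)/(1 − 2α).  The default is
α = 0 — the untrimmed estimator — because the published use of the method
invokes trimming without stating a level, and α = 0 keeps results exactly
reproducible; the trim machinery is fully exercised in tests and available
via `--trim`.

**Median and variance.** The log10 median is
m = Σ (pᵢ₊₁ − pᵢ)(xᵢ + xᵢ₊₁)/2, which equals x_last − ∫p dx (trapezoid) by
summation by parts — that identity is the estimator's oracle test.  The
variance is the classic binomial delta-method form
V = Σ_interior pᵢ(1−pᵢ)(xᵢ₊₁ − xᵢ₋₁)²/(4(nᵢ − 1)); terminal groups have
p(1−p) = 0 in estimable cases and drop out.  Confidence bounds are normal
quantiles on the log scale, back-transformed.  Interior groups need nᵢ ≥ 2;
a singleton interior group makes the variance undefined and is an error.

**Bracketing and the extension rule.** A curve that never reaches 0% or
100% after smoothing cannot bracket the median.  By default such series are
reported *not estimable* (serialised with a null point and a reason) rather
than extrapolated — extrapolation invents mass outside the tested range.
The conventional remedy, appending a 0% group one mean log-step below the
lowest dose and a 100% group one step above the highest, is available as an
explicit flag (`RunConfig.extend`).  The parameter-recovery simulations in
the acceptance tests run with the extension enabled: at 20 animals per
group a sampled curve frequently misses an exact 0/20 or 20/20 at the
extremes even when the design brackets the true median comfortably, and the
recovery experiment requires an estimate from every replicate.  The
extension enters symmetric designs symmetrically, so it leaves the median
nearly unbiased there (observed median error ≈ 1% at the simulated design;
empirical 95%-CI coverage ≈ 94%).

**LT50.** Median lethal time uses the identical algorithm on log10 time,
with groups formed as cumulative dead counts at increasing observation
times for one fixed dose.  Cumulative construction is monotone up to
recovery/scoring noise; violations are pooled by the same PAVA step.

## Morphology scores

Scores live on the ordinal 1–10 Wilby scale; the package treats the scoring
itself as an input and never re-defines the visual criteria.  Death is a
score strictly below a threshold (default 4), evaluated per observation
time — death is deliberately not latched across times, because the assay
design allows recovery.  Cell summaries use the sample median (midpoint
convention for even n).

The Friedman test operates on a complete blocks × treatments design of
cell medians; the default blocking is observation times with concentrations
as treatments.  Within-block ties get mid-ranks and the tie-corrected
statistic χ² = (k−1)Σ(Rⱼ − b(k+1)/2)² / (Σr² − bk(k+1)²/4), which reduces
to the classic 12/(bk(k+1))·ΣRⱼ² − 3b(k+1) without ties and is defined as 0
for a fully tied panel.  The p-value comes from χ² with k−1 df; for designs
with b·k ≤ 12 an exact permutation p-value (enumeration of all (k!)ᵇ
within-block orderings) is returned alongside.  The chi-square
approximation tracks the exact distribution's mid-p within ~0.03 at b = 6,
k = 3; the plain exact p differs more at large p because the discrete
distribution has sizeable atoms — an expected feature, not an error.

## Tentacle regeneration index

TRI(j, t) = Σₖ pₖ nₖʲ(t) / n_max over the five length classes.  The class
weights pₖ default to the class lengths (1/8, 1/4, 1/2, 3/4, 1): the index
is then exactly the average relative tentacle length per polyp, which is
the quantity the assay describes (1 when eight full tentacles have
regrown).  The weights are configurable for sensitivity analysis.  n_max
= 8 is the physiological maximum, not an algebraic bound: a supernumerary
polyp yields TRI > 1 with a warning, never clamped.  Length-class binning
takes the nearest nominal class, with exact midpoints assigned to the lower
class.

Group means (typically N = 4 polyps) carry sample SD and n.  Treatment
comparisons are unpaired two-sample t-tests, pooled-variance by default
(Welch by flag; the two coincide for balanced equal-variance groups).  Two
identical zero-variance groups return t = 0, p = 1 by convention.
Day-by-day comparisons across the 14-day profile report both raw and
Holm-adjusted p-values and take no position on which to act on, since the
assay tradition reports per-day tests without a stated multiplicity
correction.

## Population growth

ln(n/n₀) = k·t with n₀ the day-0 founder count, so y(0) = 0 exactly.  The
default fit is through the origin (k = Σty/Σt²) because the model has no
intercept; a free-intercept fit is available as a diagnostic (it needs ≥ 3
distinct days).  R² is uncentered for through-origin fits.  T₂ = ln2/k is
computed analytically from k rather than read off the fitted line at
y = ln 2 — equivalent under the model and deterministic; k ≤ 0 flags the
fit non-growing with T₂ undefined (null).

Slope equality between two conditions is the interaction F-test of the
pooled regression with a group indicator (the standard ANCOVA
slope-heterogeneity test): F = (SSE_common − SSE_separate)/(SSE_separate/df)
with 1 numerator df.  Degenerate noiseless inputs are handled explicitly:
identical series give F = 0, p = 1; distinct exact slopes give the p → 0
bound.  Replicate populations are fitted per replicate and pooled for the
comparison; both per-replicate and pooled summaries are emitted.

## Synthetic data generator

Every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`.

* **Tolerance model** (dose-only mortality): p(d) = 1/(1 + (LC50/d)^h)
  (log-logistic; probit optional).  The log-logistic default is a
  convenience, not a commitment — Spearman–Kärber is distribution-free —
  and has closed-form median = LC50 for recovery tests.
* **Hazard model** (joint dose–time): each animal draws a log-logistic
  lifetime with median LT50_ref·(d/d_ref)^(−γ) and shape β.  Its implied
  LC50 at observation time t is d_ref·(LT50_ref/t)^(1/γ), so LC50 falls
  with time and LT50 falls with dose by construction — the qualitative
  pattern the assay exhibits.  Dose- and time-marginals are computed from
  the same lifetimes, hence mutually consistent.
* **Scores** are a deterministic monotone map of the remaining-life
  fraction (alive: 4–10; dead: 1–3) plus one-step ordinal observation
  noise clipped within the alive/dead band.  Clipping is what makes the
  score < 4 rule reproduce the latent death sets *exactly*, mirroring an
  assay in which mortality is itself read off the scores; the price is
  that the generator never produces a scoring error across the death
  boundary, so it cannot probe misclassification robustness.
* **Regeneration**: per-tentacle emergence times are cumulative
  exponential spacings with mean delay_factor/emergence_rate; relative
  length then grows as the shifted logistic 2/(1+e^(−g·Δt)) − 1 and is
  binned by the length classifier.  Defaults (emergence 2.5/day, g =
  0.8/day) give a control group that completes regeneration within ~10–14
  days, matching the assay's observation window.  Treated-vs-control
  Monte-Carlo checks pair the arms on a common seed (common random
  numbers): delay_factor = 1 then reproduces the control exactly, and the
  paired design isolates the treatment effect from emergence noise.
* **Budding**: a Yule birth process (per-capita rate k, exponential
  waiting times) from n₀ = 4 founders, mean n₀e^(kt); or a deterministic
  rounded exponential.  Realistic rates: control k = 0.25/day (T₂ ≈ 2.8
  days, a well-fed culture), treated k below that.

**Scenario calibration.**  The two packaged scenarios anchor the hazard
model to the published reference points of each chemistry: the TGA
scenario sets (d_ref = 300 nM, LT50_ref = 36 hr) and solves the dose
exponent (γ = 1.0319) so the implied 72-hr LC50 equals 153.24 nM; the GSH
scenario sets (500 nM, 63 hr) and γ = 0.9478 for an implied 72-hr LC50 of
434.29 nM (its implied LT50 at 1000 nM, ≈ 32.7 hr, then falls out close to
the published 32 hr).  The single-median-per-dose hazard cannot also match
the published 24-hr LC50 exactly (it implies ≈ 444 nM for TGA); the
scenarios are calibrated to the 72-hr medians and are meant for
qualitative, ordering-level reproduction, which is what the end-to-end
acceptance test asserts.  Lifetime shape β = 6, the score-noise law, and
the regeneration/budding parameters are not constrained by any published
number and were fixed once at field-realistic values (above).

**What passing tests show.**  The generator emulates binomial group
sampling, a monotone smooth tolerance/hazard structure, and
lifetime-consistent scoring.  It does not emulate between-experiment
heterogeneity, scoring disagreement between observers, partial mortality
recording (missing animals), or toxicokinetics (uptake, ion release).
Recovery and coverage results therefore validate the estimators under
their own sampling assumptions, not the field behaviour of real assays.

## Problem sizes

Simulation-backed checks use: 500 replicate assays of 6 doses × 20 animals
for LC50 recovery and CI coverage; 200 cohorts of 20 animals × 5 times for
LT50 recovery; 500 null replicates for the growth F-test error rate; 200
paired runs for the regeneration ordering; 200 full-pipeline runs (9 doses
× 3 times × 20 animals per arm) for the scenario-level orderings; 1000
random curves for the median identity and 500 for PAVA-vs-exhaustive.
These sizes put Monte-Carlo noise well inside the asserted tolerances
while keeping the whole suite to a few seconds.

## Known limitations

* The delta-method CI is asymptotic; at very steep curves (one interior
  group) it degenerates toward zero width.
* Not-estimable outcomes are a reportable state, not an imputation; users
  who need an estimate from a non-bracketing curve must opt into the
  extension rule and accept its convention.
* The Friedman exact enumeration is limited to b·k ≤ 12 (beyond that the
  (k!)ᵇ product explodes); larger designs rely on the chi-square
  approximation.
* TRI weights equal to class lengths are a modelling identification, made
  configurable precisely because the index's defining formula leaves the
  weights implicit.
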