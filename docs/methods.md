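# Methods

This note documents the statistical procedures implemented in
`progmetrics`, the assumptions behind the synthetic-data generator, the
numerical choices, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Metric taxonomy

Thirty built-in summary metrics form the coordinate system of the
pipeline: 7 cpRNFL sectors from the 3.5-mm circle scan (`G_small`,
`T_small`, `TI_small`, `TS_small`, `N_small`, `NI_small`, `NS_small`),
7 BMO-MRW sectors (`*_MRW`), 7 macular GCL regions (`G_GCL`, `I_GCL`,
`TI_GCL`, `NI_GCL`, `S_GCL`, `TS_GCL`, `NS_GCL`), 5 indices of the 24-2
visual field (`MD_24`, `supMD_24`, `infMD_24`, `PSD_24`, `VFI_24`) and 4
of the 10-2 (`MD_10`, `supMD_10`, `infMD_10`, `PSD_10`). Thicknesses are
in µm, MD/PSD in dB, VFI in %.

Each metric carries a **direction of worsening**. All thickness metrics,
MD, hemifield MD and VFI fall with damage; PSD rises with localized
damage. All classifiers operate on the worsening tail. Applying a lower-
tail threshold or a "significantly negative slope" criterion to PSD would
test the wrong tail, so the honest default flips the tail for PSD; a
`paper_literal` switch forces the lower/negative tail for every metric
for strict replication of a uniform lower-tail convention.

## Visual-field quality filter

VF values (only) are removed from any visit with a false-positive response
rate above 15% or a fixation-loss rate above 33%. Both comparisons are
strict, so a visit at exactly 15% / 33% is kept. The filter is idempotent
and logs (eye, date, rule) for every exclusion.

## Test–retest variability thresholds

Short-term repeat tests within a 120-day window are assumed free of true
change. For each metric, the first in-window test of each eye is the
independent variable and every later in-window test contributes one
dependent observation. We chose first-vs-each-later pairing (not
consecutive or all ordered pairs) because the baseline test is the natural
anchor of a short-term series and it matches the independent/dependent
role assignment of the threshold-estimation design.

The τ-quantile line is fitted by minimizing the pinball loss
`ρ_τ(u) = u·(τ − 1[u<0])`, cast as a linear program (residual split into
positive and negative parts) and solved exactly with HiGHS via
`scipy.optimize.linprog`. An LP solution is a global minimizer of this
convex problem; the test suite cross-checks it against both a brute-force
grid search and an independent iteratively-reweighted implementation
(statsmodels `QuantReg`). For increase-worsening metrics the line is
fitted at probability 1 − τ. Numerical edge cases:

* fewer than 20 pairs (configurable floor) is an error — a 2.5th-percentile
  line from a handful of points is meaningless;
* zero baseline variance degenerates to an intercept-only empirical
  quantile with a warning;
* fitted lines for nested τ levels are checked for crossing inside the
  observed baseline range, with a logged warning if they cross (flags at
  the stricter level are then no longer guaranteed to nest).

All eyes are pooled per metric — a single cutoff line per metric, no
per-eye effects and no covariates (no age adjustment; thickness metrics
are deliberately analyzed unadjusted).

## Event classification

Eligibility per metric: at least two non-missing tests with the last
365 days or more after the first. The baseline is the first non-missing
test *of that metric* (so an eye can be eligible for OCT metrics while
ineligible for a VF metric), the comparison value is the last. The eye
progresses when the last value lies strictly beyond
`intercept + slope × baseline`; equality is stable, since a variability
threshold must be exceeded. A `second_vs_last` confirmation variant uses
the second baseline test instead and returns *undetermined* with fewer
than three tests.

## Trend classification

Eligibility per metric: at least four non-missing tests spanning at least
a year. The metric is regressed on time in 365.25-day years from the
first test by closed-form OLS; the slope's standard error uses the
classical residual-variance formula with n − 2 degrees of freedom, and the
one-tailed p-value is the Student-t tail probability in the worsening
direction. Linearity is assumed for all metrics, including PSD and VFI,
for which it is only an approximation over short series. A perfect
(zero-residual) fit is flagged degenerate with p set to 0, 0.5 or 1 by
the slope's sign. Classification is strict: progressing iff the slope
worsens and p < α.

## Composite rules

Rules are AND/OR trees over metric leaves, written in a grammar where AND
binds tighter than OR. Evaluation uses Kleene three-valued logic with
*undetermined*/*ineligible* as the unknown value: AND is false if any
component is false (a stable component settles the conjunction even when
another is unknown), OR is true if any component is true. An unknown
result surfaces as *undetermined*. This conservative propagation was a
design choice — the alternative, treating missing components as stable, is
available via `missing_as_stable`. Built-ins cover the named composites
(`InferiorSS`, `SuperiorSS`, `SS`, `SF_global`, `SF_sec`) and all AND/OR
pairings of the comparison tables. The ambiguous printed precedence of the
S-F rows is resolved as `(InferiorSS OR SuperiorSS) AND (MD_24 OR MD_10)`
for the global form, since the surrounding description pairs the whole S-S
metric with the global MDs; the sectoral form is hemifield-matched:
`(InferiorSS AND (infMD_24 OR infMD_10)) OR (SuperiorSS AND (supMD_24 OR supMD_10))`.

## Performance evaluation

Specificity counts false positives among HC eyes; sensitivity counts true
positives among DP eyes; precision is TP / (all flagged patient eyes).
Undetermined and ineligible decisions count as *not flagged*. Eyes are the
unit of analysis (no correction for inter-eye correlation).

Percentages are rounded half-up in two stages — to one decimal percent,
then to the integer — because that is the convention the reference tables
follow (13/17 = 76.47% is reported as 77 via 76.5, while 11/17 = 64.71%
is 65). A single-stage half-up rounding reproduces all but the x.45–x.49
cases.

The 95% CI is a percentile bootstrap: B = 1000 resamples of equal size
drawn with replacement *within the reference group* (HC resampled for the
specificity CI, DP for the sensitivity CI, independently), with the
empirical order statistics of rank ⌈0.025·B⌉ and ⌈0.975·B⌉ — no
interpolation — each converted to an integer percent. For outcomes that
are k successes of n, the bootstrap proportion is Binomial(n, k/n)/n, so
the bounds converge to binomial quantiles; the suite verifies this against
`scipy.stats.binom.ppf`. Bounds whose binomial quantile falls near a
resampling-probability boundary are seed-sensitive at B = 1000;
`scripts/acceptance.py` therefore reports the modal bound over 21 seeded
replicates.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes:

* **Groups and sizes** (defaults): 30 HC eyes and 91 patient/suspect eyes
  (37 labelled suspects), 17 of the patients definitely progressing; the
  test–retest set has 176 eyes with 2–4 tests each inside the 4-month
  window, ~80% of repeat tests within 60 days.
* **Visit schedule**: 2–4 baseline tests within 4 months, follow-ups every
  6 months (±3 weeks seeded jitter) to a follow-up length drawn uniformly
  from 12–59 months; the last visit is kept ≥ 366 days so every eye meets
  the 1-year criterion.
* **Values**: per-eye true baseline drawn from per-group Normal
  distributions; measurement = baseline + rate × t + independent Gaussian
  noise. The 24-2 MD/PSD baseline parameters are the published cohort
  summary statistics (HC −1.25 ± 2.03 / 1.78 ± 0.77 dB; patients
  −1.58 ± 1.96 / 2.82 ± 1.92 dB). OCT baseline levels (e.g. `G_small`
  97 ± 9 µm) and all test–retest noise SDs (e.g. 1.5 µm global cpRNFL,
  1.0 dB MD, 0.6 dB PSD) are generator parameters chosen as typical
  instrument magnitudes; no acceptance check depends on their specific
  values. Plausibility floors clip thicknesses positive, VFI to [0, 100]
  and PSD non-negative.
* **Progression**: each DP eye draws an inferior or superior hemifield and
  receives concordant worsening rates — cpRNFL sector −2.5 µm/yr, matching
  GCL region(s) −1.5 µm/yr, matching hemifield MDs −0.8 dB/yr — plus
  attenuated global change (G_small −1.2 µm/yr, MD −0.5 dB/yr, PSD
  +0.3 dB/yr), so the S-S and hemifield S-F composites have true signal to
  find. 30% of the remaining patient eyes progress in structure only at
  half rate, providing discordant cases; the rest are stable.
* **Randomness**: one seed; each eye draws from a deterministic
  sub-stream, so enlarging a group never reshuffles existing eyes.

What the generator does **not** emulate: heteroscedastic noise that grows
with damage (available as an off-by-default variance-inflation factor for
patients), OCT segmentation artifacts and BMO-detection failures, VF
learning effects, floor effects of advanced disease, inter-eye
correlation, and split OCT/VF acquisition dates (real data with split
dates can be merged with `merge_paired_visits`, default 45-day pairing
window — a convention choice, since the handling of such visits in the
reference analysis is not specified). Passing calibration and
qualitative-reproduction tests on this generator therefore shows the
pipeline's statistics behave as designed under the stated noise model; it
does not certify performance numbers on clinical data, where the
generator's simplifications (and the clinical confusion counts, which
depend on the actual cohort) do not transfer.

## Problem sizes used in the checks

The suite fits the τ = 0.025 line on 5000 synthetic pairs for the
closed-form Gaussian recovery check; event-classifier calibration uses a
20 000-pair threshold fit applied to 2000 fresh stable eyes, with a
two-binomial 95% interval that accounts for the pair-level quantile
estimation error; trend type-I error uses 2000 null series at the three α
levels; the qualitative composite-metric checks run the full event
pipeline on the default 30/91/17 cohort. These sizes give the binomial
intervals stated with each check while keeping the default test run fast.

## Known limitations

* Thresholds assume the short-term window is change-free; slow true change
  within 4 months inflates the variability estimate slightly.
* The quantile line is linear in the baseline value; no nonparametric or
  covariate-adjusted quantile models.
* OLS trends assume linearity and homoscedastic Gaussian errors; no robust
  or censored regression.
* DP adjudication is an input label (synthetic ground truth here), not a
  reimplementation of expert review of OCT/VF reports.
* Dates or month offsets are both accepted on input, but all analysis is
  calendar-blind beyond 365.25-day year arithmetic.
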