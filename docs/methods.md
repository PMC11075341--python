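# Methods

This note documents the models, numerical choices and limitations of the
`actipheno` pipeline: what each stage assumes, which parameters matter, what
the synthetic cohort does and does not emulate, and therefore what passing
tests do and do not establish about real actigraphy data.

## Preprocessing

Minute-level counts (1440 per day) are summed into 24 hourly counts and each
day is z-scored with the *population* standard deviation (denominator 24).
The population denominator makes simple symmetric cases exact (an alternating
0/2 day standardizes to exactly ±1), and the tolerance on the mean-0/SD-1
invariant is 1e-9. Standardization deliberately discards the amount of
activity: the clustering unit is the shape of the daily rhythm, and total
volume re-enters the analysis only as the `total_activity` covariate (mean
daily sum over the week).

Only participants with seven distinct complete days (all 1440 minutes
present, no imputation) are retained, so the day count after filtering is
always 7 × participants. Days run midnight-to-midnight and `day_index` is
positional; no timezone or wear-time handling is attempted. A zero-variance
day has no z-score; such a day disqualifies its whole participant, treated
exactly like an incomplete week. With the synthetic generator's nonzero
night-time baseline this path never triggers in practice, but it is exercised
directly in tests.

## Day-pattern clustering

Similarity between standardized day curves is a normalized Global Alignment
Kernel. The local Gaussian kernel κ(a,b)=exp(−(a−b)²/2σ²) is replaced by the
divisible form κ/(2−κ), which keeps the alignment kernel positive definite,
and the alignment recursion is evaluated in log space — a 24-step product of
sub-unit factors underflows quickly otherwise. The DP inner loop is compiled
with numba; an n=1400 Gram takes tens of seconds on one CPU.

The bandwidth rule `sigma="auto"` is the common GAK heuristic: the median
|a−b| over pooled point pairs from at most 100 sampled curves (fixed internal
sampling seed, so the value is reproducible), scaled by √T with T=24. Pairs
are unordered and distinct; a zero median falls back to the mean positive
distance, and fully constant input is rejected since no bandwidth is
meaningful.

Kernel k-means is Lloyd's algorithm using Gram-only feature-space distances:
no explicit centroids exist. Determinism comes from a seeded restart scheme
(10 restarts, each seeding clusters from k random days), ties broken toward
the lowest cluster index, and convergence declared when the assignment stops
changing (cap 100 iterations). An emptied cluster is reseeded with the point
farthest from its own cluster, keeping k fixed at 5. The objective
Σᵢ d²(i, C(i)) is non-increasing across iterations, which is asserted as a
property test. An RBF kernel on the 24-vectors is available as a fast
alternative; on low-noise synthetic data both kernels recover the planted
patterns (ARI ≥ 0.9) and agree within 0.1 ARI.

Cluster naming is an operationalization choice: the study names clusters by
visual inspection, whereas here each cluster's mean z-curve is Pearson-
correlated with each standardized template and names are assigned by the
maximum-total-correlation bijection (Hungarian algorithm). Naming requires
exactly five populated clusters.

A dense Gram over a full survey-scale corpus (46,291 days ≈ 17 GB) is out of
scope by design; `compute_gram` refuses beyond a configurable cap (default
5,000 days) and the intended extension is fit-on-subsample followed by
nearest-cluster assignment of held-out days.

## Behavior clustering

Each retained participant's seven day labels become a relative-frequency
5-vector over (AD, M, E, BP, IM); components are multiples of 1/7 and sum to
one. Participants are clustered with standard k-means (squared Euclidean,
k-means++ initialization, 10 restarts, fixed seed), k fixed at 4. Cluster
naming uses a dominance gap δ = 0.15 on the sorted centroid: a single
"<top> dominant" name if top − second > δ, otherwise the combined
"<a>+<b> dominant" with components in canonical pattern order. δ = 0.15
separates the observed combined centroid (AD/M gap ≈ 0.005) from the
single-dominant centroids (gap ≥ 0.3). Duplicate names raise an error rather
than being silently disambiguated — at small n, k-means can legitimately
split one behavior into two clusters, and the caller should revisit δ or k.

## PHQ-9

Nine items scored 0–3; total 0–27; depressive symptoms ⇔ total ≥ 10. The
threshold lives in a single module constant. Records with a missing or
out-of-range item are excluded listwise, never imputed, and the association
analysis additionally requires complete age, BMI, gender and work situation.
The screening instrument's tenth impairment question is not scored. The flag
is a screening classification, not a diagnosis.

## Association analysis

The analysis mirrors a two-population design: pattern/behavior clustering
uses every participant passing the activity filter, while the association
uses only the complete-case subset. Descriptives are per-behavior means ± SD
with classical one-way (equal-variance) ANOVA for continuous variables and
Pearson chi-square (no continuity correction) for categorical ones;
significance is declared at p < 0.05 with no multiplicity correction.

Logistic models are fitted by IRLS (via statsmodels GLM/binomial,
convergence tolerance 1e-10, 100 iterations). Design columns are
standardized internally purely for conditioning — the affine
reparametrization is inverted exactly on output, so reported coefficients
and standard errors are in the original units (age in years, total activity
in counts). Categorical coding: behavior dummies against the M-dominant
reference, gender as a Male indicator (reference Female), work situation as
three dummies against "Working"; age, BMI and total activity enter
continuous and unscaled. Wald inference throughout with z = 1.959964; the
normal rather than a t quantile is used. A one-factor behavior model is
algebraically a saturated 2×2 analysis, and the fitted ORs reproduce the
closed-form contingency odds ratios to 1e-6 — this dual route (IRLS fit vs
closed form) is asserted in tests.

Zero contingency cells raise an error; no Haldane–Anscombe correction is
applied, because silent corrections can mask simulation pathologies.
Complete or quasi-complete separation (detected by non-convergence,
singularities, or per-term standard errors exploding beyond 10⁴ in original
units) raises a `SeparationError`. In the orchestrated pipeline the adjusted
models are fitted with `on_error="skip"`: an inestimable model is recorded
as failed in the results rather than aborting the run, since rare work
categories (≈1.5% of participants) routinely separate in small cohorts at a
7% outcome prevalence. The crude model failing is always fatal.

The model ladder: Model 1 is behavior only; Models 2–6 add age, BMI,
gender, work situation and total activity cumulatively in that order.
Sensitivity models pair the behavior factor with exactly one covariate each.
`total_activity` is the participant's mean daily count sum over the week;
a weekly-sum definition would differ only by the constant factor 7 and is a
configuration choice, not a modelling one.

## Synthetic cohort

The generator emulates a cohort in which every participant contributes seven
complete 24-h days. Defaults are desk-scale study conditions: 200
participants, behavior prevalences (23.86%, 34.04%, 25.34%, 16.76%) for
(AD, M, AD+M, E dominant), baseline depressive-symptom prevalence 6.99% in
the M-dominant reference, and planted crude odds ratios (1.21, 1.0, 1.24,
2.48); covariate marginals (age, BMI, sex, work situation) are set per
behavior to match the observed cohort composition.

Diurnal templates are smooth bump/plateau curves in counts/hour satisfying
the qualitative shape constraints of each pattern (E peaks 18–20 h, M peaks
7–10 h, BP has two peaks ≥ 6 h apart, AD is flat within 1.5× across 8–19 h);
the exact curves are a design choice since only shapes, not tables, define
the patterns. The irregular-morning template is a broad two-lobed morning
shape whose hour axis is circularly shifted day-to-day by round(N(0, 1.5 h)),
making it distinguishable from the clean morning peak even at zero shift.
Night-time baselines are 60–90 counts/h, and template daily totals sit near
the observed 11,500–13,000 count range.

Minute counts are negative binomial with mean template-intensity/60 and
dispersion `noise` (default 10, a realistic overdispersion for wrist counts;
`None` selects the Poisson limit used in tests). Each day's pattern is drawn
i.i.d. from the behavior's mixture: the dominant component carries the
observed mean relative frequency (AD-dom 0.79, M-dom 0.83, AD+M 0.43/0.44,
E-dom 0.49) and the remaining mass is spread uniformly — a maximum-entropy
default where no finer distribution is published. PHQ-9 items are drawn from
status-conditional item distributions, resampled until the total is
consistent with the planted status, guaranteeing label/threshold coherence.
Randomness uses a single seed sequence with one spawned substream per
participant, so cohorts are reproducible and participants independent.

What the generator does *not* emulate: nonwear episodes, missing days,
within-week behavioral drift, autocorrelated minute noise, or any feature of
raw 80 Hz acceleration. Passing recovery tests therefore demonstrates the
pipeline's correctness on well-specified planted structure, not robustness
to the messiness of field recordings.

A consequence of the planted mixtures worth stating: because the i.i.d.
7-day multinomial draws of the four behaviors genuinely overlap (an
AD+M-dominant week with 4 AD days looks like a mild AD-dominant week), the
Bayes-optimal accuracy of any method classifying participants from their
frequency vectors is ≈ 90.5% under these defaults, and Euclidean k-means
partitions plateau near 88% even with unlimited data. Behavior-label
agreement on a finite cohort of 200 therefore fluctuates around the high
80s / low 90s depending on the seed, while day-pattern recovery is essentially
perfect (ARI ≥ 0.99). This is an intrinsic property of the planted mixture
overlap, not a convergence failure.

## Problem sizes

Default test and reproduction scales were chosen as desk-scale conditions:
pattern clustering at 1,400 days (200 participants), estimator calibration
over 200 replicate cohorts of 4,000 participants (statistics-only
simulation, no minute-level counts), and study-scale effect recovery at
n = 4,242. The full-survey clustering scale (46,291 days) is analytically
accounted for through the completeness-filter rule but not executed.
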