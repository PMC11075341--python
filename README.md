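# actipheno

Diurnal activity-pattern phenotyping from wrist actigraphy, and its
association with depressive symptoms.

`actipheno` is a reference implementation of a two-stage unsupervised
phenotyping pipeline for minute-level accelerometer count data, aimed at
epidemiologists and biostatisticians working with 24-h wearable recordings
(e.g. population surveys such as NHANES). Given seven complete days of
minute-level activity counts per participant and a PHQ-9 questionnaire table,
it

1. aggregates counts to hourly resolution and z-scores each day
   (mean 0, SD 1), so only the *shape* of the daily rhythm remains;
2. clusters the standardized 24-point day curves with **kernel k-means**
   using a **Global Alignment Kernel (GAK)** into five diurnal patterns —
   all-day (AD), morning (M), evening (E), bi-phasic (BP) and
   irregular-morning (IM);
3. collapses each participant's week into a 5-vector of pattern relative
   frequencies (multiples of 1/7) and clusters participants with standard
   k-means into four weekly **behaviors** (AD dominant, M dominant,
   AD+M dominant, E dominant), named by their dominant components;
4. binarizes depressive symptoms at the standard PHQ-9 threshold
   (total ≥ 10) and fits a crude plus sequentially adjusted logistic
   ladder of the behavior–depression association (adding age, BMI, gender,
   work situation and total activity cumulatively), with M dominant as the
   reference behavior.

A first-class synthetic-cohort generator plants known day patterns, weekly
behaviors, covariate structure and a behavior–depression effect, so every
stage of the pipeline can be tested against ground truth without access to
the survey data.

## Model summary

**GAK.** For day curves *x*, *y* ∈ ℝ²⁴ the local Gaussian kernel
κ(a,b) = exp(−(a−b)²/2σ²) is made divisible, κ̃ = κ/(2−κ), and the alignment
sum is computed by dynamic programming in log space,

    M[0,0] = 1,  M[i,j] = κ̃(x_i, y_j) · (M[i−1,j−1] + M[i−1,j] + M[i,j−1]),

with normalization K(x,y) = k(x,y)/√(k(x,x)·k(y,y)) so that K(x,x) = 1. The
bandwidth σ defaults to the median point-pair distance times √T.

**Kernel k-means.** Lloyd's algorithm in the kernel-induced feature space
using only Gram-matrix distances,

    d²(i, C) = K_ii − (2/|C|) Σ_{j∈C} K_ij + (1/|C|²) Σ_{j,l∈C} K_jl,

best of 10 restarts by inertia, deterministic given a seed. The five clusters
are named against the diurnal templates by maximum-total-correlation
bijective (Hungarian) matching.

**Association.** Odds ratios are exp(β) from maximum-likelihood logistic
fits (IRLS); 95% CIs are Wald, exp(β ± 1.96·SE); p-values are two-sided
Wald. For a one-factor model these reproduce the closed-form 2×2
contingency odds ratios exactly.

## Worked example

Run the whole pipeline on the default synthetic cohort (200 participants ×
7 days × 1440 minutes):

```bash
actipheno --seed 0 --out-dir demo run-all
```

prints

```
pipeline complete: 200 clustered, 200 in the association analysis
crude OR [behavior[E dominant]]: 5.08 (0.93, 27.62)
```

and writes, among other artifacts, `behavior_centroids.csv`:

```
behavior_name,freq_AD,freq_M,freq_E,freq_BP,freq_IM
AD dominant,0.839,0.030,0.045,0.033,0.054
M dominant,0.062,0.832,0.038,0.036,0.032
E dominant,0.116,0.143,0.525,0.100,0.116
...
```

Each row is the mean pattern-frequency vector of one recovered behavior: AD-
and M-dominant weeks concentrate ~83% of their days on a single pattern,
while the E-dominant behavior is far more dispersed (~53% evening days) —
the high day-to-day variability characteristic of that group. The crude
odds ratio compares depressive-symptom odds in each behavior against the
M-dominant reference; at n=200 the interval is wide (0.93–27.62), and the
study-scale planted effect is recovered much more tightly in the
calibration checks below. `manifest.json` records the filter cascade
(200 participants → 1400 complete days → 1400 standardized days) and
per-stage timings; `results.json` holds the full model ladder.

Every stage is also callable on the previous stage's files
(`simulate`, `preprocess`, `cluster-patterns`, `cluster-behaviors`,
`score-phq9`, `associate`), and the whole library is importable:

```python
import actipheno as ap

activity, cohort, truth = ap.simulate_cohort(ap.SimConfig(seed=0))
std, report = ap.preprocess.preprocess(activity)
```

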