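# Methods

## The analysis model

The pipeline treats a behavioral cohort as an animals × measures matrix
with metadata (genotype, sex, cohort, treatment arm) and asks whether
unsupervised structure in behavior recovers genotype.

**Standardization.** Each measure is z-scored with the sample SD (n−1
denominator). Whether a measure is z-scored per sex is decided by a
screening two-way ANOVA (sex × genotype, Type II sums of squares) at
`sex_alpha` (default 0.05): a sex main effect *or* interaction flags the
measure. The screen runs on each measure's own complete cases from the full
dataset, not on the complete-battery subset, so measures recorded in more
cohorts are screened at their larger n. In the treatment workflow the
screen is restricted to the two control arms, so the treated arm cannot
influence standardization. Type II was chosen because the designs are
mildly unbalanced and the screen only asks whether *any* sex dependence
exists; no repeated-measures structure is modeled (only day-level summary
measures enter the analysis).

**PCA.** Principal axes come from the SVD of the column-centered
standardized matrix; variance fractions are λⱼ/Σλ. Two sign conventions
make the decomposition deterministic: each component's largest-|loading|
entry is made positive, and PC1 is then re-signed so that
Σⱼ loading<sub>j,1</sub> · impairment_direction<sub>j</sub> > 0, i.e.
higher PC1 = more impaired. Impairment directions are battery
*configuration* (+1 weight, +1 forced-swim immobility, −1 for rotarod,
open-field distance and center time, marbles, nesting), never inferred from
data, so the severity orientation is meaningful for new disease models. A
zero dot product leaves the sign unchanged with a warning.

**Clustering.** k = 2 Lloyd iterations from `n_init = 50` k-means++
seedings, run as a single vectorized batch; the labeling with minimal
within-cluster sum of squares wins. Convergence is assignment fixpoint (or
centroid shift below 1e−10 implicitly via the fixpoint); an emptied cluster
keeps its previous centroid and loses to better restarts. Fifty restarts
make the k = 2 optimum effectively deterministic at these sample sizes —
the test suite checks exact agreement with exhaustive 2-partition
enumeration on instances with n ≤ 10. Everything is deterministic given the
seed.

**Validation.** Accuracy is % agreement under the better of the two
cluster↔genotype mappings (the only convention that is well defined for
unlabeled clusters); by construction accuracy ≥ 50%. An exact tie (only
possible at 50%) maps cluster 1 to the alphabetically first genotype, for
determinism.

**Outlier screening.** Optional: a two-sided Grubbs test (critical value
G = (n−1)/√n · √(t²/(n−2+t²)), t the upper α/(2n) Student-t quantile with
n−2 df) is applied once to each of the first `n_pcs` PC score columns; the
union of flagged animals is removed and the pipeline re-runs
(re-standardize, re-fit) on the reduced cohort. One pass, no iteration —
repeated Grubbs inflates the false-positive rate and a single screening
pass matches how the method is used in practice.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_pcs` | 2 | PCs used for clustering; 1 treats PC1 as a severity score. Not auto-selected (no elbow heuristics): the scree is reported, the choice is the analyst's. |
| `sex_alpha` | 0.05 | screening level for sex-stratified standardization |
| `outlier_alpha` | off (0.05 when enabled) | Grubbs level per PC column |
| `n_init` | 50 | k-means restarts |
| bootstrap `trials` | 10 000 | resamples per n; the acceptance suite uses 400–500 to keep runs short, with Monte-Carlo error accounted for in the checks |

## The synthetic cohort generator

The generator produces the study conditions the tests run under. Per
animal with latent severity s ~ N(0,1) shared across measures:

value = center + dir·d·𝟙(mutant)·(1 − rescue·𝟙(treated)) + dir·λ·s
      + (sex d)/2·(±1) + cohort intercept + residual noise,

with residual SD √(1−λ²) so each measure's within-group SD is ≈ 1 and d is
an interpretable Cohen's d; bounded measures are clipped (marbles 0–20,
immobility 0–100%) and counts rounded. Genotype effects are injected per
measure rather than through the latent factor: routing them through a
single factor cannot reproduce both the per-measure effect sizes and the
observed classification accuracy (shared noise saturates the Mahalanobis
separation), whereas the hybrid matches configured and realized d exactly
while the factor carries the between-measure correlation.

Genotype effect sizes are fixed by published group statistics for the
*Ube3a*^m−/p+^ battery, converted via d = t·√(1/n₁+1/n₂) (weight 0.59,
open-field distance 1.18, center time 0.18 — effectively null — marbles
1.99, forced swim 1.86) and, for measures reported with repeated-measures
genotype main effects, the approximation d = 2·√(F/N) (rotarod 1.20 for
both days, nesting 1.84); the approximation ignores the RM correlation
structure and is documented as such. Sex effects (d = 0.6) go on the six
measures outside the open field, mirroring the finding that six of eight
measures are sex-dependent; tests do not depend on the specific set.
Cohort intercepts are N(0, 0.2²) per cohort × measure.

The single free parameter, the shared factor loading λ, was calibrated
once: scanning λ ∈ {0.2,…,0.45} at the default conditions, λ = 0.2 gives a
pooled PC1 variance share of ≈ 38% (within the intended 30–45% band) and
mean 2-PC accuracy ≈ 95% at n = 85/genotype, and was frozen. The fixture
writer records the full generation plan (effect sizes, cohort sizes,
missingness blocks) alongside the CSVs.

What the generator does *not* emulate: raw behavioral time series (rotarod
learning curves, daily nest weights), floor/ceiling pathologies beyond
simple clipping, heavy-tailed or skewed measure distributions,
non-Gaussian cohort effects, and attrition that correlates with phenotype.
Passing tests therefore show that the pipeline behaves correctly under the
assumed Gaussian-latent structure at realistic effect sizes — not that
real mouse data meet those assumptions.

## Numerical choices

- Two-way ANOVA by model-comparison least squares on dummy matrices
  (numpy `lstsq`), Type II; zero residual variance (relative to ‖y‖²,
  1e−12) is an error, as are empty design cells. Tukey–Kramer and Fisher's
  exact (two-sided by point-probability summation) are delegated to scipy;
  Grubbs is implemented from its closed form. All p-values come from
  distribution CDFs, no lookup tables.
- z-scoring requires ≥ 2 animals and nonzero SD per standardization group
  and errors loudly otherwise; missing cells must be removed by
  complete-case subsetting first (no imputation anywhere).
- Bootstrap resamples re-run the *entire* pipeline. The sex-stratification
  plan is inherited from the full dataset (screening at n = 3 is
  hopeless); a resample with fewer than two animals of a sex falls back to
  pooled z-scoring for that measure (counted on the curve), and zero-SD
  resamples are redrawn (counted). Drawn duplicates count separately in
  accuracy, as sampling with replacement implies.
- The false-positive chance band is empirical, not the naive 50%: k = 2
  clustering of finite null samples always exceeds 50% agreement under the
  best mapping. The band was calibrated by an independent oracle
  (spherical Gaussian data, scikit-learn k-means, 20 000 trials:
  mean 56.5%, SD 5.0 per trial at n = 36, d = 2) and is stored as a
  package resource; a run is "no separation" when its mean lies within
  3 SE of the oracle mean plus 1.5 percentage points of model slack.
- The default ablation list for the 8-measure battery is 11 conditions:
  baseline, eight single-measure exclusions, and the two multi-measure
  tests (rotarod, open field). The composition is configurable. Fisher
  comparisons are condition-vs-baseline only, with no multiplicity
  correction.
- Per-cohort runs re-screen sex dependence within each cohort (the
  analysis is run independently per cohort); a supplied plan overrides
  this, and single-sex cohorts fall back to pooled z-scoring.

## Problem sizes in the test and acceptance runs

The suite uses the emulated study sizes throughout: 286 animals in 10
cohorts (170 complete-battery), 85/genotype for power checks (100 seeds),
12/genotype for the small-cohort check (150 seeds), 36 null females with
500 control trials, bootstrap n = 3–30 at 400–500 trials, and three-arm
cohorts of 34/25/32 (100 seeds). These sizes keep the default run short
while leaving Monte-Carlo error well inside the asserted margins.

## Known limitations

- Complete-case analysis only; block missingness is handled by choosing
  the measure set, never by imputation.
- Exactly two genotype levels outside the treatment workflow; exactly
  three arms inside it.
- No alternative clusterers (GMM, hierarchical) and no
  centroid-distance/cluster-spread summaries; accuracy is the only
  separation readout.
- The d-from-F conversions and the single-latent-factor correlation
  structure are simplifications; cohort effects are additive intercepts
  only.
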