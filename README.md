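# phenoclust

Multidimensional analysis of rodent behavior: predict genotype from a
behavioral battery, and summarize per-animal phenotypic severity as a single
score.

## The problem

Mouse models of neurodevelopmental disorders — here the Angelman-syndrome
model (*Ube3a*^m−/p+^) as the reference case — show impairments spread across
many behavioral domains: weight gain, accelerating-rotarod performance,
open-field activity, marble burying, nest building, forced-swim immobility.
No single test captures the phenotype, and treatment studies need one number
that does. This package implements the multidimensional approach:

1. **Standardization.** Every measure is z-scored,
   z = (x − group mean) / group SD. Measures with a significant sex main
   effect or sex × genotype interaction (two-way ANOVA, α = 0.05) are
   z-scored separately within males and females.
2. **PCA.** Principal components of the standardized animals × measures
   matrix. PC1 is oriented so that *higher = more impaired* (using each
   measure's configured impairment direction) and serves as a composite
   severity score.
3. **k-means, k = 2.** Animals are clustered in the space of the first
   *n* PCs (default 2).
4. **Validation.** Clusters are compared with true genotypes under the best
   of the two cluster↔genotype mappings; accuracy = % agreement.

Around that core sit the experiment drivers a phenotyping study needs:
single-measure/whole-test ablation with Fisher's exact comparisons,
an exhaustive scan of all 3–8-measure subsets (219 conditions for an
8-measure battery), partial-profile conditions that trade measures for
animals on datasets with block-wise missingness, bootstrap sample-size
curves (n per genotype drawn with replacement, full pipeline re-run per
resample), per-cohort runs, a false-positive control on homogeneous groups
(with an empirically calibrated chance band — k = 2 clustering of null data
always beats 50%), Grubbs outlier screening in PC space, and a three-arm
treatment analysis (reference + control, mutant + control,
mutant + treatment) tested in 1-PC severity space with one-way ANOVA and
Tukey post hoc.

Because no animal data ship with the package, a calibrated synthetic cohort
generator (`phenoclust.simulate`) emulates the study structure: per-measure
genotype effect sizes derived from the published test statistics
(d = t·√(1/n₁+1/n₂), e.g. d ≈ 2.0 for marble burying, d ≈ 0.18 for
open-field center time), a latent severity factor carrying between-measure
correlation, sex and cohort effects, bounded/integer measures, block
missingness, and a fractional treatment-rescue arm.

## Worked example

```python
from phenoclust import BehaviorClusterModel, make_fixtures, read_dataset

files = make_fixtures("fixtures", seed=2022)           # synthetic cohorts
ds = read_dataset(files["dataset1_like"], files["battery"])
res = BehaviorClusterModel(ds, n_pcs=2, outlier_alpha=0.05).fit(seed=0)
print(res.summary())
```

```
Multidimensional Behavioral Analysis
====================================================
Animals (complete cases)     170   AS: 82  WT: 88
Measures                       8
PCs used for clustering        2
Sex-stratified measures        6   forced_swim_immobility, marbles_buried, nest_building, rotarod_day1, rotarod_day5, weight
Outliers excluded              0   (none)
----------------------------------------------------
Clustering accuracy           97.06 %
Misclassified animals          5
Cluster mapping           cluster 1 -> AS, cluster 2 -> WT
----------------------------------------------------
Variance explained:  PC1 40.0%  PC2 11.9%  PC3 10.3%  PC4 9.3%
PC1 loadings (severity orientation):
    weight                       0.296
    rotarod_day1                -0.379
    rotarod_day5                -0.364
    openfield_distance          -0.340
    openfield_center_time       -0.153
    marbles_buried              -0.416
    nest_building               -0.410
    forced_swim_immobility       0.395
```

Reading this: of the 286 simulated animals, 170 have the full battery; six
measures showed sex effects and were z-scored per sex; clustering in 2-PC
space recovered genotype for 165/170 animals (97.1%); PC1 carries 40% of
the variance, loads on every measure with the sign of its impairment
direction (heavier, slower on the rotarod, hypoactive, fewer marbles
buried, worse nests, more immobile → higher severity), so
`res.severity` is a per-animal composite severity score.

The same pipeline is available from the shell (`phenoclust analyze`,
`ablate`, `scan`, `bootstrap`, `nullcheck`, `treatment`, `cohorts`,
`simulate`), each writing JSON/CSV reports, plots and a run log to `--out`.

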