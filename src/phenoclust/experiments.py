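"""Experiment drivers built on the core pipeline.

Single-exclusion ablation, exhaustive 3..m-measure subset scans,
partial-profile conditions on datasets with block missingness, bootstrap
sample-size curves, per-cohort runs, the homogeneous-group false-positive
control, and the three-arm treatment analysis in severity (PC1) space.

All drivers are deterministic given (dataset, configuration, seed).
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Optional, Sequence

import numpy as np

from .data import BehaviorDataset, complete_case_subset
from .embedding import (DEFAULT_N_INIT, ClusteringResult, kmeans2, fit_pca,
                        orient_pc1, predict_genotype, validate_clusters)
from .preprocess import (SCOPE_CONTROLS, StandardizationPlan, screen_sex_dependence,
                         standardize)
from .stats import AnovaTable, PairwiseComparison, fisher_exact, one_way_anova, tukey_hsd

#: Default grouping of measures into behavioral tests, for test-level
#: exclusion (a test name in an exclusion set expands to its measures).
DEFAULT_TEST_MEASURES = {
    "rotarod": ("rotarod_day1", "rotarod_day5"),
    "open_field": ("openfield_distance", "openfield_center_time"),
}


# ---------------------------------------------------------------------------
# Report types
# ---------------------------------------------------------------------------

@dataclass
class AblationCondition:
    excluded: tuple[str, ...]
    n_measures: int
    n_animals: int
    accuracy: float
    fisher_p_vs_baseline: Optional[float]


@dataclass
class AblationReport:
    conditions: list[AblationCondition]
    baseline_accuracy: float


@dataclass
class SubsetRecord:
    measures: tuple[str, ...]
    accuracy: float


@dataclass
class SubsetSizeSummary:
    n_measures: int
    n_subsets: int
    mean_accuracy: float
    sem_accuracy: float


@dataclass
class SubsetScan:
    records: list[SubsetRecord]
    summary: list[SubsetSizeSummary]


@dataclass
class BootstrapCurve:
    n_values: list[int]
    mean_accuracy: list[float]
    sd_accuracy: list[float]
    trials: int
    seed: int
    retries: int = 0
    pooled_fallbacks: int = 0


@dataclass
class FalsePositiveReport:
    trials: int
    mean_accuracy: float
    sd_accuracy: float
    q025: float
    q975: float
    chance_band: Optional[tuple[float, float]]
    no_separation: Optional[bool]
    accuracies: list[float] = field(default_factory=list)


@dataclass
class ArmSummary:
    group: str
    n: int
    pc1_mean: float
    pc1_sem: float


@dataclass
class TreatmentReport:
    arms: list[ArmSummary]
    anova: AnovaTable
    tukey: list[PairwiseComparison]
    control_clustering: ClusteringResult
    plan: StandardizationPlan
    pc1_variance_fraction: float


@dataclass
class CohortRun:
    cohort: str
    n_by_genotype: dict[str, int]
    accuracy: float
    small_n: bool


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _restrict_plan(plan: StandardizationPlan, measures: Sequence[str]) -> StandardizationPlan:
    keep = set(measures)
    return StandardizationPlan(
        [m for m in plan.sex_stratified if m in keep],
        screening_alpha=plan.screening_alpha,
        screening_scope=plan.screening_scope,
    )


def _fisher_vs_baseline(acc: float, n: int, base_acc: float, base_n: int) -> float:
    corr = round(acc / 100.0 * n)
    bcorr = round(base_acc / 100.0 * base_n)
    return fisher_exact([[corr, n - corr], [bcorr, base_n - bcorr]])


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# Ablation and subset scans
# ---------------------------------------------------------------------------

def ablate_single(
    ds: BehaviorDataset,
    exclusions: Optional[Sequence[Sequence[str]]] = None,
    n_pcs: int = 2,
    seed: int = 0,
    plan: Optional[StandardizationPlan] = None,
    test_measures: Optional[dict[str, tuple[str, ...]]] = None,
) -> AblationReport:
    """Re-run the pipeline with single measures or whole tests excluded.

    The default condition list is the baseline (nothing excluded), one
    condition per measure, and one per multi-measure test — 11 conditions for
    the 8-measure battery.  Every condition runs on the same animal set (the
    complete-battery subset), and each is compared with the baseline by
    Fisher's exact test on correct/incorrect counts.
    """
    tests = DEFAULT_TEST_MEASURES if test_measures is None else test_measures
    ds = complete_case_subset(ds)
    if exclusions is None:
        exclusions = [()]
        exclusions += [(m,) for m in ds.measures]
        exclusions += [(t,) for t, members in tests.items()
                       if len(members) > 1 and set(members) <= set(ds.measures)]
    if plan is None:
        plan = screen_sex_dependence(ds)
    rng = np.random.default_rng(seed)

    expanded: list[tuple[str, ...]] = []
    for cond in exclusions:
        names: list[str] = []
        for item in cond:
            if item in tests:
                names.extend(tests[item])
            elif item in ds.measures:
                names.append(item)
            else:
                raise ValueError(f"unknown measure or test {item!r}")
        remaining = [m for m in ds.measures if m not in set(names)]
        if not remaining:
            raise ValueError("exclusion removes every measure in the battery")
        if len(remaining) < 3:
            raise ValueError(f"exclusion {tuple(cond)!r} leaves fewer than 3 measures")
        expanded.append(tuple(names))

    results = []
    for cond in expanded:
        keep = [m for m in ds.measures if m not in set(cond)]
        sub = complete_case_subset(ds, keep)
        _, cr = predict_genotype(sub, n_pcs=min(n_pcs, len(keep)),
                                 plan=_restrict_plan(plan, keep),
                                 seed=_child_seed(rng))
        results.append((cond, sub.n_animals, len(keep), cr.accuracy))

    try:
        base = next(r for r in results if r[0] == ())
    except StopIteration:
        base = results[0]
    base_acc, base_n = base[3], base[1]
    conditions = [
        AblationCondition(
            excluded=cond,
            n_measures=nm,
            n_animals=na,
            accuracy=acc,
            fisher_p_vs_baseline=(None if cond == base[0] else
                                  _fisher_vs_baseline(acc, na, base_acc, base_n)),
        )
        for cond, na, nm, acc in results
    ]
    return AblationReport(conditions=conditions, baseline_accuracy=base_acc)


def scan_subsets(
    ds: BehaviorDataset,
    k_min: int = 3,
    k_max: Optional[int] = None,
    n_pcs: int = 2,
    seed: int = 0,
    plan: Optional[StandardizationPlan] = None,
) -> SubsetScan:
    """Run the pipeline on every measure subset of size k_min..k_max.

    For the 8-measure battery with k in [3, 8] this enumerates
    C(8,3)+...+C(8,8) = 56+70+56+28+8+1 = 219 conditions.
    """
    ds = complete_case_subset(ds)
    m = len(ds.measures)
    if k_max is None:
        k_max = m
    if k_min < 3:
        raise ValueError("subset scan floor is 3 measures")
    if not k_min <= k_max <= m:
        raise ValueError("require k_min <= k_max <= number of measures")
    if plan is None:
        plan = screen_sex_dependence(ds)
    rng = np.random.default_rng(seed)
    records = []
    for k in range(k_min, k_max + 1):
        for combo in itertools.combinations(ds.measures, k):
            sub = complete_case_subset(ds, list(combo))
            _, cr = predict_genotype(sub, n_pcs=min(n_pcs, k),
                                     plan=_restrict_plan(plan, combo),
                                     seed=_child_seed(rng))
            records.append(SubsetRecord(measures=combo, accuracy=cr.accuracy))
    summary = []
    for k in range(k_min, k_max + 1):
        accs = np.array([r.accuracy for r in records if len(r.measures) == k])
        sem = float(accs.std(ddof=1) / np.sqrt(accs.size)) if accs.size > 1 else 0.0
        summary.append(SubsetSizeSummary(k, int(accs.size), float(accs.mean()), sem))
    return SubsetScan(records=records, summary=summary)


def partial_profile_conditions(
    ds_full: BehaviorDataset,
    conditions: Sequence[Sequence[str]],
    n_pcs: int = 2,
    seed: int = 0,
    plan: Optional[StandardizationPlan] = None,
) -> AblationReport:
    """Trade measures for animals: each condition keeps only the animals
    complete for its measure set, so fewer measures can mean more animals."""
    for cond in conditions:
        if len(cond) < 3:
            raise ValueError("each condition needs at least 3 measures")
    if plan is None:
        plan = screen_sex_dependence(ds_full)
    rng = np.random.default_rng(seed)
    results = []
    for cond in conditions:
        sub = complete_case_subset(ds_full, list(cond))
        _, cr = predict_genotype(sub, n_pcs=min(n_pcs, len(cond)),
                                 plan=_restrict_plan(plan, cond),
                                 seed=_child_seed(rng))
        excluded = tuple(m for m in ds_full.measures if m not in set(cond))
        results.append((excluded, sub.n_animals, len(cond), cr.accuracy))
    base = next((r for r in results if r[0] == ()), results[0])
    conditions_out = [
        AblationCondition(
            excluded=exc, n_measures=nm, n_animals=na, accuracy=acc,
            fisher_p_vs_baseline=(None if exc == base[0] else
                                  _fisher_vs_baseline(acc, na, base[3], base[1])),
        )
        for exc, na, nm, acc in results
    ]
    return AblationReport(conditions=conditions_out, baseline_accuracy=base[3])


# ---------------------------------------------------------------------------
# Fast resampling pipeline (arrays only, no DataFrame per trial)
# ---------------------------------------------------------------------------

def _resample_accuracy(X, sexes, is_mut, strat_cols, n_pcs, kseed, n_init):
    """Full pipeline on a resample.  Returns (accuracy, pooled_fallbacks) or
    (None, 0) when a standardization group has zero sd (caller retries)."""
    n, m = X.shape
    Z = np.empty_like(X)
    fallbacks = 0
    male = sexes == "M"
    for j in range(m):
        col = X[:, j]
        if j in strat_cols:
            ok = True
            for mask in (male, ~male):
                if mask.sum() < 2:
                    ok = False
                    break
            if ok:
                for mask in (male, ~male):
                    vals = col[mask]
                    sd = vals.std(ddof=1)
                    if sd <= 0:
                        return None, fallbacks
                    Z[mask, j] = (vals - vals.mean()) / sd
                continue
            fallbacks += 1
        sd = col.std(ddof=1)
        if sd <= 0:
            return None, fallbacks
        Z[:, j] = (col - col.mean()) / sd
    Zc = Z - Z.mean(axis=0)
    _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
    k = min(n_pcs, Vt.shape[0])
    scores = Zc @ Vt[:k].T
    labels, _ = kmeans2(scores, n_init=n_init, seed=kseed)
    agree = int(((labels == 1) & ~is_mut).sum() + ((labels == 2) & is_mut).sum())
    return 100.0 * max(agree, n - agree) / n, fallbacks


def bootstrap_curve(
    ds: BehaviorDataset,
    n_min: int = 3,
    n_max: int = 30,
    trials: int = 10_000,
    n_pcs: int = 2,
    seed: int = 0,
    plan: Optional[StandardizationPlan] = None,
    n_init: int = DEFAULT_N_INIT,
    replace: bool = True,
    max_retries: int = 100,
) -> BootstrapCurve:
    """Accuracy as a function of per-genotype sample size.

    Per trial, n animals per genotype are drawn (with replacement by
    default) and the entire pipeline — re-standardization, PCA, clustering,
    validation — is re-run on the resample.  The sex-stratification plan is
    inherited from the full dataset (screening is hopeless at n = 3); when a
    resample has fewer than two animals of a sex, that measure falls back to
    pooled standardization for that trial; zero-sd resamples are redrawn
    (both occurrences are counted on the returned curve).  Drawn duplicates
    each count separately in the accuracy.
    """
    ds = complete_case_subset(ds)
    genos = ds.genotypes
    levels = sorted(np.unique(genos).tolist())
    if len(levels) != 2:
        raise ValueError("bootstrap requires exactly 2 genotypes")
    if plan is None:
        plan = screen_sex_dependence(ds)
    X = ds.values_matrix()
    sexes = ds.sexes
    idx_a = np.flatnonzero(genos == levels[0])
    idx_b = np.flatnonzero(genos == levels[1])
    if min(idx_a.size, idx_b.size) < n_min:
        raise ValueError("both genotypes need at least n_min animals")
    strat_cols = {ds.measures.index(m) for m in plan.sex_stratified}
    rng = np.random.default_rng(seed)

    n_values = list(range(n_min, n_max + 1))
    means, sds = [], []
    retries = pooled = 0
    for n in n_values:
        accs = np.empty(trials)
        for t in range(trials):
            acc = None
            for _ in range(max_retries):
                if replace:
                    sel = np.concatenate([rng.choice(idx_a, n, replace=True),
                                          rng.choice(idx_b, n, replace=True)])
                else:
                    sel = np.concatenate([rng.choice(idx_a, n, replace=False),
                                          rng.choice(idx_b, n, replace=False)])
                is_mut = np.zeros(2 * n, dtype=bool)
                is_mut[n:] = True
                acc, fb = _resample_accuracy(X[sel], sexes[sel], is_mut,
                                             strat_cols, n_pcs,
                                             _child_seed(rng), n_init)
                pooled += fb
                if acc is not None:
                    break
                retries += 1
            if acc is None:
                raise RuntimeError(f"could not draw a standardizable resample at n={n}")
            accs[t] = acc
        means.append(float(accs.mean()))
        sds.append(float(accs.std(ddof=1)) if trials > 1 else 0.0)
    return BootstrapCurve(n_values=n_values, mean_accuracy=means, sd_accuracy=sds,
                          trials=trials, seed=seed, retries=retries,
                          pooled_fallbacks=pooled)


# ---------------------------------------------------------------------------
# False-positive control
# ---------------------------------------------------------------------------

def _load_chance_band(n: int, n_pcs: int, trials: int) -> Optional[tuple[float, float]]:
    """Empirical chance band for the mean accuracy of a null analysis.

    Calibrated once by a brute-force oracle (k-means accuracy on spherical
    Gaussian data of matched size and dimension; see
    scripts/calibrate_null_band.py) and stored as a package resource.  The
    band is the oracle mean +/- (3 SE of a ``trials``-trial mean + 1.5
    percentage points of model slack).
    """
    ref = importlib_resources.files("phenoclust") / "resources" / "null_band.json"
    entries = json.loads(ref.read_text(encoding="utf-8"))
    for e in entries:
        if e["n"] == n and e["n_pcs"] == n_pcs:
            se = e["sd"] / np.sqrt(trials)
            return (e["mean"] - 3 * se - 1.5, e["mean"] + 3 * se + 1.5)
    return None


def false_positive_control(
    ds: BehaviorDataset,
    trials: int = 500,
    n_pcs: int = 2,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
    keep_accuracies: bool = False,
) -> FalsePositiveReport:
    """Random balanced splits of a homogeneous (single-genotype) group.

    The accuracy distribution should sit in the empirically calibrated
    chance band: k = 2 clustering of finite null samples always agrees with
    the best label mapping more than 50% of the time, so the band is well
    above 50 but far below a real genotype separation.
    """
    ds = complete_case_subset(ds)
    if ds.data["genotype"].nunique() != 1:
        raise ValueError("false-positive control requires a single-genotype dataset")
    n = ds.n_animals
    if n < 6:
        raise ValueError("need at least 6 animals")
    X = ds.values_matrix()
    sexes = ds.sexes
    rng = np.random.default_rng(seed)
    half = n // 2
    accs = np.empty(trials)
    for t in range(trials):
        perm = rng.permutation(n)
        is_b = np.zeros(n, dtype=bool)
        is_b[perm[:half]] = True
        acc, _ = _resample_accuracy(X, sexes, is_b, set(), n_pcs,
                                    _child_seed(rng), n_init)
        if acc is None:  # pragma: no cover - constant column in real data
            raise RuntimeError("zero-variance measure in null dataset")
        accs[t] = acc
    band = _load_chance_band(n, n_pcs, trials)
    mean = float(accs.mean())
    return FalsePositiveReport(
        trials=trials,
        mean_accuracy=mean,
        sd_accuracy=float(accs.std(ddof=1)),
        q025=float(np.quantile(accs, 0.025)),
        q975=float(np.quantile(accs, 0.975)),
        chance_band=band,
        no_separation=bool(band[0] <= mean <= band[1]) if band else None,
        accuracies=accs.tolist() if keep_accuracies else [],
    )


# ---------------------------------------------------------------------------
# Treatment analysis
# ---------------------------------------------------------------------------

def treatment_analysis(
    ds: BehaviorDataset,
    n_pcs: int = 1,
    seed: int = 0,
    control_groups: Optional[tuple[str, str]] = None,
    alpha: float = 0.05,
    n_init: int = DEFAULT_N_INIT,
) -> TreatmentReport:
    """Three-arm severity analysis (reference+control, mutant+control,
    mutant+treatment).

    Sex screening uses the two control arms only; standardization and the
    PCA fit use all animals; PC1 is oriented to severity; clustering is
    validated on the control arms alone; the treatment effect is a one-way
    ANOVA across the three arms on PC1 with Tukey pairwise comparisons.
    """
    if not ds.has_groups:
        raise ValueError("treatment analysis requires a 'group' column")
    ds = complete_case_subset(ds)
    arms = sorted(ds.data["group"].unique().tolist())
    if len(arms) != 3:
        raise ValueError(f"exactly 3 treatment arms required, got {arms}")
    geno_by_arm = {a: sorted(ds.data.loc[ds.data["group"] == a, "genotype"].unique())
                   for a in arms}
    for a, g in geno_by_arm.items():
        if len(g) != 1:
            raise ValueError(f"arm {a!r} mixes genotypes {g}")
    if control_groups is None:
        genos = {a: g[0] for a, g in geno_by_arm.items()}
        counts: dict[str, list[str]] = {}
        for a, g in genos.items():
            counts.setdefault(g, []).append(a)
        ref_geno = next(g for g, a in counts.items() if len(a) == 1)
        ref_arm = counts[ref_geno][0]
        mut_arms = next(a for g, a in counts.items() if len(a) == 2)
        ctrl = [a for a in mut_arms if "control" in a.lower()]
        if len(ctrl) != 1:
            raise ValueError("cannot infer the mutant control arm; pass control_groups")
        control_groups = (ref_arm, ctrl[0])

    plan = screen_sex_dependence(ds, alpha=alpha, scope=SCOPE_CONTROLS,
                                 control_groups=control_groups)
    sm = standardize(ds, plan)
    model = orient_pc1(fit_pca(sm), ds.battery)
    pc1 = model.scores[:, 0]

    groups = ds.data["group"].to_numpy()
    ctrl_mask = np.isin(groups, list(control_groups))
    k = min(n_pcs, model.scores.shape[1])
    labels, inertia = kmeans2(model.scores[ctrl_mask, :k], n_init=n_init, seed=seed)
    control_clustering = validate_clusters(
        labels, ds.genotypes[ctrl_mask],
        [i for i, m in zip(ds.animal_ids, ctrl_mask) if m],
        n_pcs_used=n_pcs, inertia=inertia)

    by_arm = {a: pc1[groups == a] for a in arms}
    anova = one_way_anova(list(by_arm.values()))
    tukey = tukey_hsd(by_arm)
    summaries = [
        ArmSummary(group=a, n=int(v.size), pc1_mean=float(v.mean()),
                   pc1_sem=float(v.std(ddof=1) / np.sqrt(v.size)))
        for a, v in by_arm.items()
    ]
    return TreatmentReport(arms=summaries, anova=anova, tukey=tukey,
                           control_clustering=control_clustering, plan=plan,
                           pc1_variance_fraction=float(model.variance_fraction[0]))


# ---------------------------------------------------------------------------
# Per-cohort runs
# ---------------------------------------------------------------------------

def per_cohort_runs(
    ds: BehaviorDataset,
    n_pcs: int = 2,
    seed: int = 0,
    plan: Optional[StandardizationPlan] = None,
    small_n_threshold: int = 5,
) -> list[CohortRun]:
    """Run the pipeline independently within each cohort.

    Cohorts with a single genotype are skipped with a warning.  Unless a
    plan is supplied, the sex screen is re-run within each cohort (falling
    back to pooled standardization when a cohort has one sex).
    """
    if not ds.has_cohorts:
        raise ValueError("per-cohort runs require a 'cohort' column")
    rng = np.random.default_rng(seed)
    runs = []
    for cohort in sorted(ds.data["cohort"].unique().tolist()):
        sub_df = ds.data[ds.data["cohort"] == cohort]
        if sub_df["genotype"].nunique() < 2:
            warnings.warn(f"cohort {cohort!r} has a single genotype; skipped")
            continue
        sub = BehaviorDataset(list(ds.battery), sub_df.copy())
        try:
            sub = complete_case_subset(sub)
        except ValueError:
            warnings.warn(f"cohort {cohort!r} has no complete batteries; skipped")
            continue
        if sub.data["genotype"].nunique() < 2:
            warnings.warn(f"cohort {cohort!r} has one genotype after complete cases; skipped")
            continue
        if plan is not None:
            cohort_plan = plan
        elif sub.data["sex"].nunique() == 2:
            try:
                cohort_plan = screen_sex_dependence(sub)
            except ValueError:
                cohort_plan = StandardizationPlan([])
        else:
            cohort_plan = StandardizationPlan([])
        _, cr = predict_genotype(sub, n_pcs=n_pcs, plan=cohort_plan,
                                 seed=_child_seed(rng))
        counts = sub.data["genotype"].value_counts().to_dict()
        runs.append(CohortRun(
            cohort=cohort,
            n_by_genotype={str(k): int(v) for k, v in counts.items()},
            accuracy=cr.accuracy,
            small_n=min(counts.values()) < small_n_threshold,
        ))
    return runs
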