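"""Experiment drivers: ablation, subset scan, partial profiles, bootstrap,
false-positive control, treatment analysis, and per-cohort runs."""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from phenoclust.data import BehaviorDataset, complete_case_subset
from phenoclust.embedding import predict_genotype
from phenoclust.experiments import (ablate_single, bootstrap_curve,
                                    false_positive_control,
                                    partial_profile_conditions,
                                    per_cohort_runs, scan_subsets,
                                    treatment_analysis)
from phenoclust.preprocess import StandardizationPlan, screen_sex_dependence
from phenoclust.simulate import default_config, generate


# ---------------------------------------------------------------------------
# Ablation
# ---------------------------------------------------------------------------

def test_ablate_default_condition_count(dataset1_like):
    """8 single measures + rotarod + open field + baseline = 11 conditions."""
    report = ablate_single(dataset1_like, seed=0)
    assert len(report.conditions) == 11
    base = [c for c in report.conditions if c.excluded == ()]
    assert len(base) == 1
    assert base[0].fisher_p_vs_baseline is None
    assert base[0].accuracy == report.baseline_accuracy
    for c in report.conditions:
        if c.excluded:
            assert 0.0 <= c.fisher_p_vs_baseline <= 1.0
            assert c.n_animals == base[0].n_animals  # same animal set


def test_ablate_null_measure_exclusion_harmless():
    """Dropping the no-effect measure (open-field center time) leaves
    accuracy statistically indistinguishable from baseline."""
    sig = 0
    n_seeds = 15
    for seed in range(n_seeds):
        ds, _ = generate(default_config(), seed=4000 + seed)
        report = ablate_single(ds, exclusions=[(), ("openfield_center_time",)],
                               seed=seed)
        cond = next(c for c in report.conditions if c.excluded)
        sig += cond.fisher_p_vs_baseline < 0.05
    assert sig <= 2


def test_ablate_dropping_strongest_measures_hurts():
    """Removing the two largest-effect measures lowers mean accuracy."""
    deltas = []
    for seed in range(25):
        ds, _ = generate(default_config(), seed=6000 + seed)
        report = ablate_single(
            ds, exclusions=[(), ("marbles_buried", "forced_swim_immobility")],
            seed=seed)
        cond = next(c for c in report.conditions if c.excluded)
        deltas.append(cond.accuracy - report.baseline_accuracy)
    assert np.mean(deltas) < 0.0


def test_ablate_error_cases(dataset1_like):
    with pytest.raises(ValueError, match="every measure"):
        ablate_single(dataset1_like,
                      exclusions=[tuple(dataset1_like.measures)])
    with pytest.raises(ValueError, match="fewer than 3"):
        ablate_single(dataset1_like,
                      exclusions=[tuple(dataset1_like.measures[:6])])
    with pytest.raises(ValueError, match="unknown measure"):
        ablate_single(dataset1_like, exclusions=[("bogus",)])


# ---------------------------------------------------------------------------
# Subset scan
# ---------------------------------------------------------------------------

def test_scan_enumeration_counts_small_battery():
    cfg = default_config(n_per_genotype=30)
    cfg = replace(cfg, measures=cfg.measures[:5])
    ds, _ = generate(cfg, seed=0)
    scan = scan_subsets(ds, k_min=3, k_max=5, seed=0)
    by_k = {s.n_measures: s.n_subsets for s in scan.summary}
    assert by_k == {3: math.comb(5, 3), 4: math.comb(5, 4), 5: 1}
    assert len(scan.records) == 16
    assert len({r.measures for r in scan.records}) == 16  # no duplicates


def test_scan_floor_and_bounds(dataset1_like):
    with pytest.raises(ValueError, match="floor"):
        scan_subsets(dataset1_like, k_min=2)
    with pytest.raises(ValueError, match="k_min"):
        scan_subsets(dataset1_like, k_min=5, k_max=3)


def test_scan_accuracy_grows_with_measures():
    """Mean accuracy is non-decreasing in battery size on average."""
    mean_by_k = {k: [] for k in (3, 8)}
    for seed in range(8):
        ds, _ = generate(default_config(), seed=8000 + seed)
        scan = scan_subsets(ds, seed=seed)
        for s in scan.summary:
            if s.n_measures in mean_by_k:
                mean_by_k[s.n_measures].append(s.mean_accuracy)
    assert np.mean(mean_by_k[8]) > np.mean(mean_by_k[3])


# ---------------------------------------------------------------------------
# Partial profiles
# ---------------------------------------------------------------------------

def test_partial_profiles_trade_measures_for_animals(dataset1_like):
    always_present = ["rotarod_day1", "rotarod_day5", "marbles_buried",
                      "forced_swim_immobility"]
    report = partial_profile_conditions(
        dataset1_like, [dataset1_like.measures, always_present], seed=0)
    full, partial = report.conditions
    assert full.n_animals == 170
    assert partial.n_animals == 286
    assert partial.n_measures == 4
    # consistency: the full-battery condition equals a direct pipeline run
    sub = complete_case_subset(dataset1_like)
    plan = screen_sex_dependence(dataset1_like)
    _, direct = predict_genotype(sub, n_pcs=2, plan=plan, seed=0)
    assert full.accuracy == pytest.approx(direct.accuracy)


def test_partial_profiles_fewer_measures_lower_accuracy():
    """More animals but fewer measures: accuracy still drops on average."""
    absent = ("weight", "openfield_distance", "openfield_center_time",
              "nest_building")
    kept = [m.name for m in default_config().measures if m.name not in absent]
    deltas = []
    for seed in range(20):
        cfg = default_config(
            cohort_sizes=[(22, 21)] * 4 + [(20, 20)] * 4,
            missingness_blocks={c: absent for c in range(4, 8)},
            seed=9000 + seed)
        ds, _ = generate(cfg)
        report = partial_profile_conditions(ds, [ds.measures, kept], seed=seed)
        full, partial = report.conditions
        assert partial.n_animals > full.n_animals
        deltas.append(partial.accuracy - full.accuracy)
    assert np.mean(deltas) < 0.0


def test_partial_profiles_minimum_measures(dataset1_like):
    with pytest.raises(ValueError, match="at least 3"):
        partial_profile_conditions(dataset1_like, [["weight", "rotarod_day1"]])


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_config_equals_direct_run(default_cohort):
    """Drawing every animal exactly once (without replacement, n = group
    size, one trial) reproduces the plain pipeline accuracy."""
    ds, _ = default_cohort
    curve = bootstrap_curve(ds, n_min=85, n_max=85, trials=1, seed=0,
                            replace=False)
    plan = screen_sex_dependence(ds)
    _, direct = predict_genotype(complete_case_subset(ds), plan=plan, seed=0)
    assert curve.mean_accuracy[0] == pytest.approx(direct.accuracy, abs=1e-9)


def test_bootstrap_reproducible_across_seeds(default_cohort):
    """Per-n means from independent seeds agree within Monte-Carlo error."""
    ds, _ = default_cohort
    trials = 150
    c1 = bootstrap_curve(ds, n_min=8, n_max=10, trials=trials, seed=1)
    c2 = bootstrap_curve(ds, n_min=8, n_max=10, trials=trials, seed=2)
    for m1, m2, s1 in zip(c1.mean_accuracy, c2.mean_accuracy, c1.sd_accuracy):
        se = s1 / np.sqrt(trials)
        assert abs(m1 - m2) < 3 * np.sqrt(2) * se + 0.5


def test_bootstrap_small_n_uses_pooled_fallback(default_cohort):
    """At n = 3 per genotype, resamples often lack one sex entirely, so
    sex-stratified measures must fall back to pooled standardization."""
    ds, _ = default_cohort
    curve = bootstrap_curve(ds, n_min=3, n_max=3, trials=50, seed=0)
    assert curve.pooled_fallbacks > 0
    assert all(50.0 <= a <= 100.0 for a in curve.mean_accuracy)


def test_bootstrap_requires_two_genotypes(null_females):
    with pytest.raises(ValueError, match="2 genotypes"):
        bootstrap_curve(null_females, n_min=3, n_max=4, trials=2)


# ---------------------------------------------------------------------------
# False-positive control
# ---------------------------------------------------------------------------

def test_false_positive_deterministic(null_females):
    r1 = false_positive_control(null_females, trials=3, seed=5,
                                keep_accuracies=True)
    r2 = false_positive_control(null_females, trials=3, seed=5,
                                keep_accuracies=True)
    assert r1.accuracies == r2.accuracies


def test_false_positive_requires_single_genotype(default_cohort):
    ds, _ = default_cohort
    with pytest.raises(ValueError, match="single-genotype"):
        false_positive_control(ds, trials=2)


def test_false_positive_randomized_labels_near_chance(default_cohort):
    """Even on data with a huge true separation, random pseudo-labels carry
    no information, so the control stays near the chance level."""
    ds, _ = default_cohort
    df = ds.data.iloc[:36].copy()
    df["genotype"] = "X"
    homog = BehaviorDataset(list(ds.battery), df)
    rep = false_positive_control(homog, trials=120, seed=0)
    assert rep.mean_accuracy < 65.0
    assert rep.chance_band is not None


# ---------------------------------------------------------------------------
# Treatment analysis
# ---------------------------------------------------------------------------

def test_treatment_basic_run(dataset3_like):
    report = treatment_analysis(dataset3_like, seed=0)
    assert {a.group for a in report.arms} == {"WT+control", "AS+control",
                                              "AS+treatment"}
    assert report.anova["group"].p < 1e-4
    assert len(report.tukey) == 3
    assert report.control_clustering.n_pcs_used == 1
    # screening used the control arms only
    assert report.plan.screening_scope == "control-groups-only"
    means = {a.group: a.pc1_mean for a in report.arms}
    assert means["WT+control"] < means["AS+treatment"] < means["AS+control"]


def test_treatment_requires_three_arms(default_cohort):
    ds, _ = default_cohort
    with pytest.raises(ValueError, match="group"):
        treatment_analysis(ds)
    cfg = default_config(arm_sizes=(20, 20, 20))
    ds3, _ = generate(cfg, seed=0)
    two = BehaviorDataset(list(ds3.battery),
                          ds3.data[ds3.data["group"] != "AS+treatment"].copy())
    with pytest.raises(ValueError, match="3 treatment arms"):
        treatment_analysis(two)


# ---------------------------------------------------------------------------
# Per-cohort runs
# ---------------------------------------------------------------------------

def test_per_cohort_single_cohort_equals_direct(default_cohort):
    ds, _ = default_cohort
    runs = per_cohort_runs(ds, seed=0)
    assert len(runs) == 1
    plan = screen_sex_dependence(ds)
    _, direct = predict_genotype(complete_case_subset(ds), plan=plan, seed=0)
    assert runs[0].accuracy == pytest.approx(direct.accuracy)
    assert not runs[0].small_n


def test_per_cohort_small_n_flag_and_skip():
    cfg = default_config(cohort_sizes=[(3, 3), (10, 10), (5, 0)])
    ds, _ = generate(cfg, seed=1)
    with pytest.warns(UserWarning, match="single genotype"):
        runs = per_cohort_runs(ds, seed=0)
    assert len(runs) == 2
    flags = {r.cohort: r.small_n for r in runs}
    assert flags["C01"] is True
    assert flags["C02"] is False


def test_per_cohort_outperforms_pooled_bootstrap(dataset1_like):
    """Within-cohort runs avoid inter-cohort variability, so their accuracy
    meets or beats the pooled bootstrap at matched n."""
    runs = per_cohort_runs(dataset1_like, seed=0)
    matched_n = int(round(np.mean([min(r.n_by_genotype.values()) for r in runs])))
    curve = bootstrap_curve(dataset1_like, n_min=matched_n, n_max=matched_n,
                            trials=300, seed=0)
    assert np.mean([r.accuracy for r in runs]) >= curve.mean_accuracy[0] - 1.0
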