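"""Standardization step: sex-dependence screening, z-scoring, PC outlier exclusion.

Measures showing a sex main effect or a sex x genotype interaction (two-way
ANOVA at ``alpha``) are z-scored separately within males and females; all
other measures are z-scored over the whole group.  Standardization absorbs
units, so the downstream analysis is invariant to positive affine rescaling
of any raw measure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import BehaviorDataset, complete_case_subset
from .stats import grubbs_test, two_way_anova

SCOPE_ALL = "all-animals"
SCOPE_CONTROLS = "control-groups-only"


@dataclass
class StandardizationPlan:
    """Which measures are z-scored per sex, and how that was decided."""

    sex_stratified: list[str] = field(default_factory=list)
    screening_alpha: float = 0.05
    screening_scope: str = SCOPE_ALL

    def __post_init__(self) -> None:
        if not 0 < self.screening_alpha < 1:
            raise ValueError("screening alpha must be in (0, 1)")
        self.sex_stratified = sorted(set(self.sex_stratified))


@dataclass
class StandardizedMatrix:
    animal_ids: list[str]
    measure_names: list[str]
    Z: np.ndarray
    plan: StandardizationPlan


def screen_sex_dependence(
    ds: BehaviorDataset,
    alpha: float = 0.05,
    scope: str = SCOPE_ALL,
    control_groups: Optional[Sequence[str]] = None,
) -> StandardizationPlan:
    """Flag measures whose sex main effect or sex x genotype interaction is
    significant at ``alpha``.

    Each measure is screened on its own complete cases from the full dataset
    (measures recorded in more cohorts use their larger n), not on the
    complete-battery subset.  With ``scope=SCOPE_CONTROLS`` only animals in
    ``control_groups`` enter the screen, as in a treatment workflow where the
    treated arm must not influence standardization.
    """
    df = ds.data
    if scope == SCOPE_CONTROLS:
        if not ds.has_groups or control_groups is None:
            raise ValueError("control-group screening requires a 'group' column "
                             "and an explicit control_groups list")
        df = df[df["group"].isin(list(control_groups))]
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes required to screen sex dependence")
    if df["genotype"].nunique() < 2:
        raise ValueError("both genotypes required to screen sex dependence")
    flagged = []
    for name in ds.measures:
        sub = df[df[name].notna()]
        cells = sub.groupby(["sex", "genotype"], observed=True).size()
        if len(cells) < 4:
            raise ValueError(f"empty sex x genotype cell for measure {name!r}")
        table = two_way_anova(sub[name].to_numpy(), sub["sex"], sub["genotype"])
        if table["A"].p < alpha or table["A:B"].p < alpha:
            flagged.append(name)
    return StandardizationPlan(flagged, screening_alpha=alpha, screening_scope=scope)


def standardize(ds: BehaviorDataset, plan: StandardizationPlan) -> StandardizedMatrix:
    """z = (value - group mean) / group sample sd (n-1 denominator).

    The group is all animals for unstratified measures and each sex for
    stratified ones.  The dataset must be complete-case for its battery
    (apply :func:`complete_case_subset` first).
    """
    unknown = set(plan.sex_stratified) - set(ds.measures)
    if unknown:
        raise ValueError(f"plan stratifies unknown measures: {sorted(unknown)}")
    X = ds.values_matrix()
    if np.isnan(X).any():
        raise ValueError("dataset has missing values; take a complete-case subset first")
    sexes = ds.sexes
    Z = np.empty_like(X)
    strat = set(plan.sex_stratified)
    for j, name in enumerate(ds.measures):
        col = X[:, j]
        if name in strat:
            for sex in np.unique(sexes):
                m = sexes == sex
                _zscore_into(col, m, Z, j, f"{name!r} in sex group {sex!r}")
        else:
            _zscore_into(col, np.ones(col.size, dtype=bool), Z, j, repr(name))
    return StandardizedMatrix(ds.animal_ids, list(ds.measures), Z, plan)


def _zscore_into(col, mask, Z, j, label) -> None:
    vals = col[mask]
    if vals.size < 2:
        raise ValueError(f"standardization group for {label} has fewer than 2 animals")
    sd = vals.std(ddof=1)
    if sd <= 0:
        raise ValueError(f"zero standard deviation for {label}")
    Z[mask, j] = (vals - vals.mean()) / sd


def exclude_pc_outliers(
    ds: BehaviorDataset,
    plan: StandardizationPlan,
    n_pcs: int = 2,
    alpha: float = 0.05,
) -> tuple[BehaviorDataset, list[str]]:
    """Grubbs-screen the first ``n_pcs`` principal-component score columns
    and drop the flagged animals (single pass, no iteration).

    Downstream analyses should re-standardize and re-fit the PCA on the
    reduced dataset.
    """
    from .embedding import fit_pca  # local import to avoid a cycle

    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    sm = standardize(ds, plan)
    model = fit_pca(sm)
    k = min(n_pcs, model.scores.shape[1])
    flagged_idx = set()
    for j in range(k):
        res = grubbs_test(model.scores[:, j], alpha=alpha)
        if res.flagged:
            flagged_idx.add(res.index)
    flagged_ids = [sm.animal_ids[i] for i in sorted(flagged_idx)]
    if not flagged_ids:
        return ds, []
    keep = ~ds.data["animal_id"].isin(flagged_ids).to_numpy()
    if keep.sum() < 2:
        warnings.warn("outlier screen would leave <2 animals; skipping exclusion")
        return ds, []
    return ds.select_rows(keep), flagged_ids
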