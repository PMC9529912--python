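"""Model/Results front end for the multidimensional behavioral analysis.

`BehaviorClusterModel` bundles the full pipeline — sex-dependence screening,
(optionally sex-stratified) z-standardization, optional Grubbs outlier
exclusion in PC space, PCA, k-means clustering and genotype validation —
behind a fit() that returns a `BehaviorClusterResults` carrying the
estimates (loadings, variance fractions, severity scores, clustering
accuracy) and a text summary().
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import BehaviorDataset, MeasureSpec, complete_case_subset
from .embedding import (DEFAULT_N_INIT, ClusteringResult, PCAModel,
                        predict_genotype)
from .preprocess import (StandardizationPlan, exclude_pc_outliers,
                         screen_sex_dependence)


class BehaviorClusterModel:
    """Genotype prediction from a behavioral battery.

    Parameters
    ----------
    dataset
        Behavioral cohort; animals with missing battery measures are dropped
        (complete-case analysis).
    n_pcs
        Number of principal components used for clustering (default 2; one
        PC treats PC1 as a composite severity score).
    sex_alpha
        Significance level of the two-way (sex x genotype) ANOVA screen that
        decides which measures are standardized per sex.
    outlier_alpha
        When set, animals flagged by a two-sided Grubbs test on the first
        ``n_pcs`` PC score columns are excluded (single pass) and the
        pipeline is re-run on the reduced cohort.
    plan
        Pre-computed standardization plan; overrides the screen.
    """

    def __init__(
        self,
        dataset: BehaviorDataset,
        n_pcs: int = 2,
        sex_alpha: float = 0.05,
        outlier_alpha: Optional[float] = None,
        plan: Optional[StandardizationPlan] = None,
        n_init: int = DEFAULT_N_INIT,
    ) -> None:
        self.dataset = dataset
        self.n_pcs = n_pcs
        self.sex_alpha = sex_alpha
        self.outlier_alpha = outlier_alpha
        self.plan = plan
        self.n_init = n_init

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, battery: Sequence[MeasureSpec],
                       **kwargs) -> "BehaviorClusterModel":
        return cls(BehaviorDataset(list(battery), df.copy()), **kwargs)

    def fit(self, seed: int = 0) -> "BehaviorClusterResults":
        ds = complete_case_subset(self.dataset)
        plan = self.plan
        if plan is None:
            # screen on the full dataset so each measure uses its own
            # complete cases (measures present in more cohorts keep their n)
            plan = screen_sex_dependence(self.dataset, alpha=self.sex_alpha)
        excluded: list[str] = []
        if self.outlier_alpha is not None:
            ds, excluded = exclude_pc_outliers(ds, plan, n_pcs=self.n_pcs,
                                               alpha=self.outlier_alpha)
        pca, clustering = predict_genotype(ds, n_pcs=self.n_pcs, plan=plan,
                                           seed=seed, n_init=self.n_init)
        return BehaviorClusterResults(self, ds, plan, pca, clustering,
                                      excluded_outliers=excluded, seed=seed)


@dataclass
class BehaviorClusterResults:
    """Fitted pipeline: standardization plan, PCA, clustering, validation."""

    model: BehaviorClusterModel
    dataset: BehaviorDataset
    plan: StandardizationPlan
    pca: PCAModel
    clustering: ClusteringResult
    excluded_outliers: list[str]
    seed: int

    @property
    def accuracy(self) -> float:
        return self.clustering.accuracy

    @property
    def severity(self) -> pd.Series:
        """Per-animal PC1 severity score (higher = more impaired)."""
        return pd.Series(self.pca.scores[:, 0], index=self.pca.animal_ids,
                         name="pc1_severity")

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.pca.n_components)]
        return pd.DataFrame(self.pca.loadings, index=self.pca.measure_names,
                            columns=cols)

    def scree_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.pca.variance_fraction.size + 1),
            "variance_fraction": self.pca.variance_fraction,
        })

    def scores_frame(self) -> pd.DataFrame:
        """Per-animal PC scores with genotype, cluster and error flags."""
        mapping = self.clustering.mapping
        labels = np.asarray(self.clustering.labels)
        df = pd.DataFrame(self.pca.scores[:, :max(2, self.clustering.n_pcs_used)],
                          columns=[f"PC{j + 1}" for j in
                                   range(max(2, self.clustering.n_pcs_used))])
        df.insert(0, "animal_id", self.pca.animal_ids)
        df["genotype"] = self.dataset.genotypes
        df["cluster"] = labels
        df["predicted_genotype"] = [mapping[l] for l in labels]
        df["misclassified"] = df["animal_id"].isin(self.clustering.misclassified)
        return df

    def summary(self) -> str:
        ds, cl, pca = self.dataset, self.clustering, self.pca
        counts = ds.data["genotype"].value_counts().to_dict()
        lines = [
            "Multidimensional Behavioral Analysis",
            "=" * 52,
            f"Animals (complete cases)  {ds.n_animals:>6}   "
            + "  ".join(f"{g}: {n}" for g, n in sorted(counts.items())),
            f"Measures                  {len(ds.measures):>6}",
            f"PCs used for clustering   {cl.n_pcs_used:>6}",
            f"Sex-stratified measures   {len(self.plan.sex_stratified):>6}   "
            + (", ".join(self.plan.sex_stratified) or "(none)"),
            f"Outliers excluded         {len(self.excluded_outliers):>6}   "
            + (", ".join(self.excluded_outliers) or "(none)"),
            "-" * 52,
            f"Clustering accuracy       {cl.accuracy:>9.2f} %",
            f"Misclassified animals     {len(cl.misclassified):>6}",
            f"Cluster mapping           " + ", ".join(
                f"cluster {k} -> {v}" for k, v in sorted(cl.mapping.items())),
            "-" * 52,
            "Variance explained:  " + "  ".join(
                f"PC{j + 1} {100 * f:.1f}%" for j, f in
                enumerate(pca.variance_fraction[:4])),
            "PC1 loadings (severity orientation):",
        ]
        for name, w in zip(pca.measure_names, pca.loadings[:, 0]):
            lines.append(f"    {name:<26}{w:>8.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<BehaviorClusterResults accuracy={self.accuracy:.2f}% "
                f"n={self.dataset.n_animals} n_pcs={self.clustering.n_pcs_used}>")
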