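"""PCA, k-means in PC space, and cluster-to-genotype validation.

The pipeline here is the core of multidimensional behavioral analysis: the
standardized animals x measures matrix is rotated onto its principal axes,
animals are split into k = 2 clusters in the space of the first ``n_pcs``
score columns, and the clusters are compared with the true genotypes under
the best of the two possible cluster-to-genotype mappings.

PC1 doubles as a composite severity score: its sign is fixed so that higher
PC1 means more impaired, using the battery's per-measure impairment
directions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .data import BehaviorDataset, MeasureSpec
from .preprocess import StandardizationPlan, StandardizedMatrix, screen_sex_dependence, standardize

DEFAULT_N_INIT = 50


@dataclass
class PCAModel:
    """Principal axes of a centered standardized matrix.

    ``loadings`` is measures x components with orthonormal columns;
    ``scores = centered Z @ loadings``; ``variance_fraction`` sums to 1 over
    all retained components.  ``orientation`` records the sign convention
    applied ("largest-loading-positive", optionally "+pc1-severity").
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    measure_names: list[str]
    animal_ids: list[str]
    orientation: str = "largest-loading-positive"

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ClusteringResult:
    labels: list[int]
    mapping: dict[int, str]
    accuracy: float
    misclassified: list[str]
    n_pcs_used: int
    inertia: float


def fit_pca(Z: StandardizedMatrix | np.ndarray,
            measure_names: Optional[list[str]] = None,
            animal_ids: Optional[list[str]] = None) -> PCAModel:
    """PCA by SVD of the column-centered matrix.

    Component signs follow the largest-|loading|-positive convention so the
    decomposition is deterministic; PC1's sign is subsequently overridden by
    :func:`orient_pc1` where a severity interpretation is wanted.
    """
    if isinstance(Z, StandardizedMatrix):
        X, measure_names, animal_ids = Z.Z, Z.measure_names, Z.animal_ids
    else:
        X = np.asarray(Z, dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("PCA needs at least 2 animals and 2 measures")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in standardized matrix")
    Xc = X - X.mean(axis=0)
    if not Xc.any():
        raise ValueError("matrix has rank 0 after centering")
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        i = int(np.abs(loadings[:, j]).argmax())
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var = S**2 / max(n - 1, 1)
    total = var.sum()
    scores = Xc @ loadings
    return PCAModel(
        loadings=loadings,
        scores=scores,
        variance_fraction=var / total,
        measure_names=list(measure_names) if measure_names else [f"m{j}" for j in range(m)],
        animal_ids=list(animal_ids) if animal_ids else [str(i) for i in range(n)],
    )


def orient_pc1(model: PCAModel, specs: Sequence[MeasureSpec]) -> PCAModel:
    """Flip PC1 if needed so higher PC1 = more impaired.

    The criterion is the sign of sum_j loading_{j,1} * impairment_direction_j.
    A zero dot product leaves the sign unchanged with a warning.
    """
    by_name = {s.name: s for s in specs}
    try:
        dirs = np.array([by_name[n].impairment_direction for n in model.measure_names], float)
    except KeyError as e:
        raise ValueError(f"no MeasureSpec for model measure {e.args[0]!r}") from None
    dot = float(model.loadings[:, 0] @ dirs)
    if dot == 0.0:
        warnings.warn("PC1 loading / impairment-direction dot product is zero; "
                      "severity orientation left unchanged")
        return model
    if dot < 0:
        loadings = model.loadings.copy()
        scores = model.scores.copy()
        loadings[:, 0] = -loadings[:, 0]
        scores[:, 0] = -scores[:, 0]
        model = replace(model, loadings=loadings, scores=scores)
    return replace(model, orientation=model.orientation + "+pc1-severity")


# ---------------------------------------------------------------------------
# k-means, k = 2
# ---------------------------------------------------------------------------

def kmeans2(points: np.ndarray, n_init: int = DEFAULT_N_INIT, seed: int = 0,
            max_iter: int = 300) -> tuple[np.ndarray, float]:
    """Lloyd's algorithm with k = 2 from ``n_init`` k-means++ seedings.

    Returns the labeling (values in {1, 2}) with minimal within-cluster sum
    of squares across restarts.  All restarts are run simultaneously as a
    vectorized batch, which keeps tens of thousands of small bootstrap
    replicates cheap.  Deterministic given ``seed``.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(X, axis=0).max() == 0:
        raise ValueError("all points are identical")
    rng = np.random.default_rng(seed)
    R = int(n_init)

    first = rng.integers(0, n, size=R)
    c0 = X[first]                                        # (R, d)
    d2 = ((X[None, :, :] - c0[:, None, :]) ** 2).sum(-1)  # (R, n)
    cum = np.cumsum(d2, axis=1)
    u = rng.random(R) * cum[:, -1]
    second = np.minimum((cum < u[:, None]).sum(1), n - 1)
    C = np.stack([c0, X[second]], axis=1)                # (R, 2, d)

    prev = np.full((R, n), -1, dtype=np.int8)
    total = X.sum(axis=0)
    for _ in range(max_iter):
        dist = ((X[None, None, :, :] - C[:, :, None, :]) ** 2).sum(-1)  # (R, 2, n)
        assign = dist.argmin(axis=1).astype(np.int8)
        if np.array_equal(assign, prev):
            break
        prev = assign
        m1 = assign.astype(float)                         # 1.0 where cluster 2
        cnt1 = m1.sum(axis=1)
        cnt0 = n - cnt1
        s1 = m1 @ X
        s0 = total[None, :] - s1
        new0 = np.where(cnt0[:, None] > 0, s0 / np.maximum(cnt0, 1)[:, None], C[:, 0, :])
        new1 = np.where(cnt1[:, None] > 0, s1 / np.maximum(cnt1, 1)[:, None], C[:, 1, :])
        C = np.stack([new0, new1], axis=1)

    dist = ((X[None, None, :, :] - C[:, :, None, :]) ** 2).sum(-1)
    assign = dist.argmin(axis=1)
    inertia = dist.min(axis=1).sum(axis=1)
    best = int(inertia.argmin())
    return assign[best].astype(int) + 1, float(inertia[best])


def validate_clusters(
    labels: Sequence[int],
    genotypes: Sequence[str],
    animal_ids: Optional[Sequence[str]] = None,
    n_pcs_used: int = 0,
    inertia: float = float("nan"),
) -> ClusteringResult:
    """Best-of-two cluster-to-genotype mapping and percent accuracy.

    Ties (only possible at exactly 50%) resolve to mapping cluster 1 onto the
    alphabetically first genotype, for determinism.
    """
    labels = np.asarray(labels, dtype=int)
    genos = np.asarray(genotypes)
    levels = sorted(np.unique(genos).tolist())
    if len(levels) != 2:
        raise ValueError(f"exactly 2 genotype levels required, got {levels}")
    if animal_ids is None:
        animal_ids = [str(i) for i in range(labels.size)]
    n = labels.size
    # agreement under mapping {1 -> levels[0], 2 -> levels[1]}
    m_direct = int(((labels == 1) & (genos == levels[0])).sum()
                   + ((labels == 2) & (genos == levels[1])).sum())
    if m_direct >= n - m_direct:
        mapping = {1: levels[0], 2: levels[1]}
        agreements = m_direct
    else:
        mapping = {1: levels[1], 2: levels[0]}
        agreements = n - m_direct
    predicted = np.where(labels == 1, mapping[1], mapping[2])
    wrong = predicted != genos
    return ClusteringResult(
        labels=labels.tolist(),
        mapping=mapping,
        accuracy=100.0 * agreements / n,
        misclassified=[animal_ids[i] for i in np.flatnonzero(wrong)],
        n_pcs_used=n_pcs_used,
        inertia=inertia,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def predict_genotype(
    ds: BehaviorDataset,
    n_pcs: int = 2,
    plan: Optional[StandardizationPlan] = None,
    seed: int = 0,
    n_init: int = DEFAULT_N_INIT,
) -> tuple[PCAModel, ClusteringResult]:
    """standardize -> PCA -> orient PC1 -> k-means on the first ``n_pcs``
    score columns -> validate against genotype.

    ``ds`` must be complete-case for its battery.  When ``plan`` is None the
    sex-dependence screen is run on ``ds`` itself.
    """
    if not 1 <= n_pcs <= len(ds.measures):
        raise ValueError(f"n_pcs must be in [1, {len(ds.measures)}]")
    if plan is None:
        plan = screen_sex_dependence(ds)
    sm = standardize(ds, plan)
    model = orient_pc1(fit_pca(sm), ds.battery)
    k = min(n_pcs, model.scores.shape[1])
    labels, inertia = kmeans2(model.scores[:, :k], n_init=n_init, seed=seed)
    result = validate_clusters(labels, ds.genotypes, ds.animal_ids,
                               n_pcs_used=n_pcs, inertia=inertia)
    return model, result
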