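"""Statistical primitives used throughout the pipeline.

Two-way ANOVA (Type II sums of squares, for the sex-dependence screen),
one-way ANOVA with Tukey-Kramer post hoc (treatment analysis in severity
space), Fisher's exact 2x2 (comparing clustering accuracies between
conditions) and Grubbs' outlier test (screening principal-component scores).

The two-way ANOVA is computed by model-comparison least squares on dummy
design matrices rather than through a formula interface: the sex screen runs
inside simulation loops with thousands of replicates, so per-call overhead
matters.  Type II is used for unbalanced designs (each main effect adjusted
for the other; the interaction adjusted for both), the conventional default
for factorial behavioral data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class AnovaTerm:
    term: str
    sum_sq: float
    df: int
    F: float
    p: float


@dataclass
class AnovaTable:
    terms: list[AnovaTerm]
    residual_sum_sq: float
    residual_df: int

    def __getitem__(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    adjusted_p: float


@dataclass
class GrubbsResult:
    """Two-sided Grubbs test: flags the single most extreme value if
    G = max|x - mean|/sd exceeds the critical value at ``alpha``."""

    index: Optional[int]
    G: float
    G_crit: float
    alpha: float

    @property
    def flagged(self) -> bool:
        return self.index is not None


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(y: Sequence[float], factor_a: Sequence, factor_b: Sequence) -> AnovaTable:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Every cell of the a x b design must contain at least one observation and
    the residual degrees of freedom must be positive.
    """
    y = np.asarray(y, dtype=float)
    a_codes, a_levels = _codes(factor_a)
    b_codes, b_levels = _codes(factor_b)
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("each factor needs at least two levels")
    cell_counts = np.zeros((na, nb), dtype=int)
    np.add.at(cell_counts, (a_codes, b_codes), 1)
    if (cell_counts == 0).any():
        ia, ib = np.argwhere(cell_counts == 0)[0]
        raise ValueError(f"empty design cell: {a_levels[ia]!r} x {b_levels[ib]!r}")
    n = y.size
    df_res = n - na * nb
    if df_res < 1:
        raise ValueError("residual degrees of freedom < 1")

    one = np.ones((n, 1))
    A = _dummies(a_codes, na)
    B = _dummies(b_codes, nb)
    AB = np.einsum("ij,ik->ijk", A, B).reshape(n, -1)

    rss_full = _rss(np.hstack([one, A, B, AB]), y)
    rss_ab = _rss(np.hstack([one, A, B]), y)
    rss_a = _rss(np.hstack([one, A]), y)
    rss_b = _rss(np.hstack([one, B]), y)

    ms_res = rss_full / df_res
    if rss_full <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("zero residual variance")

    def term(name: str, ss: float, df: int) -> AnovaTerm:
        ss = max(ss, 0.0)
        F = (ss / df) / ms_res
        return AnovaTerm(name, ss, df, F, float(sps.f.sf(F, df, df_res)))

    terms = [
        term("A", rss_b - rss_ab, na - 1),
        term("B", rss_a - rss_ab, nb - 1),
        term("A:B", rss_ab - rss_full, (na - 1) * (nb - 1)),
    ]
    return AnovaTable(terms, rss_full, df_res)


def _codes(factor: Sequence) -> tuple[np.ndarray, list]:
    arr = np.asarray(factor)
    levels, codes = np.unique(arr, return_inverse=True)
    return codes, levels.tolist()


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Classical between/within one-way decomposition."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than two values")
    all_y = np.concatenate(gs)
    grand = all_y.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    df_b = len(gs) - 1
    df_w = all_y.size - len(gs)
    if df_w < 1:
        raise ValueError("residual degrees of freedom < 1")
    tol = 1e-12 * max(1.0, float(all_y @ all_y))
    if ss_within <= tol:
        if ss_between <= tol:
            F, p = 0.0, 1.0
        else:
            raise ValueError("zero within-group variance")
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaTable([AnovaTerm("group", float(ss_between), df_b, float(F), p)],
                      float(ss_within), df_w)


def tukey_hsd(groups: dict[str, Sequence[float]]) -> list[PairwiseComparison]:
    """Tukey-Kramer all-pairs comparisons via the studentized-range
    distribution (unequal n handled by the Kramer correction)."""
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    one_way_anova(arrays)  # enforce shared preconditions
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                PairwiseComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                    adjusted_p=float(min(1.0, res.pvalue[i, j])),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table, by summing
    hypergeometric point probabilities no larger than the observed one."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("negative cell count")
    if not np.all(arr == np.floor(arr)):
        raise ValueError("non-integer cell count")
    if arr.sum() < 1:
        raise ValueError("grand total must be >= 1")
    return float(sps.fisher_exact(arr.astype(np.int64), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Grubbs' test
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value:
    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_test(x: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = x.std(ddof=1)
    if sd <= 0:
        raise ValueError("zero standard deviation")
    dev = np.abs(x - x.mean())
    idx = int(dev.argmax())
    G = float(dev[idx] / sd)
    crit = grubbs_critical(x.size, alpha)
    return GrubbsResult(index=idx if G > crit else None, G=G, G_crit=crit, alpha=alpha)
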