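"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route independent of the package
implementation it checks: nested-model least squares by normal equations for
the two-way ANOVA, exact rational enumeration for Fisher's test, double
quadrature of the studentized-range distribution for Tukey p-values, and
exhaustive 2-partition enumeration for k-means.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import integrate
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Two-way ANOVA via normal equations on nested models
# ---------------------------------------------------------------------------

def _rss_normal_eq(X: np.ndarray, y: np.ndarray) -> float:
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    r = y - X @ beta
    return float(r @ r)


def _onehot(labels, drop_first: bool) -> np.ndarray:
    levels = sorted(set(labels))
    cols = levels[1:] if drop_first else levels
    return np.column_stack([[1.0 if l == c else 0.0 for l in labels] for c in cols])


def two_way_anova_type2_oracle(y, a, b):
    """Type II F and p for main effects and interaction, by comparing
    residual sums of squares of nested linear models."""
    y = np.asarray(y, float)
    n = y.size
    one = np.ones((n, 1))
    A = _onehot(a, drop_first=True)
    B = _onehot(b, drop_first=True)
    # cell-means parametrization for the full model (always full rank)
    cells = [f"{ai}|{bi}" for ai, bi in zip(a, b)]
    C = _onehot(cells, drop_first=False)
    rss_full = _rss_normal_eq(C, y)
    rss_ab = _rss_normal_eq(np.hstack([one, A, B]), y)
    rss_a = _rss_normal_eq(np.hstack([one, A]), y)
    rss_b = _rss_normal_eq(np.hstack([one, B]), y)
    na = A.shape[1] + 1
    nb = B.shape[1] + 1
    df_res = n - na * nb
    ms = rss_full / df_res
    out = {}
    for name, ss, df in (("A", rss_b - rss_ab, na - 1),
                         ("B", rss_a - rss_ab, nb - 1),
                         ("A:B", rss_ab - rss_full, (na - 1) * (nb - 1))):
        F = (ss / df) / ms
        out[name] = (F, float(sps.f.sf(F, df, df_res)))
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test by exact rational enumeration
# ---------------------------------------------------------------------------

def fisher_exact_oracle(table) -> float:
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                        math.comb(N, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Studentized-range CDF by double quadrature
# ---------------------------------------------------------------------------

def studentized_range_cdf_oracle(q: float, k: int, df: int) -> float:
    """P(Q <= q) for the range of k standard normals divided by an
    independent chi(df)/sqrt(df) scale, by direct numerical integration."""
    phi = sps.norm.pdf
    Phi = sps.norm.cdf

    def inner(s: float) -> float:
        def f(z):
            return k * phi(z) * (Phi(z) - Phi(z - q * s)) ** (k - 1)
        val, _ = integrate.quad(f, -9.0, 9.0 + q * s, limit=200)
        return val

    # density of S = chi_df / sqrt(df)
    log_c = (df / 2) * math.log(df) - (df / 2 - 1) * math.log(2) - math.lgamma(df / 2)

    def outer(s):
        log_f = log_c + (df - 1) * math.log(s) - df * s * s / 2
        return math.exp(log_f) * inner(s)

    val, _ = integrate.quad(outer, 1e-9, 10.0, limit=200)
    return min(val, 1.0)


def tukey_p_oracle(groups: list[np.ndarray], i: int, j: int) -> float:
    """Tukey-Kramer adjusted p for the (i, j) pair via the quadrature CDF."""
    k = len(groups)
    df = sum(g.size for g in groups) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    gi, gj = groups[i], groups[j]
    se = math.sqrt(msw / 2 * (1 / gi.size + 1 / gj.size))
    q = abs(gi.mean() - gj.mean()) / se
    return 1.0 - studentized_range_cdf_oracle(q, k, df)


# ---------------------------------------------------------------------------
# Exhaustive optimal 2-partition
# ---------------------------------------------------------------------------

def brute_force_2partition_inertia(points: np.ndarray) -> float:
    """Minimal within-cluster sum of squares over all 2-partitions with two
    non-empty parts (point 0 fixed in part 0 to halve the enumeration)."""
    X = np.asarray(points, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    best = math.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        mask = np.concatenate([[False], mask[: n - 1]])
        for part in (X[mask], X[~mask]):
            if part.size == 0:
                break
        a, b = X[mask], X[~mask]
        inertia = (((a - a.mean(0)) ** 2).sum() + ((b - b.mean(0)) ** 2).sum())
        best = min(best, inertia)
    return float(best)
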