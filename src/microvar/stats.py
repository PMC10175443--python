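"""Statistical battery for distance-based and univariate group comparisons.

All procedures are implemented here directly from their defining formulas —
permutational multivariate ANOVA (pseudo-F on a distance matrix with a
label-permutation p-value), the homogeneity-of-dispersions test (distances
to group centroids in PCoA space with Anderson's negative-axis correction),
Kruskal-Wallis with tie correction, Dunn's pairwise post-hoc z tests,
additive two-way ANOVA with Type-II sums of squares, the pooled-variance
two-sample t-test and Benjamini-Hochberg step-up adjustment.  scipy supplies
only rank computation and reference distributions (chi-square, normal, t, F).

Permutation p-values use the (count + 1) / (n_perm + 1) convention, so 999
permutations bottom out at p = 0.001.  Passing ``n_perm="all"`` enumerates
every label permutation and returns the exact proportion instead.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    """One test outcome: statistic, degrees of freedom, p-value and friends."""

    method: str
    statistic: float
    df: tuple[float, ...] = ()
    p_value: float = float("nan")
    r_squared: float | None = None
    p_adjusted: float | None = None
    n_permutations: int | None = None
    comparison: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": None if math.isnan(self.statistic) else self.statistic,
            "df": list(self.df),
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "r_squared": self.r_squared,
            "p_adjusted": self.p_adjusted,
            "n_permutations": self.n_permutations,
            "comparison": list(self.comparison),
        }


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.data
    mat = np.asarray(D, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise StatsError("distance matrix must be square")
    return mat


def _group_indices(groups) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(groups))
    cats = sorted(labels.unique(), key=str)
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    return codes, cats


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """One-factor pseudo-F and R^2 from squared dissimilarities."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    a = n_groups
    if ss_within <= 0 or n - a <= 0:
        return float("nan"), (ss_between / ss_total if ss_total > 0 else float("nan"))
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else float("nan")
    return f, r2


def permanova(
    D,
    groups,
    n_perm: int | str = 999,
    rng: np.random.Generator | None = None,
) -> StatResult:
    """One-factor PERMANOVA on a distance matrix.

    ``SS_total = sum_{i<j} d_ij^2 / n``; ``SS_within`` sums the analogous
    within-group terms; ``F = (SS_between/(a-1)) / (SS_within/(n-a))`` and
    ``R^2 = SS_between / SS_total``.  The p-value permutes group labels:
    sampled with the +1/+1 convention, or exhaustively over all n! label
    orders when ``n_perm="all"``.
    """
    mat = _as_matrix(D)
    codes, cats = _group_indices(groups)
    n = mat.shape[0]
    if codes.size != n:
        raise StatsError(f"group vector length {codes.size} != matrix size {n}")
    if len(cats) < 2:
        raise StatsError("need >= 2 groups")
    d2 = mat ** 2
    f_obs, r2 = _pseudo_f(d2, codes, len(cats))
    if math.isnan(f_obs):
        warnings.warn("degenerate PERMANOVA (no within-group variation)", stacklevel=2)
        return StatResult(
            "permanova", float("nan"), (len(cats) - 1, n - len(cats)),
            float("nan"), r_squared=r2, comparison=tuple(map(str, cats)),
        )

    if n_perm == "all":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            fp, _ = _pseudo_f(d2, codes[list(perm)], len(cats))
            count += fp >= f_obs - 1e-12
            total += 1
        p = count / total
        n_used = total
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        count = 0
        for _ in range(int(n_perm)):
            fp, _ = _pseudo_f(d2, rng.permutation(codes), len(cats))
            count += fp >= f_obs - 1e-12
        p = (count + 1) / (int(n_perm) + 1)
        n_used = int(n_perm)
    return StatResult(
        "permanova", float(f_obs), (len(cats) - 1, n - len(cats)), float(p),
        r_squared=float(r2), n_permutations=n_used, comparison=tuple(map(str, cats)),
    )


# --------------------------------------------------------------------------
# betadisper
# --------------------------------------------------------------------------

def _anova1_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, int, int]:
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        if v.size == 0:
            continue
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df1, df2 = n_groups - 1, n - n_groups
    if ss_within <= 0 or df2 <= 0:
        return float("nan"), df1, df2
    return (ss_between / df1) / (ss_within / df2), df1, df2


def betadisper(
    D,
    groups,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[StatResult, pd.Series]:
    """Homogeneity of multivariate dispersions.

    Embeds the distance matrix by PCoA (keeping real and imaginary axes),
    computes each sample's distance to its group centroid as
    ``sqrt(d+^2 - d-^2)`` (squared distance on the positive-eigenvalue axes
    minus the squared distance on the negative ones, truncated at zero), and
    tests the group means of those distances with a one-way ANOVA F whose
    p-value comes from permuting group labels.

    Returns the test result and the per-sample dispersion distances.
    """
    from .diversity import full_embedding

    mat = _as_matrix(D)
    codes, cats = _group_indices(groups)
    n = mat.shape[0]
    if codes.size != n:
        raise StatsError(f"group vector length {codes.size} != matrix size {n}")
    if len(cats) < 2:
        raise StatsError("need >= 2 groups")
    for g, cat in enumerate(cats):
        if (codes == g).sum() == 1:
            warnings.warn(f"group {cat!r} has a single sample; its dispersion is 0", stacklevel=2)

    pos, _, neg, _ = full_embedding(mat)
    dist = np.zeros(n)
    for g in range(len(cats)):
        idx = np.flatnonzero(codes == g)
        dp = pos[idx] - pos[idx].mean(axis=0) if pos.size else np.zeros((idx.size, 0))
        dn = neg[idx] - neg[idx].mean(axis=0) if neg.size else np.zeros((idx.size, 0))
        sq = (dp ** 2).sum(axis=1) - (dn ** 2).sum(axis=1)
        if (sq < -1e-10).any():
            warnings.warn("negative squared dispersion truncated to 0", stacklevel=2)
        dist[idx] = np.sqrt(np.maximum(sq, 0.0))

    f_obs, df1, df2 = _anova1_f(dist, codes, len(cats))
    if math.isnan(f_obs):
        warnings.warn("degenerate dispersion test (no within-group spread)", stacklevel=2)
        p = float("nan")
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        count = 0
        for _ in range(int(n_perm)):
            fp, _, _ = _anova1_f(dist, rng.permutation(codes), len(cats))
            count += fp >= f_obs - 1e-12
        p = (count + 1) / (int(n_perm) + 1)
    ids = list(D.ids) if isinstance(D, DistanceMatrix) else list(range(n))
    return (
        StatResult(
            "betadisper", float(f_obs), (df1, df2), float(p),
            n_permutations=int(n_perm), comparison=tuple(map(str, cats)),
        ),
        pd.Series(dist, index=ids, name="dispersion"),
    )


# --------------------------------------------------------------------------
# rank-based tests
# --------------------------------------------------------------------------

def _tie_term(values: np.ndarray) -> float:
    """sum over tie groups of (t^3 - t)."""
    _, counts = np.unique(values, return_counts=True)
    return float((counts ** 3 - counts).sum())


def kruskal_wallis(values, groups) -> StatResult:
    """Kruskal-Wallis H with tie correction; p from chi-square (a-1 df)."""
    x = np.asarray(values, dtype=float)
    codes, cats = _group_indices(groups)
    if len(cats) < 2:
        raise StatsError("need >= 2 groups")
    if x.size != codes.size:
        raise StatsError("values and groups differ in length")
    for g, cat in enumerate(cats):
        if (codes == g).sum() == 0:
            raise StatsError(f"group {cat!r} is empty")
    n = x.size
    if n < 3:
        raise StatsError("need N >= 3")
    ranks = sps.rankdata(x)
    h = 12.0 / (n * (n + 1)) * sum(
        (ranks[codes == g].sum() ** 2) / (codes == g).sum() for g in range(len(cats))
    ) - 3 * (n + 1)
    correction = 1.0 - _tie_term(x) / (n ** 3 - n)
    if correction <= 0:
        # every value identical: no evidence against the null
        return StatResult("kruskal_wallis", 0.0, (len(cats) - 1,), 1.0,
                          comparison=tuple(map(str, cats)))
    h /= correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, len(cats) - 1))
    return StatResult("kruskal_wallis", float(h), (len(cats) - 1,), p,
                      comparison=tuple(map(str, cats)))


def dunn_posthoc(values, groups, adjust: str = "BH") -> list[StatResult]:
    """Dunn's pairwise z tests on pooled ranks, two-sided, BH-adjusted.

    ``z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b))``
    with the tie term ``T = sum (t^3 - t)``.
    """
    if adjust not in ("BH", "none"):
        raise StatsError(f"unknown adjustment {adjust!r} (use 'BH' or 'none')")
    x = np.asarray(values, dtype=float)
    codes, cats = _group_indices(groups)
    if len(cats) < 2:
        raise StatsError("need >= 2 groups")
    n = x.size
    ranks = sps.rankdata(x)
    tie = _tie_term(x)
    var_term = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    results: list[StatResult] = []
    for a, b in itertools.combinations(range(len(cats)), 2):
        ia, ib = codes == a, codes == b
        na, nb = int(ia.sum()), int(ib.sum())
        denom = math.sqrt(var_term * (1.0 / na + 1.0 / nb))
        if denom == 0:
            z, p = 0.0, 1.0
        else:
            z = (ranks[ia].mean() - ranks[ib].mean()) / denom
            p = float(2 * sps.norm.sf(abs(z)))
        results.append(StatResult("dunn", float(z), (), p,
                                  comparison=(str(cats[a]), str(cats[b]))))
    if adjust == "BH":
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results


# --------------------------------------------------------------------------
# ANOVA and t-test
# --------------------------------------------------------------------------

def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def two_way_anova(values, factor_a, factor_b) -> tuple[StatResult, StatResult]:
    """Additive two-way fixed-effects ANOVA (no interaction), Type-II SS.

    ``SS_a = RSS(b only) - RSS(a+b)`` and symmetrically for b (identical to
    Type-I on balanced data); residual df = N - levels_a - levels_b + 1.
    """
    y = np.asarray(values, dtype=float)
    ca, cats_a = _group_indices(factor_a)
    cb, cats_b = _group_indices(factor_b)
    if len(cats_a) < 2 or len(cats_b) < 2:
        raise StatsError("both factors need >= 2 levels")
    if y.size != ca.size or y.size != cb.size:
        raise StatsError("values and factors differ in length")
    cells = pd.crosstab(pd.Series(ca), pd.Series(cb))
    if (cells.to_numpy() == 0).any():
        raise StatsError("empty factor cell")

    n = y.size
    la, lb = len(cats_a), len(cats_b)
    ones = np.ones((n, 1))
    da = np.eye(la)[ca][:, 1:]  # drop-first dummy coding
    db = np.eye(lb)[cb][:, 1:]
    rss_full = _rss(y, np.hstack([ones, da, db]))
    rss_a_only = _rss(y, np.hstack([ones, da]))
    rss_b_only = _rss(y, np.hstack([ones, db]))
    ss_a = rss_b_only - rss_full
    ss_b = rss_a_only - rss_full
    df_res = n - la - lb + 1
    df_a, df_b = la - 1, lb - 1
    ms_res = rss_full / df_res if df_res > 0 else float("nan")

    def result(name, ss, df1):
        if ms_res == 0 or math.isnan(ms_res):
            warnings.warn("zero residual variance in two-way ANOVA", stacklevel=3)
            return StatResult(f"two_way_anova[{name}]", float("nan"), (df1, df_res))
        f = max(ss, 0.0) / df1 / ms_res
        return StatResult(
            f"two_way_anova[{name}]", float(f), (df1, df_res),
            float(sps.f.sf(f, df1, df_res)),
        )

    return result("a", ss_a, df_a), result("b", ss_b, df_b)


def t_test(values_a, values_b, equal_var: bool = True) -> StatResult:
    """Two-sided pooled-variance two-sample t-test (Student's)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs n >= 2")
    if not equal_var:
        raise StatsError("only the pooled-variance (Student) form is provided")
    na, nb = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    df = na + nb - 2
    if sp2 == 0:
        if a.mean() == b.mean():
            return StatResult("t_test", 0.0, (df,), 1.0)
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return StatResult("t_test", float("nan"), (df,), float("nan"))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = float(2 * sps.t.sf(abs(t), df))
    return StatResult("t_test", float(t), (df,), p)


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
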