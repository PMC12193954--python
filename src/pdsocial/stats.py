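"""Statistical battery with explicit conventions.

Implements the tests used in the longitudinal analysis — Welch's t from
summary statistics (with pooled-SD Cohen's d), Fisher's exact test, the
Wilcoxon signed-rank test, the Mann-Whitney U test, the Shapiro-Wilk
normality test, and Cohen's kappa — with the reporting conventions fixed:

* all p-values are two-sided, no multiple-testing correction;
* Wilcoxon: zero differences ("identical pairs") are dropped before
  ranking; W is the smaller of the positive/negative rank sums; exact
  sign-flip enumeration for n <= 12, otherwise the tie- and
  continuity-corrected normal approximation;
* Mann-Whitney: U is the smaller of the two U statistics; exact
  enumeration when n1*n2 <= 100, otherwise the tie- and
  continuity-corrected normal approximation;
* Cohen's kappa uses marginal-product expected agreement, with kappa = 1
  when both raters are constant and identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "welch_t",
    "fisher_exact",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "shapiro_wilk",
    "cohens_kappa",
]


@dataclass
class StatResult:
    """One test outcome: statistic, df (possibly fractional), two-sided p."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    effect_size: float | None = None
    n_used: int = 0
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "effect_size": self.effect_size,
            "n_used": self.n_used,
            "notes": self.notes,
        }


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> StatResult:
    """Welch's two-sample t-test from summary statistics, with Cohen's d.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), Welch-Satterthwaite df, and
    d = (m1 - m2) / pooled SD (pooled with n-1 weights).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = 0.0 if pooled == 0 else (mean1 - mean2) / pooled
    return StatResult("welch_t", float(t), float(p), df=float(df), effect_size=float(d), n_used=n1 + n2)


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher's exact test for a 2x2 table of counts."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return StatResult(
        "fisher_exact", float(odds), float(p), n_used=int(arr.sum()),
        notes={"convention": "sum of hypergeometric probabilities <= observed"},
    )


def _signed_rank_p_exact(ranks: np.ndarray, w: float) -> float:
    """P(min rank sum <= w) over all 2^n sign assignments (two-sided exact)."""
    n = len(ranks)
    total = ranks.sum()
    count = 0
    for mask in range(1 << n):
        positive = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if min(positive, total - positive) <= w + 1e-9:
            count += 1
    return count / (1 << n)


def wilcoxon_signed_rank(pre, post, exact_max_n: int = 12) -> StatResult:
    """Wilcoxon signed-rank test for paired samples.

    Pairs with a missing value or a zero difference (identical pre/post) are
    dropped.  |differences| are ranked with midranks; W is the smaller rank
    sum.  Exact sign-flip enumeration when the usable n <= ``exact_max_n``,
    otherwise normal approximation with tie correction.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired arrays must have equal length")
    valid = ~(np.isnan(pre) | np.isnan(post))
    diff = post[valid] - pre[valid]
    n_missing = int((~valid).sum())
    n_zero = int((diff == 0).sum())
    diff = diff[diff != 0]
    n = len(diff)
    if n < 1:
        raise ValueError("no usable (valid, non-identical) pairs")

    ranks = sps.rankdata(np.abs(diff))
    w_pos = float(ranks[diff > 0].sum())
    w_neg = float(ranks[diff < 0].sum())
    w = min(w_pos, w_neg)

    if n <= exact_max_n:
        p = _signed_rank_p_exact(ranks, w)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            raise ValueError("zero variance after tie correction")
        z = (w + 0.5 - mean) / np.sqrt(var)  # continuity-corrected
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal_approx"
    return StatResult(
        "wilcoxon_signed_rank", w, float(p), n_used=n,
        notes={
            "method": method,
            "w_positive": w_pos,
            "w_negative": w_neg,
            "pairs_dropped_missing": n_missing,
            "pairs_dropped_zero": n_zero,
            "convention": "W = smaller rank sum",
        },
    )


def _rank_sum_p_exact(all_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p for the smaller U by enumerating group-1 subsets."""
    n = len(all_ranks)
    n2 = n - n1
    base = n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for subset in combinations(range(n), n1):
        u1 = all_ranks[list(subset)].sum() - base
        u = min(u1, n1 * n2 - u1)
        if u <= u_obs + 1e-9:
            count += 1
        total += 1
    return count / total


def mann_whitney_u(x, y, exact_max_product: int = 100) -> StatResult:
    """Mann-Whitney U test for two independent samples.

    U is the smaller of the two U statistics (midranks for ties).  Exact
    enumeration of all group assignments when n1*n2 <= ``exact_max_product``,
    otherwise normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)
    u = min(u1, u2)

    if n1 * n2 <= exact_max_product:
        p = _rank_sum_p_exact(ranks, n1, u)
        method = "exact"
    else:
        mean = n1 * n2 / 2.0
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u + 0.5 - mean) / np.sqrt(var)  # continuity-corrected
            p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal_approx"
    return StatResult(
        "mann_whitney_u", u, float(p), n_used=n1 + n2,
        notes={"method": method, "u1": u1, "u2": u2, "convention": "U = smaller statistic"},
    )


def shapiro_wilk(x) -> StatResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk supports n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W undefined")
    w, p = sps.shapiro(x)
    return StatResult("shapiro_wilk", float(w), float(p), n_used=len(x))


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected inter-rater agreement for two equal-length label vectors.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected agreement;
    when both raters are constant and identical (p_e = 1), kappa is 1.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and equal length")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    categories = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    p_e = 0.0
    n = len(a)
    for cat in categories:
        p_e += (np.sum(a == cat) / n) * (np.sum(b == cat) / n)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
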