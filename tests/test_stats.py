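import math
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps

from pdsocial.stats import (
    cohens_kappa,
    fisher_exact,
    mann_whitney_u,
    shapiro_wilk,
    welch_t,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------


def test_welch_worked_example_from_summary_stats():
    r = welch_t(64.46, 13.24, 49, 75.72, 6.41, 11)
    assert abs(r.statistic) == pytest.approx(4.16, abs=0.005)
    assert r.effect_size == pytest.approx(-0.91, abs=0.005)
    assert r.p_value < 0.001


def test_welch_identical_groups():
    r = welch_t(5.0, 2.0, 10, 5.0, 2.0, 10)
    assert r.statistic == 0.0 and r.effect_size == 0.0
    assert r.p_value == pytest.approx(1.0)


def test_welch_equal_n_equal_sd_df_closed_form():
    n = 12
    r = welch_t(1.0, 3.0, n, 2.0, 3.0, n)
    assert r.df == pytest.approx(2 * n - 2)


def test_welch_symmetry_and_errors():
    a = welch_t(1.0, 2.0, 8, 3.0, 1.0, 9)
    b = welch_t(3.0, 1.0, 9, 1.0, 2.0, 8)
    assert a.p_value == pytest.approx(b.p_value)
    assert a.statistic == pytest.approx(-b.statistic)
    with pytest.raises(ValueError):
        welch_t(1.0, 0.0, 5, 1.0, 0.0, 5)
    with pytest.raises(ValueError):
        welch_t(1.0, 1.0, 1, 2.0, 1.0, 5)


# ---------------------------------------------------------------------------
# Fisher's exact
# ---------------------------------------------------------------------------


def brute_force_fisher(table):
    """Sum hypergeometric probabilities <= observed, by enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    observed = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= observed * (1 + 1e-9):
            total += p
    return min(1.0, total)


@pytest.mark.parametrize(
    "table",
    [
        [[0, 10], [10, 0]],
        [[5, 5], [5, 5]],
        [[2, 7], [8, 2]],
        [[1, 0], [0, 1]],
        [[3, 1], [1, 6]],
        [[0, 0], [4, 5]],
    ],
)
def test_fisher_matches_enumeration(table):
    assert fisher_exact(table).p_value == pytest.approx(brute_force_fisher(table))


def test_fisher_symmetric_table_p_one():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_random_small_tables_match_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(50):
        table = rng.integers(0, 12, (2, 2))
        assert fisher_exact(table).p_value == pytest.approx(
            brute_force_fisher(table.tolist())
        )


def test_fisher_rejects_non_integer():
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 2], [3, 4]])


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def enumerate_signed_rank_p(diff):
    """Independent exact p: all 2^n sign assignments of the |diff| midranks."""
    diff = np.asarray(diff, dtype=float)
    diff = diff[diff != 0]
    ranks = sps.rankdata(np.abs(diff))
    total = ranks.sum()
    w_obs = min(ranks[diff > 0].sum(), ranks[diff < 0].sum())
    hits = 0
    n = len(ranks)
    for signs in product([0, 1], repeat=n):
        w_pos = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_pos, total - w_pos) <= w_obs + 1e-9:
            hits += 1
    return hits / 2**n


def test_wilcoxon_all_positive_diffs_w_zero():
    r = wilcoxon_signed_rank([1, 1, 2], [2, 3, 5])
    assert r.statistic == 0.0
    assert r.notes["w_negative"] == 0.0


def test_wilcoxon_identical_pairs_error():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])


def test_wilcoxon_drops_missing_and_zero_pairs():
    pre = [1.0, 2.0, np.nan, 4.0, 5.0]
    post = [2.0, 2.0, 3.0, 6.0, 7.0]
    r = wilcoxon_signed_rank(pre, post)
    assert r.n_used == 3
    assert r.notes["pairs_dropped_missing"] == 1
    assert r.notes["pairs_dropped_zero"] == 1


def test_wilcoxon_exact_matches_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = rng.integers(3, 11)
        pre = rng.normal(0, 1, n)
        post = pre + rng.normal(0.3, 1, n)
        r = wilcoxon_signed_rank(pre, post)
        assert r.notes["method"] == "exact"
        assert r.p_value == pytest.approx(enumerate_signed_rank_p(post - pre))


def test_wilcoxon_normal_approx_close_to_exact_at_small_n():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = rng.integers(8, 13)
        pre = rng.normal(0, 1, n)
        post = pre + rng.normal(0.5, 1, n)
        exact = wilcoxon_signed_rank(pre, post).p_value
        approx = wilcoxon_signed_rank(pre, post, exact_max_n=0).p_value
        assert abs(exact - approx) < 0.05


def test_wilcoxon_sign_flip_symmetry():
    rng = np.random.default_rng(3)
    pre = rng.normal(0, 1, 25)
    post = pre + rng.normal(0.4, 1, 25)
    forward = wilcoxon_signed_rank(pre, post)
    reverse = wilcoxon_signed_rank(post, pre)
    assert forward.statistic == pytest.approx(reverse.statistic)
    assert forward.p_value == pytest.approx(reverse.p_value)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def enumerate_mwu_p(x, y):
    """Independent exact p: every assignment of pooled ranks to group 1."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    u_obs_1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_obs = min(u_obs_1, n1 * n2 - u_obs_1)
    hits = total = 0
    for subset in combinations(range(n1 + n2), n1):
        u1 = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
        if min(u1, n1 * n2 - u1) <= u_obs + 1e-9:
            hits += 1
        total += 1
    return hits / total


def test_mwu_complete_separation():
    r = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0


def test_mwu_identical_samples():
    r = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert r.statistic == pytest.approx(8.0)  # n^2 / 2
    assert r.p_value == pytest.approx(1.0)


def test_mwu_exact_matches_enumeration():
    rng = np.random.default_rng(4)
    for _ in range(15):
        n1, n2 = rng.integers(2, 7, 2)
        x = np.round(rng.normal(0, 1, n1), 1)  # rounding produces ties
        y = np.round(rng.normal(0.5, 1, n2), 1)
        r = mann_whitney_u(x, y)
        assert r.notes["method"] == "exact"
        assert r.p_value == pytest.approx(enumerate_mwu_p(x, y))


def test_mwu_group_order_symmetry():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
    a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
    assert a.statistic == pytest.approx(b.statistic)
    assert a.p_value == pytest.approx(b.p_value)


def test_mwu_empty_sample_error():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1, 2])


# ---------------------------------------------------------------------------
# Shapiro-Wilk
# ---------------------------------------------------------------------------


def test_shapiro_rejects_skewed_samples():
    rng = np.random.default_rng(6)
    rejections = sum(
        shapiro_wilk(rng.exponential(1, 100)).p_value < 0.05 for _ in range(200)
    )
    assert rejections >= 190  # >= 95% power on exponential data


def test_shapiro_type_one_calibration():
    rng = np.random.default_rng(7)
    rejections = sum(
        shapiro_wilk(rng.normal(0, 1, 100)).p_value < 0.05 for _ in range(1000)
    )
    assert abs(rejections / 1000 - 0.05) < 0.02


def test_shapiro_degenerate_inputs():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0] * 10)  # constant vector: W undefined


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


def test_kappa_identical_vectors():
    assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)


def test_kappa_hand_computation():
    # both-yes=4, both-no=4, a-only=1, b-only=1 -> p_o=0.8, p_e=0.5, kappa=0.6
    a = [1] * 4 + [0] * 4 + [1, 0]
    b = [1] * 4 + [0] * 4 + [0, 1]
    assert cohens_kappa(a, b) == pytest.approx(0.6)


def test_kappa_independent_raters_near_zero():
    rng = np.random.default_rng(8)
    a = rng.integers(0, 2, 20000)
    b = rng.integers(0, 2, 20000)
    assert abs(cohens_kappa(a, b)) < 0.03


def test_kappa_constant_identical_raters():
    assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0
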