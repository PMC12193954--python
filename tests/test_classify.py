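import numpy as np
import pytest
from sklearn.naive_bayes import MultinomialNB

from pdsocial import classify
from pdsocial.classify import (
    Candidate,
    ModelReport,
    SoftVotingEnsemble,
    build_ensemble,
    evaluate,
    predict,
    select_model,
    split_data,
    train_candidates,
)


def separable_data(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(int)
    X = np.abs(rng.normal(0, 0.2, (n, 4)))
    X[y == 1, 0] += 3.0
    X[y == 0, 1] += 3.0
    return X, y


class FixedProb:
    """Stub classifier with preset positive-class probabilities."""

    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = np.asarray(p, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.p, self.p])


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def test_split_is_stratified_and_exhaustive():
    y = np.array([1] * 35 + [0] * 65)
    train, test = split_data(np.arange(100), y, test_fraction=0.2, seed=0)
    assert len(test) == 20 and len(train) == 80
    assert y[test].sum() == 7
    assert sorted(np.concatenate([train, test])) == list(range(100))


def test_split_deterministic_and_validates():
    y = np.array([0, 0, 1, 1, 0, 1])
    a = split_data(np.arange(6), y, test_fraction=0.34, seed=3)
    b = split_data(np.arange(6), y, test_fraction=0.34, seed=3)
    np.testing.assert_array_equal(a[0], b[0])
    with pytest.raises(ValueError):
        split_data(np.arange(6), y, test_fraction=0.0)
    with pytest.raises(ValueError):
        split_data(np.arange(3), np.array([0, 0, 1]))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def test_separable_data_reaches_perfect_cv_recall():
    X, y = separable_data()
    candidates = train_candidates(X, y, families=("naive_bayes", "decision_tree"), seed=0)
    for cand in candidates.values():
        assert cand.cv_macro_recall == pytest.approx(1.0)


def test_training_is_deterministic_under_seed():
    X, y = separable_data(seed=4)
    a = train_candidates(X, y, families=("decision_tree",), seed=7)
    b = train_candidates(X, y, families=("decision_tree",), seed=7)
    assert a["decision_tree"].params == b["decision_tree"].params
    assert a["decision_tree"].cv_macro_recall == b["decision_tree"].cv_macro_recall


def test_permuted_labels_give_chance_level_recall():
    rng = np.random.default_rng(0)
    X, y = separable_data(n=200, seed=1)
    scores = []
    for _ in range(20):
        permuted = rng.permutation(y)
        cand = train_candidates(X, permuted, families=("naive_bayes",), seed=0)
        scores.append(cand["naive_bayes"].cv_macro_recall)
    assert abs(np.mean(scores) - 0.5) < 0.05


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------


def test_ensemble_probability_is_unweighted_mean():
    ens = SoftVotingEnsemble([FixedProb([0.6]), FixedProb([0.7]), FixedProb([0.8])])
    assert ens.predict_proba(None)[0, 1] == pytest.approx(0.7)


def test_ensemble_boundary_half_classified_positive():
    ens = SoftVotingEnsemble([FixedProb([0.9]), FixedProb([0.1])])
    assert ens.predict_proba(None)[0, 1] == pytest.approx(0.5)
    assert ens.predict(None)[0] == 1


def test_ensemble_of_identical_members_is_identity():
    member = FixedProb([0.3, 0.8])
    ens = SoftVotingEnsemble([member, member])
    np.testing.assert_allclose(ens.predict_proba(None), member.predict_proba(None))


def test_ensemble_requires_probabilities():
    class NoProb:
        pass

    with pytest.raises(ValueError):
        SoftVotingEnsemble([NoProb()])


def test_build_ensemble_from_candidates():
    cands = {
        "naive_bayes": Candidate("naive_bayes", FixedProb([0.9]), {}, 1.0),
        "knn": Candidate("knn", FixedProb([0.5]), {}, 1.0),
    }
    ens = build_ensemble(cands)
    assert ens.family == "ensemble"
    assert ens.estimator.predict_proba(None)[0, 1] == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def test_macro_recall_matches_hand_confusion():
    # TP=8 FN=2 TN=9 FP=1 -> macro recall (0.8 + 0.9) / 2 = 0.85
    y = np.array([1] * 10 + [0] * 10)
    p = np.array([0.9] * 8 + [0.1] * 2 + [0.1] * 9 + [0.9] * 1)
    cand = Candidate("naive_bayes", FixedProb(p), {}, 1.0)
    report = evaluate(cand, None, y, B=50, seed=0)
    assert report.macro_recall == pytest.approx(0.85)


def test_perfect_separation_auc_one():
    y = np.array([0, 0, 1, 1])
    cand = Candidate("svm", FixedProb([0.1, 0.2, 0.8, 0.9]), {}, 1.0)
    assert evaluate(cand, None, y, B=20, seed=0).auc == pytest.approx(1.0)


def concordant_pair_auc(y, scores):
    """Brute-force AUC: concordant-pair fraction with 0.5 for score ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_equals_concordant_pair_fraction():
    rng = np.random.default_rng(5)
    y = (rng.random(150) < 0.4).astype(int)
    scores = np.round(rng.random(150), 2)  # ties included
    cand = Candidate("knn", FixedProb(scores), {}, 1.0)
    report = evaluate(cand, None, y, B=20, seed=0)
    assert report.auc == pytest.approx(concordant_pair_auc(y, scores))


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(6)
    y = (rng.random(1000) < 0.5).astype(int)
    scores = rng.random(1000)
    cand = Candidate("knn", FixedProb(scores), {}, 1.0)
    assert abs(evaluate(cand, None, y, B=20, seed=0).auc - 0.5) < 0.05


def test_bootstrap_ci_contains_point_and_shrinks():
    rng = np.random.default_rng(7)
    widths = []
    for n in (100, 1000):
        y = (rng.random(n) < 0.4).astype(int)
        p = np.clip(y * 0.7 + rng.normal(0, 0.25, n), 0, 1)
        cand = Candidate("naive_bayes", FixedProb(p), {}, 1.0)
        report = evaluate(cand, None, y, B=300, seed=0)
        lo, hi = report.ci_recall
        assert lo <= report.macro_recall <= hi
        widths.append(hi - lo)
    assert widths[1] < widths[0]


def test_single_class_test_set_is_error():
    cand = Candidate("naive_bayes", FixedProb([0.5, 0.5]), {}, 1.0)
    with pytest.raises(ValueError):
        evaluate(cand, None, np.array([1, 1]), B=10, seed=0)


# ---------------------------------------------------------------------------
# Selection and prediction
# ---------------------------------------------------------------------------


def make_report(family, recall, f1=0.5):
    return ModelReport(family, {}, recall, 0.5, f1, (0, 1), (0, 1), (0, 1), 0.9)


def test_select_highest_recall():
    picked = select_model([make_report("naive_bayes", 0.86), make_report("ensemble", 0.84)])
    assert picked.family == "naive_bayes"


def test_select_tie_broken_by_f1_then_order():
    picked = select_model([make_report("svm", 0.8, f1=0.7), make_report("knn", 0.8, f1=0.9)])
    assert picked.family == "knn"
    picked = select_model([make_report("adaboost", 0.8), make_report("svm", 0.8)])
    assert picked.family == "svm"  # earlier in documented family order


def test_select_single_report():
    only = make_report("xgboost", 0.5)
    assert select_model([only]) is only


@pytest.mark.parametrize("prob,label", [(0.51, 1), (0.5, 1), (0.49, 0)])
def test_predict_threshold_boundary(prob, label):
    p, labels = predict(FixedProb([prob]), None)
    assert p[0] == pytest.approx(prob)
    assert labels[0] == label


def test_predict_dimension_mismatch_is_error():
    X, y = separable_data()
    model = MultinomialNB().fit(X, y)
    with pytest.raises(ValueError):
        predict(model, X[:, :2])
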