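import numpy as np
import pytest

import vitaxrd as vx
from vitaxrd.classify import _binary_labels
from vitaxrd.exceptions import SingleClassTest, SingleClassTrain, TooFewPatients


def mann_whitney_auc(scores, y):
    """Concordant-pair oracle: P(score_pos > score_neg) with ties = 1/2."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_operating_point(scores, y):
    """Enumerate every threshold; return min distance² to the ideal (0, 1)."""
    best = np.inf
    for t in np.concatenate(([np.inf], np.unique(scores))):
        pred = scores >= t
        tpr = np.sum(pred & (y == 1)) / np.sum(y == 1)
        fpr = np.sum(pred & (y == 0)) / np.sum(y == 0)
        best = min(best, fpr**2 + (1 - tpr) ** 2)
    return best


class TestPatientSplits:
    def test_ten_plus_ten_split_counts(self):
        pats = [f"C{i}" for i in range(10)] + [f"N{i}" for i in range(10)]
        labels = ["cancer"] * 10 + ["non-cancer"] * 10
        splits = vx.make_patient_splits(pats, labels, 5, 0.6, seed=0)
        for s in splits:
            train_c = sum(p.startswith("C") for p in s.train_patients)
            train_n = sum(p.startswith("N") for p in s.train_patients)
            assert (train_c, train_n) == (6, 6)
            assert len(s.test_patients) == 8

    def test_disjoint_and_exhaustive(self):
        pats = [f"P{i}" for i in range(30)]
        labels = ["cancer" if i < 17 else "non-cancer" for i in range(30)]
        for s in vx.make_patient_splits(pats, labels, 20, 0.6, seed=1):
            assert not (s.train_patients & s.test_patients)
            assert s.train_patients | s.test_patients == set(pats)

    def test_deterministic(self):
        pats = [f"P{i}" for i in range(20)]
        labels = ["cancer" if i % 2 else "non-cancer" for i in range(20)]
        a = vx.make_patient_splits(pats, labels, 200, 0.6, seed=3)
        b = vx.make_patient_splits(pats, labels, 200, 0.6, seed=3)
        assert a == b

    def test_too_few_patients(self):
        with pytest.raises(TooFewPatients):
            vx.make_patient_splits(["A", "B"], ["cancer", "cancer"], 1, 0.6, 0)


class TestTrainAndScore:
    def test_memorization_on_separable_classes(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 5)),
                       rng.normal(5, 0.1, (20, 5))])
        y = np.array([0] * 20 + [1] * 20)
        scores = vx.train_and_score(X, y, X, seed=0)
        roc = vx.roc_and_threshold(scores, y)
        assert roc.auc == 1.0

    def test_single_class_train_rejected(self):
        X = np.ones((5, 3))
        with pytest.raises(SingleClassTrain):
            vx.train_and_score(X, np.ones(5), X)

    def test_scores_are_vote_fractions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        scores = vx.train_and_score(X, y, X, vx.ClassifierConfig(n_trees=10), 0)
        assert np.all((scores >= 0) & (scores <= 1))
        assert np.allclose(scores * 10, np.round(scores * 10))


class TestRocAndThreshold:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        roc = vx.roc_and_threshold(np.array([0.0, 0.0, 1.0, 1.0]), y)
        assert (roc.auc, roc.sensitivity, roc.specificity) == (1.0, 1.0, 1.0)

    def test_separable_toy(self):
        y = np.array([1, 1, 0, 0])
        roc = vx.roc_and_threshold(np.array([0.9, 0.8, 0.1, 0.2]), y)
        assert roc.auc == 1.0
        assert 0.2 < roc.threshold <= 0.8
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_single_class_test_rejected(self):
        with pytest.raises(SingleClassTest):
            vx.roc_and_threshold(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_auc_matches_concordant_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(6, 40)
            y = np.zeros(n, int)
            y[rng.permutation(n)[: rng.integers(2, n - 2)]] = 1
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # with ties
            roc = vx.roc_and_threshold(scores, y)
            assert roc.auc == pytest.approx(mann_whitney_auc(scores, y),
                                            abs=1e-9)

    def test_sens_spec_reproducible_from_confusion_matrix(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        scores = rng.random(50)
        roc = vx.roc_and_threshold(scores, y)
        pred = scores >= roc.threshold
        sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
        spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        assert roc.sensitivity == pytest.approx(sens)
        assert roc.specificity == pytest.approx(spec)


class TestAggregate:
    def _roc(self, auc, idx):
        return vx.RocResult(idx, np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                            np.array([np.inf, 0.0]), auc, 0.5, auc, auc)

    def test_single_realization_min_equals_max(self):
        summary, _, _ = vx.aggregate([self._roc(0.8, 0)])
        m = summary.metrics["auc"]
        assert m["min"] == m["max"] == m["mean"] == 0.8

    def test_two_realizations_mean_and_best(self):
        summary, _, _ = vx.aggregate([self._roc(0.6, 0), self._roc(0.9, 1)])
        assert summary.metrics["auc"]["mean"] == pytest.approx(0.75)
        assert summary.best_realization == 1
        assert summary.worst_realization == 0

    def test_average_of_identical_curves_is_the_curve(self):
        fpr = np.array([0.0, 0.2, 1.0])
        tpr = np.array([0.0, 0.9, 1.0])
        r = vx.RocResult(0, fpr, tpr, np.array([np.inf, 0.5, 0.0]),
                         0.95, 0.5, 0.9, 0.8)
        _, grid, mean_tpr = vx.aggregate([r, r])
        assert np.allclose(mean_tpr, np.interp(grid, fpr, tpr))


class TestBinaryLabels:
    def test_mapping(self):
        assert _binary_labels(["cancer", "non-cancer"]).tolist() == [1, 0]
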