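"""Fold balancing, soft voting, metrics, ROC/OOP, and leakage-free CV."""

import numpy as np
import pandas as pd
import pytest
from helpers import fitted_stub

from myoscreen import (EnsembleSpec, cross_validate, make_folds, metrics,
                       roc_auc, search_weights, select_oop, soft_vote)
from myoscreen.classify import fit_members

SMALL_SPEC = EnsembleSpec(svm_c_grid=(1.0,), rf_n_estimators=25,
                          rf_depth_grid=(3,), gbm_learning_rate_grid=(0.1,),
                          gbm_n_estimators=25, seed=0)


class TestFolds:
    def test_study_sized_partition(self):
        y = np.array([0] * 45 + [1] * 48)
        folds = make_folds(y, k=5, seed=3)
        sizes = [np.sum(folds == f) for f in range(5)]
        assert sorted(sizes) == [18, 18, 19, 19, 19]
        for f in range(5):
            gap = abs(np.sum(y[folds == f] == 0) - np.sum(y[folds == f] == 1))
            assert gap <= 1

    def test_balanced_small_case(self):
        y = np.array([0] * 10 + [1] * 10)
        folds = make_folds(y, k=5, seed=0)
        for f in range(5):
            assert np.sum(y[folds == f] == 0) == 2
            assert np.sum(y[folds == f] == 1) == 2

    def test_deterministic(self):
        y = np.array([0] * 20 + [1] * 23)
        np.testing.assert_array_equal(make_folds(y, seed=7), make_folds(y, seed=7))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 0, 1, 1]), k=5)


class TestSoftVote:
    def test_weighted_argmax(self):
        members = [fitted_stub(lambda x, p=p: np.full(len(x), p))
                   for p in (0.4, 0.8, 0.55)]
        score, label = soft_vote(members, np.ones(3), np.zeros((1, 2)))
        assert score[0] == pytest.approx(1.75 / 3)
        assert label[0] == 1

    def test_single_weight_reproduces_member(self, rng):
        fns = [lambda x: x[:, 0] % 1.0, lambda x: 1 - x[:, 0] % 1.0,
               lambda x: np.full(len(x), 0.5)]
        members = [fitted_stub(f) for f in fns]
        x = rng.uniform(size=(40, 1))
        score, label = soft_vote(members, np.array([1.0, 0.0, 0.0]), x)
        np.testing.assert_allclose(score, fns[0](x))
        np.testing.assert_array_equal(label, members[0].predict(x))

    def test_tie_votes_sarcopenic(self):
        members = [fitted_stub(lambda x: np.full(len(x), 0.5))] * 3
        _, label = soft_vote(members, np.ones(3), np.zeros((1, 2)))
        assert label[0] == 1

    def test_zero_weights_rejected(self):
        members = [fitted_stub(lambda x: np.full(len(x), 0.5))] * 3
        with pytest.raises(ValueError):
            soft_vote(members, np.zeros(3), np.zeros((1, 2)))


class TestMetrics:
    def test_confusion_arithmetic(self):
        y = np.array([1] * 48 + [0] * 45)
        pred = np.array([1] * 38 + [0] * 10 + [0] * 30 + [1] * 15)
        m = metrics(y, pred)
        assert m["sensitivity"] == pytest.approx(0.7917, abs=1e-4)
        assert m["specificity"] == pytest.approx(0.6667, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.7312, abs=1e-4)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        assert all(v == 1.0 for v in metrics(y, y).values())

    def test_all_positive_predictor(self):
        y = np.array([0, 0, 1, 1])
        m = metrics(y, np.ones(4, dtype=int))
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_class_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 30)
        pred = rng.integers(0, 2, 30)
        m1 = metrics(y, pred)
        m2 = metrics(1 - y, 1 - pred)
        assert m1["sensitivity"] == pytest.approx(m2["specificity"])
        assert m1["specificity"] == pytest.approx(m2["sensitivity"])
        assert m1["accuracy"] == pytest.approx(m2["accuracy"])


class TestROC:
    def test_perfect_ranking(self):
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(1.0)

    def test_matches_rank_sum_oracle(self, rng):
        """Trapezoidal AUC equals the tie-averaged pairwise-comparison rate."""
        for _ in range(50):
            n = rng.integers(6, 30)
            labels = np.concatenate([np.zeros(n // 2, int), np.ones(n - n // 2, int)])
            scores = np.round(rng.uniform(size=n), 1)     # force ties
            _, auc = roc_auc(scores, labels)
            pos = scores[labels == 1][:, None]
            neg = scores[labels == 0][None, :]
            oracle = np.mean((pos > neg) + 0.5 * (pos == neg))
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_constant_scores(self):
        with pytest.warns(UserWarning, match="constant"):
            _, auc = roc_auc(np.full(6, 0.5), np.array([0, 1] * 3))
        assert auc == pytest.approx(0.5)

    def test_monotone_roc_points(self, rng):
        roc, _ = roc_auc(rng.uniform(size=40), rng.integers(0, 2, 40))
        assert (np.diff(roc["fpr"]) >= 0).all()
        assert (np.diff(roc["tpr"]) >= 0).all()


class TestOOP:
    def test_specificity_floor_rule(self):
        roc = pd.DataFrame({"threshold": [0.9, 0.6, 0.3],
                            "fpr": [0.1, 0.3, 0.4],
                            "tpr": [0.5, 0.8, 0.95]})
        oop = select_oop(roc)
        assert oop["sensitivity"] == pytest.approx(0.8)
        assert oop["specificity"] == pytest.approx(0.7)

    def test_no_qualifying_point(self):
        roc = pd.DataFrame({"threshold": [0.5], "fpr": [0.6], "tpr": [0.9]})
        with pytest.raises(ValueError, match="0.4"):
            select_oop(roc)

    def test_single_qualifying_point(self):
        roc = pd.DataFrame({"threshold": [0.5], "fpr": [0.2], "tpr": [0.6]})
        assert select_oop(roc)["sensitivity"] == pytest.approx(0.6)


class TestWeightSearch:
    def test_mass_on_perfect_member(self, rng):
        x = np.column_stack([np.repeat([0.0, 1.0], 15), rng.uniform(size=30)])
        y = x[:, 0].astype(int)
        members = [fitted_stub(lambda z: z[:, 0] * 0.98 + 0.01),
                   fitted_stub(lambda z: np.full(len(z), 0.5)),
                   fitted_stub(lambda z: np.full(len(z), 0.5))]
        w = search_weights(members, x, y, SMALL_SPEC)
        assert w[0] == pytest.approx(1.0)

    def test_identical_members_lexicographic_tiebreak(self, rng):
        x = rng.uniform(size=(20, 2))
        y = np.array([0, 1] * 10)
        members = [fitted_stub(lambda z: np.full(len(z), 0.7))] * 3
        w = search_weights(members, x, y, SMALL_SPEC)
        np.testing.assert_allclose(w, [0.0, 0.0, 1.0])

    def test_single_point_grid(self, rng):
        x = rng.uniform(size=(12, 2))
        y = np.array([0, 1] * 6)
        spec = EnsembleSpec(weight_grid=(1.0,), inner_folds=3, seed=0)
        members = [fitted_stub(lambda z: z[:, 0])] * 3
        w = search_weights(members, x, y, spec)
        np.testing.assert_allclose(w, [1 / 3] * 3)


class TestMembersAndCV:
    def test_separable_toy_training_accuracy(self):
        x = np.vstack([np.random.default_rng(0).normal(0, 0.1, (10, 2)),
                       np.random.default_rng(1).normal(3, 0.1, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        for m in fit_members(x, y, SMALL_SPEC):
            assert np.mean(m.predict(x) == y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_members(np.zeros((5, 2)), np.zeros(5, int), SMALL_SPEC)

    def test_training_ignores_heldout_features(self, rng):
        """Corrupting held-out subjects' features cannot change a model trained
        without them."""
        x = rng.normal(size=(30, 3))
        y = np.array([0, 1] * 15)
        train = np.arange(20)
        probe = rng.normal(size=(8, 3))
        m1 = fit_members(x[train], y[train], SMALL_SPEC)
        w1 = search_weights(m1, x[train], y[train], SMALL_SPEC)
        x2 = x.copy()
        x2[20:] = rng.normal(size=(10, 3)) * 100       # corrupt held-out rows
        m2 = fit_members(x2[train], y[train], SMALL_SPEC)
        w2 = search_weights(m2, x2[train], y[train], SMALL_SPEC)
        np.testing.assert_array_equal(w1, w2)
        s1, _ = soft_vote(m1, w1, probe)
        s2, _ = soft_vote(m2, w2, probe)
        np.testing.assert_array_equal(s1, s2)

    def test_permuted_labels_give_chance_accuracy(self, rng):
        accs = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            x = r.normal(size=(40, 4))
            y = np.array([0, 1] * 20)
            r.shuffle(y)
            members = fit_members(x[:30], y[:30], SMALL_SPEC)
            w = search_weights(members, x[:30], y[:30], SMALL_SPEC)
            _, pred = soft_vote(members, w, x[30:])
            accs.append(np.mean(pred == y[30:]))
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_cross_validate_deterministic(self, rng):
        x = np.vstack([rng.normal(0, 1, (12, 3)), rng.normal(1.5, 1, (12, 3))])
        y = np.array([0] * 12 + [1] * 12)
        r1 = cross_validate(x, y, spec=SMALL_SPEC, k=4, seed=2)
        r2 = cross_validate(x, y, spec=SMALL_SPEC, k=4, seed=2)
        pd.testing.assert_frame_equal(r1.fold_metrics, r2.fold_metrics)
        np.testing.assert_array_equal(r1.pooled_scores, r2.pooled_scores)
        assert r1.auc == r2.auc
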