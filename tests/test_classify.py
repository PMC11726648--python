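"""Split, feature selection, tuning, and the 12-cell progression experiment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from mosaicmap import (ClassifierConfig, PatchSet, ProgressionClassifier,
                       run_full_experiment, select_features, split_train_test,
                       summary_table, tune_and_train)
from mosaicmap.classify import SplitError, evaluate, run_experiment_cell


def blobs(rng, n=80, n_features=20, sep=3.0):
    y = np.repeat([False, True], n // 2)
    X = rng.normal(size=(n, n_features))
    X[y, :3] += sep
    return X, y


class TestSplit:
    def test_test_size_is_rounded_fifth(self):
        ids = [f"s{i}" for i in range(135)]
        labels = np.arange(135) % 2 == 0
        train, test = split_train_test(ids, labels, ClassifierConfig(seed=0))
        assert len(test) == 27
        assert len(train) == 108
        assert not set(train) & set(test)

    def test_same_seed_gives_identical_split(self):
        ids = [f"s{i}" for i in range(60)]
        labels = np.arange(60) % 3 == 0
        config = ClassifierConfig(seed=5)
        assert split_train_test(ids, labels, config) == split_train_test(ids, labels, config)

    def test_stratified_split_preserves_class_counts_within_one(self):
        rng = np.random.default_rng(0)
        labels = np.concatenate([np.ones(73, dtype=bool), np.zeros(62, dtype=bool)])
        rng.shuffle(labels)
        ids = [f"s{i}" for i in range(135)]
        _, test = split_train_test(ids, labels, ClassifierConfig(seed=1))
        test_labels = labels[[ids.index(s) for s in test]]
        assert abs(test_labels.sum() - 0.2 * 73) <= 1
        assert abs((~test_labels).sum() - 0.2 * 62) <= 1

    def test_single_class_rejected(self):
        with pytest.raises(SplitError):
            split_train_test([f"s{i}" for i in range(20)], np.ones(20, dtype=bool),
                             ClassifierConfig(seed=0))


class TestFeatureSelection:
    def test_perfectly_separating_feature_selected_first(self, rng):
        X = rng.normal(size=(40, 10))
        y = np.arange(40) % 2 == 0
        X[y, 6] += 10
        assert select_features(X, y, k=1).tolist() == [6]

    def test_matches_brute_force_t_ranking(self, rng):
        X = rng.normal(size=(60, 100))
        y = rng.random(60) < 0.5
        k = 30
        selected = select_features(X, y, k=k)
        # independent oracle: pooled-variance t computed from first principles
        a, b = X[y], X[~y]
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        expected = np.sort(np.argsort(-np.abs(t), kind="stable")[:k])
        assert selected.tolist() == expected.tolist()

    def test_zero_variance_feature_ranks_last(self, rng):
        X = rng.normal(size=(30, 5))
        X[:, 2] = 1.0
        y = np.arange(30) % 2 == 0
        assert 2 not in select_features(X, y, k=4)

    def test_restricted_mode_returns_roi_unchanged(self, rng):
        roi = PatchSet(name="roi", indices=(1, 4, 7))
        X, y = blobs(rng, n_features=10)
        clf = ProgressionClassifier(mode="restricted_roi", patch_set=roi,
                                    n_features=3).fit(X, y)
        assert clf.selected_features_.tolist() == [1, 4, 7]


class TestTuning:
    def test_separable_blobs_reach_high_cv_accuracy(self, rng):
        X, y = blobs(rng)
        _, params, cv_acc = tune_and_train(X, y, ClassifierConfig(seed=0, n_features=20))
        assert cv_acc >= 0.95
        assert set(params) == {"C", "gamma"}

    def test_shuffled_labels_stay_near_majority_rate(self, rng):
        X, y = blobs(rng)
        y = rng.permutation(y)
        _, _, cv_acc = tune_and_train(X, y, ClassifierConfig(seed=0))
        majority = max(y.mean(), 1 - y.mean())
        # CV tuning picks the best of 30 grid points, so allow optimism
        assert cv_acc < majority + 3.5 * np.sqrt(majority * (1 - majority) / y.size)

    def test_tuning_is_deterministic(self, rng):
        X, y = blobs(rng, sep=1.0)
        config = ClassifierConfig(seed=3)
        _, params_a, acc_a = tune_and_train(X, y, config)
        _, params_b, acc_b = tune_and_train(X, y, config)
        assert params_a == params_b and acc_a == acc_b


class TestEvaluate:
    def test_accuracy_is_fraction_correct(self, rng):
        X, y = blobs(rng)
        model, _, _ = tune_and_train(X, y, ClassifierConfig(seed=0))
        acc, pred = evaluate(model, X, y)
        assert acc == pytest.approx((pred == y).mean())

    def test_empty_test_set_rejected(self, rng):
        X, y = blobs(rng)
        model, _, _ = tune_and_train(X, y, ClassifierConfig(seed=0))
        with pytest.raises(ValueError):
            evaluate(model, X[:0], y[:0])


class TestNoLeak:
    def test_test_labels_never_influence_fit_or_selection(self, rng):
        X, y = blobs(rng, n=100, sep=1.0)
        train, test = np.arange(80), np.arange(80, 100)
        clf_a = ProgressionClassifier(n_features=10, random_state=0).fit(X[train], y[train])
        y_perturbed = y.copy()
        y_perturbed[test] = ~y_perturbed[test]
        clf_b = ProgressionClassifier(n_features=10, random_state=0).fit(X[train], y_perturbed[train])
        assert clf_a.selected_features_.tolist() == clf_b.selected_features_.tolist()
        assert clf_a.best_params_ == clf_b.best_params_
        assert np.array_equal(clf_a.model_.dual_coef_, clf_b.model_.dual_coef_)
        probe = rng.normal(size=(50, X.shape[1]))
        assert np.array_equal(clf_a.predict(probe), clf_b.predict(probe))


class TestEstimatorApi:
    def test_clone_and_get_params(self):
        clf = ProgressionClassifier(n_features=5, kernel="linear", random_state=9)
        cloned = clone(clf)
        assert cloned.get_params()["n_features"] == 5
        assert cloned.get_params()["kernel"] == "linear"

    def test_predict_before_fit_raises(self, rng):
        with pytest.raises(Exception):
            ProgressionClassifier().predict(rng.normal(size=(3, 4)))


def synthetic_z_and_clinical(rng, n=60, n_patches=40, signal=2.0):
    """Small z-matrix + clinical table with planted progression structure."""
    severity = np.abs(rng.normal(size=n))
    z = rng.normal(size=(n, n_patches))
    roi = np.arange(0, 8)
    z[:, roi] -= signal * severity[:, None]
    ids = [f"p{i:03d}" for i in range(n)]
    z_frame = pd.DataFrame(z, columns=[f"patch_{j+1:04d}" for j in range(n_patches)])
    z_frame.insert(0, "subject_id", ids)
    rows = []
    for visit, h in (("BL", 0.0), ("Y1", 1.0), ("Y3", 3.0)):
        ext = 10 + 5 * severity + (2.5 * severity - 1) * h + rng.normal(0, 2, n)
        cog = 27 - 0.2 * h + rng.normal(0, 1, n)
        for i, sid in enumerate(ids):
            rows.append((sid, visit, "extremity", round(ext[i])))
            rows.append((sid, visit, "total_motor", round(ext[i]) + 5))
            rows.append((sid, visit, "cognitive", round(cog[i])))
    clinical = pd.DataFrame(rows, columns=["subject_id", "visit", "measure", "value"])
    return z_frame, clinical, PatchSet(name="roi", indices=tuple(roi))


def test_full_experiment_produces_all_twelve_cells(rng):
    z, clinical, roi = synthetic_z_and_clinical(rng)
    config = ClassifierConfig(seed=0, n_features=8,
                              c_grid=(0.1, 1.0, 10.0), gamma_grid=(0.01, 0.1))
    reports = run_full_experiment(z, clinical, roi, config)
    assert len(reports) == 12
    cells = {(r.feature_mode, r.outcome, r.horizon) for r in reports}
    assert len(cells) == 12
    for r in reports:
        assert len(r.selected_patches) == 8
        assert 0 <= r.test_accuracy <= 1
        assert len(r.predictions) == len(r.test_ids)
        if r.feature_mode == "restricted_roi":
            assert r.selected_patches == list(roi.indices)
    table = summary_table(reports)
    assert len(table) == 12


def test_full_experiment_is_seed_deterministic(rng):
    z, clinical, roi = synthetic_z_and_clinical(rng)
    config = ClassifierConfig(seed=4, n_features=8,
                              c_grid=(0.1, 1.0), gamma_grid=(0.01, 0.1))
    a = run_full_experiment(z, clinical, roi, config)
    b = run_full_experiment(z, clinical, roi, config)
    assert [r.to_dict() for r in a] == [r.to_dict() for r in b]
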