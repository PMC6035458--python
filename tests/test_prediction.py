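import numpy as np
import pandas as pd
import pytest

from rsdmtox import prediction as pr
from rsdmtox.prediction import (CVConfig, auc, balance_with_smote, bonferroni,
                                compare_rocs, confusion_metrics, delong_test,
                                repeated_cv, roc_curve, smote, svm_sfs)

FAST = CVConfig(repeats=2, sfs_max_features=2, inner_folds=3, seed=3)


class TestSmote:
    def test_two_points_on_segment(self, rng):
        pts = np.array([[0.0, 0.0], [1.0, 2.0]])
        synth = smote(pts, k=1, n_synthetic=50, rng=rng)
        t = synth[:, 0]
        np.testing.assert_allclose(synth[:, 1], 2 * t, atol=1e-12)
        assert (t >= 0).all() and (t <= 1).all()

    def test_inside_minority_bounding_box(self, rng):
        pts = rng.uniform(-3, 5, size=(12, 4))
        synth = smote(pts, k=3, n_synthetic=200, rng=rng)
        assert (synth >= pts.min(axis=0) - 1e-12).all()
        assert (synth <= pts.max(axis=0) + 1e-12).all()

    def test_balancing_equalizes_counts(self, rng):
        for n1 in (3, 7, 11):
            X = rng.normal(size=(30 + n1, 5))
            y = np.array([0] * 30 + [1] * n1)
            Xb, yb = balance_with_smote(X, y, k=5, rng=rng)
            assert (yb == 1).sum() == (yb == 0).sum() == 30
            np.testing.assert_array_equal(Xb[:len(y)], X)  # originals kept

    def test_single_minority_sample_errors(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            smote(np.array([[1.0, 2.0]]), k=1, n_synthetic=3, rng=rng)

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="k must be"):
            smote(np.eye(3), k=3, n_synthetic=3, rng=rng)


class TestConfusionMetrics:
    def test_sen(self):
        assert confusion_metrics(3, 0, 0, 1).SEN == pytest.approx(0.75)

    def test_perfect_acc(self):
        assert confusion_metrics(5, 5, 0, 0).ACC == pytest.approx(1.0)

    def test_all_equal_counts(self):
        assert confusion_metrics(4, 4, 4, 4).ACC == pytest.approx(0.5)

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(confusion_metrics(0, 5, 5, 0).SEN)


class TestAUC:
    def test_perfect_ordering(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_reversed_ordering(self):
        assert auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=60)
        scores[rng.uniform(size=60) < 0.2] = 0.5  # inject ties
        labels = (rng.uniform(size=60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        oracle = np.mean([(1.0 if p > n else 0.5 if p == n else 0.0)
                          for p in pos for n in neg])
        assert auc(scores, labels) == pytest.approx(oracle, abs=1e-12)

    def test_trapezoid_roc_equals_auc(self, rng):
        scores = rng.normal(size=80)
        labels = (rng.uniform(size=80) < 0.3).astype(int)
        labels[:2] = [0, 1]
        fpr, tpr, _ = roc_curve(scores, labels)
        assert np.trapezoid(tpr, fpr) == pytest.approx(auc(scores, labels),
                                                       abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.uniform(size=50) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert auc(np.exp(scores), labels) == pytest.approx(
            auc(scores, labels), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])


class TestSFS:
    def _separable(self, rng, n=60, n_noise=6):
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, n_noise + 1))
        X[:, 3] = y * 2.0 + rng.normal(scale=0.3, size=n)
        return X, y

    def test_single_feature_returned(self, rng):
        X, y = self._separable(rng)
        cols, clf = svm_sfs(X[:, [3]], y, FAST)
        assert cols == [0]

    def test_separating_feature_selected_first(self, rng):
        hits = 0
        for trial in range(20):
            X, y = self._separable(rng)
            cols, _ = svm_sfs(X, y, FAST, seed=trial)
            hits += cols[0] == 3
        assert hits >= 19  # probability >= 0.95

    def test_criterion_non_decreasing(self, rng):
        X, y = self._separable(rng)
        _, clf = svm_sfs(X, y, CVConfig(repeats=1, sfs_max_features=4,
                                        seed=0))
        trace = clf.sfs_trace_
        assert np.all(np.diff(trace) >= 0)

    def test_degenerate_errors(self, rng):
        with pytest.raises(ValueError):
            svm_sfs(rng.normal(size=(10, 3)), np.zeros(10, int), FAST)


class TestRepeatedCV:
    def _table(self, rng, informative):
        n = 40
        y = np.array([0] * 28 + [1] * 12)
        X = rng.normal(size=(n, 8))
        if informative:
            X[:, 2] += y * 3.0
        cols = [f"f{i}" for i in range(8)]
        return pd.DataFrame(X, columns=cols), y

    def test_determinism_same_seed(self, rng):
        table, y = self._table(rng, informative=True)
        r1, k1 = repeated_cv(table, y, FAST)
        r2, k2 = repeated_cv(table, y, FAST)
        np.testing.assert_array_equal(r1.auc, r2.auc)
        np.testing.assert_array_equal(r1.acc, r2.acc)
        pd.testing.assert_series_equal(k1.frequency, k2.frequency)

    def test_informative_feature_found(self, rng):
        table, y = self._table(rng, informative=True)
        result, ranking = repeated_cv(table, y, CVConfig(
            repeats=3, sfs_max_features=2, seed=1))
        assert result.mean_auc > 0.75
        assert ranking.top(1) == ["f2"]

    def test_null_auc_near_half(self, rng):
        # a single 40-sample noise draw can contain a feature that happens
        # to discriminate, so calibration is checked across datasets
        means = []
        for s in range(4):
            table, y = self._table(rng, informative=False)
            result, _ = repeated_cv(table, y, CVConfig(
                repeats=3, sfs_max_features=2, seed=s))
            means.append(result.mean_auc)
        assert 0.38 < np.mean(means) < 0.62

    def test_smote_only_sees_training_rows(self, rng, monkeypatch):
        table, y = self._table(rng, informative=True)
        calls = []
        original = pr.balance_with_smote

        def spy(X, yy, k, rng_):
            calls.append(len(yy))
            return original(X, yy, k, rng_)

        monkeypatch.setattr(pr, "balance_with_smote", spy)
        repeated_cv(table, y, CVConfig(repeats=1, sfs_max_features=1,
                                       seed=0))
        # 5 folds: SMOTE always received the training portion only
        assert len(calls) == 5
        assert all(c in (31, 32) for c in calls)

    def test_metrics_in_unit_interval(self, rng):
        table, y = self._table(rng, informative=True)
        result, _ = repeated_cv(table, y, FAST)
        for arr in (result.acc, result.sen, result.spe, result.auc):
            assert ((arr >= 0) & (arr <= 1)).all()
        lo, hi = result.auc_ci
        assert lo <= hi


class TestROCComparison:
    def test_identical_scores_z0_p1(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.uniform(size=40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_bonferroni_direct(self):
        np.testing.assert_allclose(bonferroni([0.01], m=3), [0.03])
        np.testing.assert_allclose(bonferroni([0.5, 0.9]), [1.0, 1.0])

    def test_z_matches_bootstrap_oracle(self, rng):
        n = 120
        labels = (rng.uniform(size=n) < 0.4).astype(int)
        labels[:2] = [0, 1]
        latent = labels * 1.2 + rng.normal(size=n)
        sa = latent + rng.normal(scale=0.6, size=n)
        sb = 0.5 * latent + rng.normal(scale=1.0, size=n)
        z, _ = delong_test(sa, sb, labels)
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if len(set(labels[idx])) < 2:
                continue
            diffs.append(auc(sa[idx], labels[idx])
                         - auc(sb[idx], labels[idx]))
        boot_z = (auc(sa, labels) - auc(sb, labels)) / np.std(diffs)
        assert z == pytest.approx(boot_z, rel=0.10)

    def test_compare_rocs_requires_pairing(self, rng):
        table = pd.DataFrame(rng.normal(size=(30, 4)),
                             columns=list("abcd"))
        y = np.array([0] * 20 + [1] * 10)
        r1, _ = repeated_cv(table, y, CVConfig(repeats=1,
                                               sfs_max_features=1, seed=0))
        r2, _ = repeated_cv(table, y, CVConfig(repeats=1,
                                               sfs_max_features=1, seed=0))
        z, p = compare_rocs(r1, r2)
        assert p == pytest.approx(1.0)
        bad = pd.DataFrame(rng.normal(size=(28, 4)), columns=list("abcd"))
        yb = np.array([0] * 18 + [1] * 10)
        r3, _ = repeated_cv(bad, yb, CVConfig(repeats=1,
                                              sfs_max_features=1, seed=0))
        with pytest.raises(ValueError, match="paired"):
            compare_rocs(r1, r3)
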