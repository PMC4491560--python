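import numpy as np
import pytest

from taxvision import (
    InputError,
    classification_harness,
    cluster_metrics,
    fuzzy_cmeans,
    percentage_improvement,
    pr_sweep,
)


def _two_clouds(rng, n=40, sep=10.0):
    a = rng.normal(-sep / 2, 1.0, (n, 2))
    b = rng.normal(sep / 2, 1.0, (n, 2))
    X = np.vstack([a, b])
    truth = np.array(["artificial"] * n + ["natural"] * n)
    return X, truth


class TestFuzzyCMeans:
    def test_separated_clouds_confident_memberships(self, rng):
        X, truth = _two_clouds(rng)
        fcm = fuzzy_cmeans(X, c=2, seed=0)
        assert fcm.converged
        assert np.all(fcm.memberships.max(axis=1) >= 0.9)
        hard = fcm.memberships.argmax(axis=1)
        # each cloud lands in one cluster
        assert len(set(hard[:40])) == 1 and len(set(hard[40:])) == 1
        assert hard[0] != hard[-1]

    def test_memberships_row_stochastic(self, rng):
        fcm = fuzzy_cmeans(rng.random((30, 3)), c=2, seed=1)
        np.testing.assert_allclose(fcm.memberships.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(fcm.memberships >= 0)

    def test_equidistant_point_gets_half_membership(self):
        # symmetric 1-D data: the midpoint ends exactly between both centers
        X = np.array([[-2.0], [-2.0], [-1.9], [0.0], [1.9], [2.0], [2.0]])
        fcm = fuzzy_cmeans(X, c=2, seed=3, tol=1e-12, max_iter=2000)
        mid = fcm.memberships[3]
        np.testing.assert_allclose(mid, [0.5, 0.5], atol=1e-6)

    def test_objective_non_increasing(self, rng):
        X, _ = _two_clouds(rng, n=25, sep=3.0)
        fcm = fuzzy_cmeans(X, c=2, seed=5)
        diffs = np.diff(fcm.objective_history)
        assert np.all(diffs <= 1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fuzzy_cmeans(np.zeros((2, 2)), c=2)


class TestClusterMetrics:
    def test_perfect_clustering(self):
        truth = np.array(["natural"] * 5 + ["artificial"] * 5)
        m = cluster_metrics(np.array([0] * 5 + [1] * 5), truth)
        assert (m.f_measure, m.precision, m.recall, m.accuracy) == (1, 1, 1, 1)

    def test_all_positive_balanced(self):
        truth = np.array(["natural"] * 5 + ["artificial"] * 5)
        # degenerate clustering: everything in one cluster
        m = cluster_metrics(np.zeros(10, dtype=int), truth)
        assert m.recall == 1.0
        assert m.precision == 0.5
        assert m.accuracy == 0.5
        assert m.f_measure == pytest.approx(2 / 3)

    def test_cluster_index_permutation_invariance(self):
        truth = np.array(["natural"] * 6 + ["artificial"] * 4)
        a = np.array([0] * 6 + [1] * 4)
        m0 = cluster_metrics(a, truth)
        m1 = cluster_metrics(1 - a, truth)
        assert m0 == m1

    def test_matches_sklearn_on_mapped_labels(self, rng):
        from sklearn.metrics import precision_score, recall_score

        truth = np.where(rng.random(50) < 0.5, "natural", "artificial")
        assign = rng.integers(0, 2, 50)
        m = cluster_metrics(assign, truth)
        from taxvision.evaluate import best_cluster_mapping

        mapping = best_cluster_mapping(assign, truth)
        pred = np.array([mapping[a] for a in assign])
        assert m.precision == pytest.approx(
            precision_score(truth, pred, pos_label="natural")
        )
        assert m.recall == pytest.approx(
            recall_score(truth, pred, pos_label="natural")
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            cluster_metrics(np.zeros(3, dtype=int), np.array(["natural"] * 4))


class TestPrSweep:
    @pytest.fixture
    def clustering(self, rng):
        X, truth = _two_clouds(rng, n=10, sep=6.0)
        return fuzzy_cmeans(X, c=2, seed=0), truth

    def test_zero_threshold_full_recall(self, clustering):
        fcm, truth = clustering
        (precision, recall), = pr_sweep(fcm, truth, [0.0])
        assert recall == 1.0

    def test_impossible_threshold_convention(self, clustering):
        fcm, truth = clustering
        (precision, recall), = pr_sweep(fcm, truth, [1.0])
        if recall == 0.0:
            assert precision == 1.0

    def test_recall_monotone_in_threshold(self, clustering):
        fcm, truth = clustering
        thresholds = np.linspace(0, 1, 21)
        pairs = pr_sweep(fcm, truth, thresholds)
        recalls = [r for _, r in pairs]
        assert all(r0 >= r1 - 1e-12 for r0, r1 in zip(recalls, recalls[1:]))

    def test_bad_threshold_rejected(self, clustering):
        fcm, truth = clustering
        with pytest.raises(InputError):
            pr_sweep(fcm, truth, [1.5])


class TestClassificationHarness:
    def test_separable_data_perfect_score(self, rng):
        X, truth = _two_clouds(rng, n=30, sep=20.0)
        rep = classification_harness(X, truth, train_fraction=0.5, n_runs=10, seed=0)
        assert rep.total == (100.0, 0.0)
        for mean, std in rep.per_class.values():
            assert (mean, std) == (100.0, 0.0)

    def test_shuffled_labels_at_chance(self, rng):
        X = rng.random((200, 5))
        y = np.array(["a", "b"] * 100)
        rep = classification_harness(X, y, train_fraction=0.5, n_runs=10, seed=1)
        assert 40.0 <= rep.total[0] <= 60.0

    def test_seeded_determinism(self, rng):
        X, truth = _two_clouds(rng, n=20, sep=2.0)
        r1 = classification_harness(X, truth, 0.5, n_runs=5, seed=7)
        r2 = classification_harness(X, truth, 0.5, n_runs=5, seed=7)
        assert r1.total == r2.total
        assert r1.per_class == r2.per_class

    def test_weighted_class_means_reproduce_totals(self, rng):
        X, _ = _two_clouds(rng, n=30, sep=3.0)
        y = np.array(["a"] * 20 + ["b"] * 40)
        rep = classification_harness(X, y, train_fraction=0.5, n_runs=4, seed=2)
        # per run, class accuracies weighted by test-split class sizes must
        # reproduce the total accuracy (splits are stratified: 10 vs 20)
        for i in range(4):
            weighted = (
                rep.per_run_class["a"][i] * 10 + rep.per_run_class["b"][i] * 20
            ) / 30
            assert weighted == pytest.approx(rep.per_run_total[i])

    def test_accuracies_bounded(self, rng):
        X = rng.random((40, 3))
        y = np.array(["a", "b"] * 20)
        rep = classification_harness(X, y, 0.5, n_runs=5, seed=0)
        assert 0.0 <= rep.total[0] <= 100.0
        assert rep.total[1] >= 0.0

    def test_small_class_rejected(self, rng):
        X = rng.random((5, 2))
        with pytest.raises(InputError):
            classification_harness(X, np.array(["a"] * 4 + ["b"]), 0.5)


class TestPercentageImprovement:
    @staticmethod
    def _report(per_class):
        from taxvision.evaluate import ClassificationReport

        return ClassificationReport(
            per_class={k: (v, 0.0) for k, v in per_class.items()},
            total=(0.0, 0.0), n_runs=1, train_fraction=0.5, seed=0,
        )

    def test_identical_reports_zero(self):
        r = self._report({"a": 50.0, "b": 80.0})
        assert percentage_improvement(r, r) == 0.0

    def test_known_gains(self):
        base = self._report({"a": 50.0, "b": 80.0})
        new = self._report({"a": 60.0, "b": 88.0})
        assert percentage_improvement(new, base) == pytest.approx(15.0)

    def test_regression_is_negative(self):
        base = self._report({"a": 50.0, "b": 80.0})
        worse = self._report({"a": 40.0, "b": 70.0})
        assert percentage_improvement(worse, base) < 0.0

    def test_zero_baseline_excluded_with_warning(self):
        base = self._report({"a": 0.0, "b": 50.0})
        new = self._report({"a": 10.0, "b": 55.0})
        with pytest.warns(UserWarning):
            assert percentage_improvement(new, base) == pytest.approx(10.0)

    def test_class_mismatch_rejected(self):
        with pytest.raises(InputError):
            percentage_improvement(
                self._report({"a": 1.0}), self._report({"b": 1.0})
            )
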