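"""Single-feature discriminant classification and evaluation protocols."""

import numpy as np
import pytest

from cspshape import (
    feature_analysis,
    fit_single_feature_lda,
    loocv_evaluate,
    repeated_evaluation,
    select_best_feature,
    train_test_evaluate,
)
from cspshape.classify import split_train_test, ImageData

from conftest import tiny_dataset


class TestSingleFeatureLDA:
    def test_symmetric_separation_boundary_at_midpoint(self):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        clf = fit_single_feature_lda(X, y, 0)
        assert clf.accuracy(X[:, 0], y) == 1.0
        assert clf.predict(np.array([0.49]))[0] == "a"
        assert clf.predict(np.array([0.51]))[0] == "b"

    def test_three_wide_classes_classified_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.concatenate(
            [rng.normal(mu, 0.1, size=(10, 1)) for mu in (0.0, 10.0, 20.0)]
        )
        y = np.repeat(["a", "b", "c"], 10)
        clf = fit_single_feature_lda(X, y, 0)
        assert clf.accuracy(X[:, 0], y) == 1.0

    def test_identically_distributed_classes_are_chance_level(self):
        """Permutation baseline: with both classes drawn from the same
        distribution, held-out accuracy averages near 1/2."""
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(100):
            x = rng.normal(size=40)
            y = np.repeat(["a", "b"], 20)
            train = rng.permutation(40)[:20]
            test = np.setdiff1d(np.arange(40), train)
            if len(set(y[train])) < 2:
                continue
            clf = fit_single_feature_lda(x[:, None][train], y[train], 0)
            accs.append(clf.accuracy(x[test], y[test]))
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_matches_sklearn_lda_with_uniform_priors(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(0, 1, (30, 1)), rng.normal(2, 1, (25, 1))])
        y = np.repeat(["a", "b"], [30, 25])
        clf = fit_single_feature_lda(X, y, 0)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        grid = np.linspace(-3, 5, 201)
        np.testing.assert_array_equal(clf.predict(grid), sk.predict(grid[:, None]))

    def test_zero_pooled_variance_falls_back_to_nearest_mean(self):
        X = np.array([[1.0], [1.0], [5.0], [5.0]])
        y = np.array(["a", "a", "b", "b"])
        clf = fit_single_feature_lda(X, y, 0)
        assert clf.pooled_var == 0.0
        assert clf.predict(np.array([2.0]))[0] == "a"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_single_feature_lda(np.ones((3, 1)), np.array(["a"] * 3), 0)


class TestSelectBestFeature:
    def test_separating_coordinate_dominates_noise(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        y = np.repeat(["a", "b"], 10)
        X[:, 4] = np.where(y == "a", 0.0, 10.0) + rng.normal(0, 0.1, 20)
        j, _, _ = select_best_feature(X, y)
        assert j == 4

    def test_tie_goes_to_smallest_index(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        j, _, tied = select_best_feature(X, y)
        assert j == 0
        assert tied == [0, 1]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 13))
        y = np.repeat(["a", "b", "c"], 8)
        j, clf, tied = select_best_feature(X, y)
        # independent re-scan: accuracy first, then standardized margin
        accs, margins = [], []
        for k in range(13):
            c = fit_single_feature_lda(X, y, k)
            accs.append(c.accuracy(X[:, k], y))
            gap = float(np.diff(np.sort(c.class_means)).min())
            sd = np.sqrt(c.pooled_var)
            margins.append(gap / sd if sd > 0 else np.inf)
        expected_tied = [k for k, a in enumerate(accs) if a == max(accs)]
        assert tied == expected_tied
        assert j == min(expected_tied, key=lambda k: (-margins[k], k))


class TestSplitRule:
    def test_ten_and_nine_split_as_printed(self):
        data = [
            ImageData(f"a{i}", "A", np.ones((4, 4)), None) for i in range(10)
        ] + [ImageData(f"b{i}", "B", np.ones((4, 4)), None) for i in range(9)]
        rng = np.random.default_rng(0)
        train, test = split_train_test(data, rng)
        per_group = lambda idx, g: sum(data[i].group == g for i in idx)
        assert per_group(train, "A") == 5 and per_group(test, "A") == 5
        assert per_group(train, "B") == 5 and per_group(test, "B") == 4
        assert sorted(train + test) == list(range(19))

    def test_group_of_one_rejected(self):
        data = [ImageData("a0", "A", np.ones((4, 4)), None),
                ImageData("b0", "B", np.ones((4, 4)), None),
                ImageData("b1", "B", np.ones((4, 4)), None)]
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(data, np.random.default_rng(0))


class TestProtocols:
    def test_separable_groups_reach_perfect_accuracy(self, separable_tiny_dataset):
        acc, j, tied, model = train_test_evaluate(
            separable_tiny_dataset, K=5, split_seed=1, kmeans_seed=2
        )
        assert acc == 1.0
        assert model.M == 10

    def test_repeated_evaluation_bookkeeping(self, separable_tiny_dataset):
        res = repeated_evaluation(separable_tiny_dataset, K=5, n=5, seed=3)
        assert res.n_runs == 5
        assert res.mean_accuracy == pytest.approx(res.accuracies.mean())
        assert res.feature_space_size == 13
        assert all(0 <= a <= 1 for a in res.accuracies)
        assert all(0 <= c <= 5 for c in res.index_counts.values())

    def test_single_run_sd_is_zero(self, separable_tiny_dataset):
        res = repeated_evaluation(separable_tiny_dataset, K=5, n=1, seed=4)
        assert res.sd_accuracy == 0.0

    def test_repeated_evaluation_is_deterministic(self, separable_tiny_dataset):
        r1 = repeated_evaluation(separable_tiny_dataset, K=5, n=3, seed=5)
        r2 = repeated_evaluation(separable_tiny_dataset, K=5, n=3, seed=5)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        assert r1.best_features == r2.best_features
        assert r1.index_counts == r2.index_counts

    def test_loocv_classifies_every_image_once(self, separable_tiny_dataset):
        res = loocv_evaluate(separable_tiny_dataset, K=5, seed=6)
        assert res.S == len(separable_tiny_dataset)
        assert len(res.accuracies) == res.S
        assert res.mean_accuracy == 1.0  # well-separated groups

    def test_feature_analysis_perfect_set_matches_rescan(
        self, separable_tiny_dataset
    ):
        res = feature_analysis(separable_tiny_dataset, K=5, seed=7)
        assert res.best_score == 1.0
        names = [name for _, name in res.perfect_features]
        assert len(names) == len(set(names))
        # every reported CSP feature index has its centre attached
        for k, name in res.perfect_features:
            if name.startswith("CSP_"):
                assert k in res.perfect_centres
                assert len(res.perfect_centres[k]) == 4

    def test_monotone_separation_ladder(self):
        """Widening the filament-length gap between the groups does not
        decrease the mean accuracy, up to the Monte Carlo noise of a
        30-run mean (rungs near saturation fluctuate by ~1 test image)."""
        means = []
        for long_mu in (16.0, 28.0, 45.0):
            data = tiny_dataset({"short": 12.0, "long": long_mu}, seed=21)
            res = repeated_evaluation(data, K=5, n=30, seed=22)
            means.append(res.mean_accuracy)
        assert means[0] <= means[1] + 0.05
        assert means[1] <= means[2] + 0.05
        assert means[0] <= means[2] + 0.05
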