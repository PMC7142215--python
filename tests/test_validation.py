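"""Accuracy, generalization, specificity, and permutation component tests."""

import numpy as np
import pytest

import kinemodes as km
from kinemodes.validation import (
    accuracy,
    accuracy_summary,
    channel_rmse,
    generalization_curve,
    permutation_component_test,
    significant_components,
    specificity,
    summarize_generalization,
)


def brute_force_accuracy(model, X, t):
    """Naive loop implementation of per-subject per-channel RMSE."""
    out = np.empty((X.shape[0], 6))
    for i in range(X.shape[0]):
        x_hat = model.reconstruct(X[i], t)
        for c in range(6):
            sl = slice(101 * c, 101 * (c + 1))
            out[i, c] = np.sqrt(np.mean((X[i, sl] - x_hat[sl]) ** 2))
    return out


class TestAccuracy:
    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((8, 606))
        model = km.KineticPCA().fit(X)
        np.testing.assert_allclose(
            accuracy(model, X, 3), brute_force_accuracy(model, X, 3), atol=1e-12
        )

    def test_full_rank_error_vanishes(self, squat_model, squat_training):
        rmse = accuracy(squat_model, squat_training.samples, None)
        assert np.max(rmse) <= 1e-9

    def test_zero_components_is_deviation_from_mean(self, squat_model, squat_training):
        X = squat_training.samples
        rmse = accuracy(squat_model, X, 0)
        expected = channel_rmse(X, np.broadcast_to(squat_model.mean_, X.shape))
        np.testing.assert_allclose(rmse, expected, atol=1e-12)

    def test_median_non_increasing_in_components(self, squat_model, squat_training):
        X = squat_training.samples
        medians = [
            np.median(accuracy(squat_model, X, t))
            for t in range(squat_model.n_components_ + 1)
        ]
        assert np.all(np.diff(medians) <= 1e-12)

    def test_summary_levels(self, squat_model, squat_training):
        table = accuracy_summary(squat_model, squat_training.samples)
        assert list(table["variance_level"]) == [0.80, 0.90, 0.95, 0.98]
        assert table["rmse_median"].is_monotonic_decreasing
        assert (table["dimensionality"].diff().dropna() >= 0).all()


class TestGeneralization:
    def test_near_identical_cohort_has_tiny_error(self, rng):
        base = rng.standard_normal(606)
        eps = 1e-6
        X = base + eps * rng.standard_normal((10, 606))
        curve = generalization_curve(X, n_values=[4], n_repeats=20, random_state=3)
        assert np.max(curve[4]) <= 10 * eps

    def test_deterministic_under_seed(self, squat_training):
        X = squat_training.samples
        a = generalization_curve(X, n_values=[5], n_repeats=1, random_state=9)
        b = generalization_curve(X, n_values=[5], n_repeats=1, random_state=9)
        np.testing.assert_array_equal(a[5], b[5])

    def test_error_shrinks_with_training_size(self, squat_training):
        X = squat_training.samples
        p = X.shape[0]
        curve = generalization_curve(
            X, n_values=[4, p - 1], n_repeats=100, random_state=5
        )
        summary = summarize_generalization(curve)
        med = dict(zip(summary["n_train"], summary["rmse_median"]))
        assert med[p - 1] <= med[4]

    def test_oversized_training_set_rejected(self, squat_training):
        X = squat_training.samples
        with pytest.raises(ValueError):
            generalization_curve(X, n_values=[X.shape[0]], n_repeats=1)


class TestVirtualSubjects:
    def test_zero_scores_give_mean(self, squat_model):
        x = squat_model.inverse_transform(np.zeros(squat_model.n_components_))
        np.testing.assert_allclose(x, squat_model.mean_, atol=1e-12)

    def test_seeded_draws_reproducible(self, squat_model):
        a = km.sample_virtual_subjects(squat_model, 5, random_state=4)
        b = km.sample_virtual_subjects(squat_model, 5, random_state=4)
        np.testing.assert_array_equal(a, b)

    def test_sample_covariance_recovers_model_covariance(self, rng):
        # compact model (few features) so 50k draws pin the covariance down
        X = rng.standard_normal((12, 24))
        model = km.KineticPCA(feature_layout=(2, 12)).fit(X)
        draws = model.sample(50_000, random_state=8)
        target = (
            model.components_.T
            @ np.diag(model.explained_variance_)
            @ model.components_
        ) * np.outer(model.scale_, model.scale_)
        sample_cov = np.cov(draws.T)
        scale = np.sqrt(np.outer(np.diag(target), np.diag(target)))
        assert np.max(np.abs(sample_cov - target) / scale) < 0.05


class TestSpecificity:
    def test_matches_brute_force_nearest_neighbour(self, squat_model, squat_training):
        X = squat_training.samples
        table = specificity(
            squat_model, X, variance_levels=(0.95,), n_virtual=100, random_state=6,
            excite_all_modes=False, common_draws=False,
        )
        t = squat_model.n_components_for_variance(0.95)
        rng = km._utils.substream(6, "specificity")
        normals = rng.standard_normal((100, t))
        virtual = squat_model.inverse_transform(
            normals * np.sqrt(squat_model.explained_variance_[:t])
        )
        nearest = np.empty(100)
        for i in range(100):
            dists = [np.sqrt(np.mean((virtual[i] - X[j]) ** 2)) for j in range(X.shape[0])]
            nearest[i] = min(dists)
        assert table["rmse_median"].iloc[0] == pytest.approx(np.median(nearest), abs=1e-12)

    def test_degenerate_spectrum_collapses_to_mean_distance(self, rng):
        X = rng.standard_normal((8, 606))
        model = km.KineticPCA().fit(X)
        table = specificity(model, X, variance_levels=(0.95,), n_virtual=10,
                            random_state=1)
        # zero out the spectrum: every virtual subject becomes the mean
        model.explained_variance_ = np.zeros_like(model.explained_variance_)
        collapsed = specificity(model, X, variance_levels=(0.95,), n_virtual=10,
                                random_state=1,
                                dimensionalities=[model.n_components_])
        expected = min(
            np.sqrt(np.mean((model.mean_ - X[j]) ** 2)) for j in range(8)
        )
        assert collapsed["rmse_median"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert table["rmse_iqr"].iloc[0] > 0.0  # non-degenerate model varies

    def test_estimate_stable_when_doubling_draws(self, squat_model, squat_training):
        X = squat_training.samples
        a = specificity(squat_model, X, variance_levels=(0.95,), n_virtual=1500,
                        random_state=2)
        b = specificity(squat_model, X, variance_levels=(0.95,), n_virtual=3000,
                        random_state=2)
        ma, mb = a["rmse_median"].iloc[0], b["rmse_median"].iloc[0]
        assert abs(ma - mb) / ma < 0.05


class TestPermutation:
    def test_p_value_floor(self, rng):
        X = rng.standard_normal((8, 60))
        table = permutation_component_test(X, n_permutations=999, max_components=1,
                                           random_state=0)
        assert table["p_rank_of_roots"].min() >= 1.0 / 1000.0
        assert table["p_equality_of_roots"].min() >= 1.0 / 1000.0

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_component_test(rng.standard_normal((8, 60)), n_permutations=10)

    def test_planted_modes_detected(self):
        spectrum = 606.0 * np.array([0.45, 0.25, 0.15])
        gt = km.make_ground_truth("squat", spectrum=spectrum,
                                  noise_sd=np.sqrt(0.03), seed=101)
        training = km.prepare_cohort(km.simulate_cohort(gt, p=80, seed=202))
        table = permutation_component_test(
            training.samples, n_permutations=199, max_components=5,
            random_state=12,
        )
        p_rank = table["p_rank_of_roots"].to_numpy()
        assert np.all(p_rank[:3] == pytest.approx(1.0 / 200.0))
        assert p_rank[3] > 0.05
        assert significant_components(table) == 3

    def test_sequential_rule_ignores_isolated_hits(self):
        import pandas as pd

        table = pd.DataFrame(
            {"p_rank_of_roots": [0.005, 0.005, 0.3, 0.01], "p_equality_of_roots": [1, 1, 1, 1]}
        )
        assert significant_components(table) == 2
        assert significant_components(table, criterion="equality_of_roots") == 0


class TestValidateModel:
    def test_report_bundle(self, squat_model, squat_training):
        report = km.validate_model(
            squat_model,
            squat_training.samples,
            n_generalization=5,
            generalization_sizes=np.array([4, 8]),
            n_virtual=50,
            n_permutations=99,
            max_components=3,
            random_state=3,
        )
        assert len(report.permutation) == 3
        assert len(report.accuracy) == 4
        summary = report.summary()
        assert summary["n_significant_rank_of_roots"] == 3
        assert report.compactness["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_feature_mismatch_rejected(self, squat_model, rng):
        with pytest.raises(ValueError, match="features"):
            km.validate_model(squat_model, rng.standard_normal((10, 100)))
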