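import numpy as np
import pandas as pd
import pytest

from drslayers.experiments import build_study_table
from drslayers.modeling import (
    CVConfig,
    StudyTable,
    grouped_kfold,
    run_classification,
    run_regression,
)


def _table_from_arrays(X, y, groups, labels_top=None, labels_bottom=None):
    n, p = X.shape
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    frame["sample_id"] = [f"s{i}" for i in range(n)]
    frame["location_id"] = groups
    frame["thickness_mm"] = y
    frame["top_label"] = labels_top if labels_top is not None else "fat"
    frame["bottom_label"] = labels_bottom if labels_bottom is not None else "muscle"
    return StudyTable(frame, tuple(f"f{i}" for i in range(p)))


class TestGroupedKfold:
    def test_balanced_partition_of_twenty_groups(self):
        groups = np.repeat([f"g{i}" for i in range(20)], 3)
        folds = grouped_kfold(groups, 10, seed=0)
        per_fold_groups = [
            len(np.unique(groups[folds == f])) for f in range(10)
        ]
        assert per_fold_groups == [2] * 10

    def test_no_group_spans_two_folds(self):
        rng = np.random.default_rng(0)
        groups = rng.integers(0, 13, size=100)
        folds = grouped_kfold(groups, 5, seed=3)
        frame = pd.DataFrame({"g": groups, "f": folds})
        assert (frame.groupby("g")["f"].nunique() == 1).all()

    def test_deterministic_given_seed(self):
        groups = np.arange(30) % 12
        assert np.array_equal(grouped_kfold(groups, 4, 7), grouped_kfold(groups, 4, 7))
        assert not np.array_equal(grouped_kfold(groups, 4, 7), grouped_kfold(groups, 4, 8))

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_kfold(np.array(["a", "a", "b"]), 3, 0)


class TestRunRegression:
    def test_no_leakage_between_train_and_test_locations(self):
        """Every fold draw keeps each location wholly on one side of the split."""
        groups = np.repeat(np.arange(15), 4)
        for it in range(5):
            folds = grouped_kfold(groups, 10, seed=it)
            for f in range(10):
                assert not set(groups[folds == f]) & set(groups[folds != f])

    def test_noiseless_linear_features_near_interpolation(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 6, size=60)
        X = np.column_stack([y, 2 * y])
        table = _table_from_arrays(X, y, [f"g{i}" for i in range(60)])
        rep = run_regression(table, "exponential_gpr", CVConfig(k=5, iterations=2, base_seed=0))
        assert rep.mean_abs_error < 0.05

    def test_mean_baseline_matches_mean_absolute_deviation(self):
        """Predicting the training mean scores close to the target's mean
        absolute deviation (SD * sqrt(2/pi) under normality)."""
        rng = np.random.default_rng(1)
        y = rng.normal(3.0, 1.5, size=200)
        X = rng.normal(size=(200, 3))
        table = _table_from_arrays(X, y, [f"g{i}" for i in range(200)])
        rep = run_regression(table, "mean_baseline", CVConfig(k=10, iterations=2, base_seed=0))
        expected = 1.5 * np.sqrt(2 / np.pi)
        assert rep.mean_abs_error == pytest.approx(expected, rel=0.15)

    def test_gpr_beats_baseline_on_synthetic_animal_data(self, animal_dataset_small):
        stratum = [s for s in animal_dataset_small if s.top_label == "fat"]
        table = build_study_table(stratum, "peaks")
        cv = CVConfig(k=5, iterations=2, base_seed=1)
        gpr = run_regression(table, "exponential_gpr", cv)
        base = run_regression(table, "mean_baseline", cv)
        assert gpr.mean_abs_error < base.mean_abs_error

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 5, size=40)
        X = np.column_stack([y, np.ones(40)])
        table = _table_from_arrays(X, y, [f"g{i}" for i in range(40)])
        with pytest.warns(UserWarning, match="zero-variance"):
            run_regression(table, "linear_svm", CVConfig(k=4, iterations=1, base_seed=0))

    def test_bland_altman_limits_symmetric(self, animal_dataset_small):
        stratum = [s for s in animal_dataset_small if s.top_label == "muscle"]
        table = build_study_table(stratum, "peaks")
        rep = run_regression(table, "linear_svm", CVConfig(k=5, iterations=1, base_seed=0))
        assert rep.upper_loa - rep.bias == pytest.approx(rep.bias - rep.lower_loa)


class TestRunClassification:
    def test_perfectly_separated_classes_score_one(self):
        rng = np.random.default_rng(0)
        n = 60
        is_fat = np.arange(n) % 2 == 0
        X = rng.normal(size=(n, 2)) + np.where(is_fat[:, None], 10.0, -10.0)
        table = _table_from_arrays(
            X, np.ones(n), [f"g{i}" for i in range(n)],
            labels_top=np.where(is_fat, "fat", "muscle"),
        )
        rep = run_classification(table, "first", CVConfig(k=5, iterations=2, base_seed=0))
        assert rep.accuracy == 1.0 and rep.mcc == 1.0 and rep.auc == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        """Random labels on 200 samples: held-out AUC averaged over several
        independent label draws stays in the chance band (single draws can
        drift a few SD below 0.5 because cross-validation anti-learns noise)."""
        aucs = []
        for seed in (5, 6, 7, 8):
            rng = np.random.default_rng(seed)
            n = 200
            X = rng.normal(size=(n, 4))
            labels = np.array(["fat", "muscle"])[rng.integers(0, 2, size=n)]
            table = _table_from_arrays(
                X, np.ones(n), [f"g{i}" for i in range(n)], labels_top=labels
            )
            rep = run_classification(table, "first", CVConfig(k=5, iterations=5, base_seed=0))
            aucs.append(rep.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_second_layer_excludes_single_layer_samples(self, animal_dataset_small):
        table = build_study_table(animal_dataset_small, "peaks")
        n_zero = int((table.frame["thickness_mm"] == 0).sum())
        assert n_zero >= 2
        rep = run_classification(table, "second", CVConfig(k=5, iterations=1, base_seed=0))
        assert rep.n_samples == len(table.frame) - n_zero

    def test_sensitivity_specificity_consistent_with_counts(self):
        rng = np.random.default_rng(3)
        n = 80
        is_fat = rng.random(n) < 0.5
        X = rng.normal(size=(n, 2)) + np.where(is_fat[:, None], 1.5, -1.5)
        table = _table_from_arrays(
            X, np.ones(n), [f"g{i}" for i in range(n)],
            labels_top=np.where(is_fat, "fat", "muscle"),
        )
        rep = run_classification(table, "first", CVConfig(k=5, iterations=1, base_seed=0))
        for value in (rep.accuracy, rep.sensitivity, rep.specificity, rep.auc):
            assert 0.0 <= value <= 1.0
        assert -1.0 <= rep.mcc <= 1.0

    def test_roc_band_shape(self, animal_dataset_small):
        table = build_study_table(animal_dataset_small, "peaks")
        rep = run_classification(table, "first", CVConfig(k=5, iterations=3, base_seed=0))
        assert rep.roc_fpr.shape == rep.roc_tpr_mean.shape == rep.roc_tpr_sd.shape
        assert rep.roc_tpr_mean[0] <= rep.roc_tpr_mean[-1]
        assert np.all(np.diff(rep.roc_tpr_mean) >= -1e-12)


class TestNoiseDegradation:
    def test_regression_error_increases_with_generator_noise(self):
        """Median held-out absolute error grows strictly across five
        generator noise levels (seeded)."""
        from drslayers.synthetic import simulate_animal_dataset

        medians = []
        for noise in (0.0, 0.01, 0.03, 0.08, 0.2):
            samples = simulate_animal_dataset(n_per_class=30, rng_seed=11, noise_sd=noise)
            table = build_study_table(
                [s for s in samples if s.top_label == "fat"], "peaks"
            )
            rep = run_regression(
                table, "exponential_gpr", CVConfig(k=5, iterations=2, base_seed=2)
            )
            medians.append(float(np.median(rep.per_sample_abs_error)))
        assert all(a < b for a, b in zip(medians, medians[1:]))
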