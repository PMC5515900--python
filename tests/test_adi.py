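"""Add-day-in validation: balancing, feature-count search, leakage."""

import numpy as np
import pytest

from rpca_eeg._rng import substream
from rpca_eeg.adi import (
    AdiCondition, balance_classes, balanced_indices, optimize_feature_count, run_adi,
)
from rpca_eeg.gnb import fit_gnb, predict
from rpca_eeg.synthetic import SyntheticConfig, generate_feature_dataset
from rpca_eeg.mesh import trial_average


def dataset_vectors(**kwargs):
    defaults = dict(n_days=3, trials_per_day=8, n_features=24, background_rank=2,
                    sparse_support=6, windows_per_trial=12, seed=0)
    defaults.update(kwargs)
    ds = generate_feature_dataset(SyntheticConfig(**defaults))
    trials, days, labels = ds.as_arrays()
    X = np.stack([trial_average(t) for t in trials])
    return X, days, labels


class TestBalance:
    def test_balanced_input_fully_retained(self, rng):
        y = np.repeat(["a", "b"], 10)
        idx = balanced_indices(y, rng)
        assert sorted(idx) == list(range(20))

    def test_majority_subsampled_without_replacement(self, rng):
        y = np.array(["a"] * 12 + ["b"] * 8)
        X = np.arange(20)[:, None].astype(float)
        Xb, yb = balance_classes(X, y, rng)
        assert (yb == "a").sum() == (yb == "b").sum() == 8
        assert len(np.unique(Xb)) == 16  # no repeats

    def test_fixed_rng_reproducible(self):
        y = np.array(["a"] * 9 + ["b"] * 5)
        i1 = balanced_indices(y, np.random.default_rng(7))
        i2 = balanced_indices(y, np.random.default_rng(7))
        assert np.array_equal(i1, i2)

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValueError):
            balanced_indices(np.array(["a", "a", "a"]), rng)


class TestOptimizeFeatureCount:
    def test_perfect_first_feature_selects_one(self, rng):
        n = 20
        y = np.repeat(["a", "b"], n // 2)
        X = rng.standard_normal((n, 10))
        X[:, 0] = np.where(y == "a", -5.0, 5.0) + 0.01 * rng.standard_normal(n)
        order = np.arange(10)
        d_star, curve = optimize_feature_count(X, y, order, reps=10, folds=5, seed=0)
        assert d_star == 1
        assert curve[0] >= 0.99

    def test_pure_noise_stays_near_chance_with_first_argmax(self):
        """Chance-level oracle over 20 seeds; smallest-argmax tie-break."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((20, 8))
            y = np.repeat(["a", "b"], 10)
            d_star, curve = optimize_feature_count(X, y, np.arange(8),
                                                   reps=5, folds=5, seed=seed)
            assert d_star == int(np.argmax(curve)) + 1
            accs.append(curve.mean())
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_curve_matches_brute_force_per_count(self, rng):
        """Oracle: refit an independent GNB for every top-d subset and fold."""
        X = rng.standard_normal((16, 6))
        y = np.repeat(["a", "b"], 8)
        X[y == "b", :2] += 1.0
        order = np.arange(6)
        seed = 3
        d_star, curve = optimize_feature_count(X, y, order, reps=2, folds=4, seed=seed)

        from rpca_eeg.adi import _stratified_folds
        brute = np.zeros(6)
        for rep in range(2):
            idx = balanced_indices(y, substream(seed, "balance", rep))
            Xb, yb = X[idx], y[idx]
            folds = _stratified_folds(yb, 4, substream(seed, "folds", rep))
            correct = np.zeros(6)
            for test_idx in folds:
                train_idx = np.setdiff1d(np.arange(yb.size), test_idx)
                for d in range(1, 7):
                    cols = order[:d]
                    model = fit_gnb(Xb[train_idx][:, cols], yb[train_idx])
                    pred = predict(model, Xb[test_idx][:, cols])
                    correct[d - 1] += (pred == yb[test_idx]).sum()
            brute += correct / yb.size
        assert np.allclose(curve, brute / 2)

    def test_too_few_trials_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        y = np.repeat(["a", "b"], 3)
        with pytest.raises(ValueError):
            optimize_feature_count(X, y, np.arange(3), reps=1, folds=5, seed=0)


class TestRunAdi:
    def test_five_days_give_four_conditions(self):
        X, days, labels = dataset_vectors(n_days=5, trials_per_day=6)
        report = run_adi(X, days, labels, reps=2, folds=3, seed=0)
        assert len(report.conditions) == 4
        comps = [(c.condition.training_days, c.condition.test_day)
                 for c in report.conditions]
        assert comps == [((1,), 2), ((1, 2), 3), ((1, 2, 3), 4), ((1, 2, 3, 4), 5)]

    def test_temporal_honesty_enforced(self):
        with pytest.raises(ValueError):
            AdiCondition(training_days=(1, 2), test_day=2)
        with pytest.raises(ValueError):
            AdiCondition(training_days=(2, 3), test_day=4)

    def test_no_shift_separable_data_near_perfect(self):
        accs = []
        for seed in range(10):
            X, days, labels = dataset_vectors(day_drift=0.0, effect_size=3.0,
                                              noise_sd=0.3, seed=seed)
            report = run_adi(X, days, labels, reps=3, folds=4, seed=seed)
            accs.append(np.mean([c.test_accuracy for c in report.conditions]))
        assert np.mean(accs) >= 0.95

    def test_permuted_labels_at_chance(self):
        accs = []
        for seed in range(20):
            X, days, labels = dataset_vectors(seed=seed)
            rng = np.random.default_rng(seed)
            for d in np.unique(days):
                sel = days == d
                labels[sel] = rng.permutation(labels[sel])
            try:
                report = run_adi(X, days, labels, reps=3, folds=3, seed=seed)
            except ValueError:
                continue  # permutation emptied a class on some day
            accs.append(np.mean([c.test_accuracy for c in report.conditions]))
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_no_leakage_from_test_day(self):
        """Replacing test-day data with noise changes only test accuracies."""
        X, days, labels = dataset_vectors(n_days=3, trials_per_day=8, seed=4)
        r1 = run_adi(X, days, labels, reps=3, folds=4, seed=9)
        X2 = X.copy()
        X2[days == 3] = np.random.default_rng(0).standard_normal(X2[days == 3].shape)
        r2 = run_adi(X2, days, labels, reps=3, folds=4, seed=9)
        for c1, c2 in zip(r1.conditions, r2.conditions):
            assert c1.selected_count == c2.selected_count
            assert np.array_equal(c1.selected_indices, c2.selected_indices)
            assert np.allclose(c1.cv_curve, c2.cv_curve)
        # first condition tests day 2, untouched; last tests the noised day 3
        assert r1.conditions[0].test_accuracy == r2.conditions[0].test_accuracy

    def test_missing_class_on_a_day_rejected(self):
        X, days, labels = dataset_vectors()
        labels[days == 2] = "happiness"
        with pytest.raises(ValueError, match="day 2"):
            run_adi(X, days, labels, reps=1, folds=2, seed=0)

    def test_neutral_must_be_excluded(self):
        X, days, labels = dataset_vectors()
        labels[0] = "neutral"
        with pytest.raises(ValueError, match="neutral"):
            run_adi(X, days, labels, reps=1, folds=2, seed=0)

    def test_summary_frame(self):
        X, days, labels = dataset_vectors()
        report = run_adi(X, days, labels, reps=2, folds=3, seed=0)
        df = report.summary()
        assert len(df) == 2
        assert {"condition", "selected_features", "test_accuracy"} <= set(df.columns)
        assert df["test_accuracy"].between(0, 1).all()
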