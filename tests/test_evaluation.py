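import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from conftest import small_model_config
from eegdcn.evaluation import (
    ConfusionCounts,
    FoldPlan,
    MetricReport,
    TrainSettings,
    binarize_ratings,
    compute_metrics,
    confusion_counts,
    make_folds,
    train_and_evaluate,
    train_model,
)


class TestBinarizeRatings:
    def test_threshold_application(self):
        np.testing.assert_array_equal(binarize_ratings([7.5, 3.0]), [1, 0])

    def test_exact_threshold_goes_low(self):
        assert binarize_ratings([5.0])[0] == 0

    def test_vector_of_40_scores(self, rng):
        scores = rng.uniform(1, 9, 40)
        labels = binarize_ratings(scores)
        assert labels.shape == (40,)
        assert set(np.unique(labels)) <= {0, 1}

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            binarize_ratings([0.5])
        with pytest.raises(ValueError, match="outside"):
            binarize_ratings([9.5])


class TestMakeFolds:
    def test_2400_segments_five_folds_of_480(self):
        labels = np.tile([0, 1], 1200)
        subjects = np.zeros(2400, dtype=int)
        plan = make_folds(labels, subjects, "kfold", k=5, seed=0)
        sizes = np.bincount(plan.assignments)
        np.testing.assert_array_equal(sizes, [480] * 5)

    def test_loso_one_fold_per_subject(self):
        subjects = np.repeat(np.arange(15), 4)
        labels = np.tile([0, 1], 30)
        plan = make_folds(labels, subjects, "loso")
        assert plan.n_folds == 15
        for fold, _, test in plan.folds():
            assert len(np.unique(subjects[test])) == 1

    def test_k_of_one_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            make_folds(np.array([0, 1]), np.zeros(2), "kfold", k=1)

    def test_k_exceeding_samples_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(np.array([0, 1]), np.zeros(2), "kfold", k=3)

    def test_deterministic_under_seed(self):
        labels = np.tile([0, 1], 20)
        subjects = np.repeat([0, 1], 20)
        a = make_folds(labels, subjects, "kfold", k=4, seed=9)
        b = make_folds(labels, subjects, "kfold", k=4, seed=9)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        c = make_folds(labels, subjects, "kfold", k=4, seed=10)
        assert not np.array_equal(a.assignments, c.assignments)

    def test_stratification_within_subject(self):
        labels = np.tile([0, 1], 25)
        subjects = np.zeros(50, dtype=int)
        plan = make_folds(labels, subjects, "kfold", k=5, seed=1)
        for _, _, test in plan.folds():
            # both classes present in every fold
            assert set(labels[test]) == {0, 1}

    @given(
        n_per_class=st.integers(3, 30),
        k=st.integers(2, 5),
        seed=st.integers(0, 100),
    )
    @hsettings(max_examples=30, deadline=None)
    def test_partition_properties(self, n_per_class, k, seed):
        labels = np.tile([0, 1], n_per_class)
        subjects = np.zeros(2 * n_per_class, dtype=int)
        if k > 2 * n_per_class:
            return
        plan = make_folds(labels, subjects, "kfold", k=k, seed=seed)
        # folds partition the index set with sizes differing by <= 1
        sizes = np.bincount(plan.assignments, minlength=k)
        assert sizes.sum() == 2 * n_per_class
        assert sizes.max() - sizes.min() <= 1


class TestMetrics:
    def test_worked_example(self):
        rep = compute_metrics(ConfusionCounts(tp=50, tn=40, fp=5, fn=5))
        assert rep.accuracy == pytest.approx(90.0)
        assert rep.precision == pytest.approx(100 * 50 / 55)
        assert rep.recall == pytest.approx(100 * 50 / 55)

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f_score) == (100.0, 100.0, 100.0, 100.0)

    def test_undefined_precision_absent_with_warning(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert rep.precision is None
        assert rep.f_score is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_accuracy_equals_one_minus_error_rate(self, rng):
        y_true = rng.integers(0, 2, 100)
        y_pred = rng.integers(0, 2, 100)
        counts = confusion_counts(y_true, y_pred, positive=1)
        rep = compute_metrics(counts)
        assert rep.accuracy == pytest.approx(100 * (1 - np.mean(y_true != y_pred)))

    @given(tp=st.integers(1, 50), tn=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @hsettings(max_examples=50, deadline=None)
    def test_f_between_precision_and_recall(self, tp, tn, fp, fn):
        rep = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert min(rep.precision, rep.recall) - 1e-9 <= rep.f_score <= max(rep.precision, rep.recall) + 1e-9


class TestFoldPlanInvariants:
    def test_unbalanced_kfold_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            FoldPlan(scheme="kfold", n_folds=2, assignments=np.array([0, 0, 0, 1]), seed=0)

    def test_out_of_range_assignment_rejected(self):
        with pytest.raises(ValueError, match="range"):
            FoldPlan(scheme="kfold", n_folds=2, assignments=np.array([0, 2]), seed=0)


@pytest.fixture(scope="module")
def quick_settings():
    return TrainSettings(epochs=3, batch_size=32)


class TestTraining:
    def test_reproducible_under_seed(self, easy_features, small_config, quick_settings):
        x, y, subjects = easy_features
        x, y, subjects = x[:64], y[:64], subjects[:64]
        plan = make_folds(y, subjects, "kfold", k=2, seed=3)
        a = train_and_evaluate(x, y, small_config, plan, quick_settings)
        b = train_and_evaluate(x, y, small_config, plan, quick_settings)
        assert a["folds"] == b["folds"]
        assert a["epoch_losses"] == b["epoch_losses"]

    def test_single_class_training_warns(self, easy_features, small_config, quick_settings):
        x, y, _ = easy_features
        idx = np.flatnonzero(y == 0)[:16]
        with pytest.warns(UserWarning, match="single class"):
            train_model(x[idx], y[idx], small_config, quick_settings)

    def test_shuffled_labels_stay_at_chance(self, easy_features, quick_settings):
        x, y, subjects = easy_features
        rng = np.random.default_rng(0)
        y_shuffled = rng.permutation(y)
        plan = make_folds(y_shuffled, subjects, "kfold", k=2, seed=0)
        cfg = small_model_config()
        summary = train_and_evaluate(x, y_shuffled, cfg, plan, quick_settings)
        # binomial chance band: 50% +/- 3 sd at n/2 test samples per fold
        n_test = len(y) // 2
        sd = 100 * 0.5 / np.sqrt(n_test)
        assert abs(summary["mean_accuracy"] - 50.0) <= 3 * sd + 5.0

    def test_class_recovery_improves_with_separation(self):
        # parameter-recovery analogue: accuracy grows with inter-class
        # band-power separation (3 generator settings, tiny budget)
        from eegdcn.features import featurize_recording
        from eegdcn.montage import build_electrode_map
        from eegdcn.synthetic import BAND_POWER_PRESETS, SynthSpec, generate_recording

        accuracies = []
        for preset in ("hard-binary", "medium-binary", "easy-binary"):
            spec = SynthSpec(
                n_trials_per_subject=8,
                n_channels=32,
                trial_seconds=8.0,
                band_power_map=BAND_POWER_PRESETS[preset],
                noise_sd=0.8,
                seed=21,
            )
            rec = generate_recording(spec)
            emap = build_electrode_map(rec.channel_names)
            x, y, subjects, _ = featurize_recording(rec, emap)
            plan = make_folds(y, subjects, "kfold", k=2, seed=0)
            summary = train_and_evaluate(
                x, y, small_model_config(), plan, TrainSettings(epochs=4, batch_size=16)
            )
            accuracies.append(summary["mean_accuracy"])
        assert accuracies[0] <= accuracies[1] + 10.0  # allow noise on the hard step
        assert accuracies[2] >= accuracies[0]
        assert accuracies[2] >= 90.0

    def test_empty_test_fold_rejected(self, easy_features, small_config, quick_settings):
        x, y, _ = easy_features
        x, y = x[:8], y[:8].copy()
        plan = FoldPlan(scheme="loso", n_folds=2, assignments=np.zeros(8, dtype=int), seed=0)
        with pytest.raises(ValueError, match="empty (test|training)"):
            train_and_evaluate(x, y, small_config, plan, quick_settings)
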