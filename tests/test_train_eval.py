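"""Fold construction, metrics (cross-checked against scikit-learn), the
training loop's checkpoint contract, cross-validation plumbing and the
paired variant comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from difnet.model import build_difnet
from difnet.train_eval import (
    ConfusionMatrix,
    TrainConfig,
    compare_variants,
    compute_metrics,
    crossval,
    evaluate,
    make_folds,
    train,
)

from conftest import tiny_config


class TestMakeFolds:
    def test_partition_arithmetic(self, small_epochs):
        n = small_epochs.n_epochs
        plan = make_folds(small_epochs, k=4, seed=0)
        sizes = [len(plan.fold_indices(f)[1]) for f in range(4)]
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 2  # stratified dealing stays balanced
        all_test = np.concatenate([plan.fold_indices(f)[1] for f in range(4)])
        assert sorted(all_test) == list(range(n))

    def test_same_seed_identical_plan(self, small_epochs):
        a = make_folds(small_epochs, k=4, seed=3)
        b = make_folds(small_epochs, k=4, seed=3)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.plan_hash() == b.plan_hash()
        c = make_folds(small_epochs, k=4, seed=4)
        assert a.plan_hash() != c.plan_hash()

    def test_stratification_spreads_classes(self, small_epochs):
        plan = make_folds(small_epochs, k=4, seed=0)
        for f in range(4):
            _, test = plan.fold_indices(f)
            labels = small_epochs.labels[test]
            assert len(np.unique(labels)) == 2

    def test_too_many_folds_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            make_folds(small_epochs, k=small_epochs.n_epochs + 1)

    def test_finetune_eighty_twenty_split(self, small_epochs):
        plan = make_folds(small_epochs, mode="subject_finetune", seed=0)
        for subj, (tr, te) in plan.finetune_splits.items():
            n = len(tr) + len(te)
            assert len(tr) == int(np.floor(0.8 * n))
            assert np.all(tr < te.min())  # chronological by default

    def test_finetune_297_trial_subject(self):
        """A 300 s recording's 297 trials split 237 train / 60 test."""
        import pandas as pd
        from difnet.preprocess import EpochSet

        n = 297
        es = EpochSet(
            data=np.zeros((n, 1, 8)), sampling_rate=250.0,
            channel_names=("Cz",), labels=np.zeros(n, dtype=int),
            subject_ids=np.array(["s1"] * n),
            demographics=pd.DataFrame({"subject_id": ["s1"] * n}),
        )
        plan = make_folds(es, mode="subject_finetune")
        tr, te = plan.finetune_splits["s1"]
        assert (len(tr), len(te)) == (237, 60)

    def test_blocked_mode_is_chronological_and_purged(self, small_epochs):
        plan = make_folds(small_epochs, k=2, mode="blocked", seed=0)
        w, s = small_epochs.window_samples, small_epochs.step_samples
        purge = int(np.ceil(w / s)) - 1
        for subj in np.unique(small_epochs.subject_ids):
            idx = np.flatnonzero(small_epochs.subject_ids == subj)
            folds = plan.assignments[idx]
            # every subject spans both folds, chronological blocks, with the
            # boundary-overlapping epochs excluded from both
            assert set(folds) == {-1, 0, 1} if purge else {0, 1}
            kept = folds[folds >= 0]
            assert (np.diff(kept) >= 0).all()
        # no training window shares samples with any test window
        for fold in range(2):
            tr, te = plan.fold_indices(fold)
            starts = {}
            pos = 0
            for subj in small_epochs.subject_ids:
                starts.setdefault(subj, 0)
            # reconstruct start sample of each epoch within its subject
            start_of = np.empty(small_epochs.n_epochs, dtype=int)
            for subj in np.unique(small_epochs.subject_ids):
                idx = np.flatnonzero(small_epochs.subject_ids == subj)
                start_of[idx] = np.arange(len(idx)) * s
            for i in tr:
                for j in te:
                    if small_epochs.subject_ids[i] == small_epochs.subject_ids[j]:
                        assert abs(start_of[i] - start_of[j]) >= w

    def test_subject_disjoint_mode(self, small_epochs):
        plan = make_folds(small_epochs, k=2, mode="subject_disjoint", seed=0)
        for f in range(2):
            tr, te = plan.fold_indices(f)
            assert not (set(small_epochs.subject_ids[tr])
                        & set(small_epochs.subject_ids[te]))


class TestMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionMatrix(tp=50, tn=50, fp=0, fn=0))
        assert rep.accuracy == 1.0
        assert rep.kappa == 1.0
        assert rep.f1 == 1.0

    def test_hand_computed_example(self):
        rep = compute_metrics(ConfusionMatrix(tp=40, tn=40, fp=10, fn=10))
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.kappa == pytest.approx(0.6)  # P_e = 0.5 under N^2 margins
        assert rep.precision == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_one_class_prediction_on_balanced_data_gives_zero_kappa(self):
        rep = compute_metrics(ConfusionMatrix(tp=50, tn=0, fp=50, fn=0))
        assert rep.kappa == pytest.approx(0.0)
        assert rep.accuracy == pytest.approx(0.5)

    def test_undefined_metrics_flagged_not_zeroed(self):
        rep = compute_metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=5))
        assert rep.precision is None
        assert "precision" in rep.undefined

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40))
    def test_matches_sklearn_on_random_matrices(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        from sklearn.metrics import cohen_kappa_score, f1_score

        y_true = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
        y_pred = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
        rep = compute_metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        assert rep.accuracy == pytest.approx((y_true == y_pred).mean())
        if len(np.unique(y_pred)) == 2 and len(np.unique(y_true)) == 2:
            assert rep.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12)
        if rep.f1 is not None:
            assert rep.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)

    def test_f1_is_harmonic_mean(self):
        rep = compute_metrics(ConfusionMatrix(tp=30, tn=20, fp=14, fn=6))
        p, r = rep.precision, rep.recall
        assert rep.f1 == pytest.approx(2 * p * r / (p + r))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=0, tn=0, fp=0, fn=0)


def separable_dataset(n=48, n_channels=4, n_samples=500, seed=0):
    """Class 1 carries a strong 20 Hz oscillation; class 0 is pure noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / 250.0
    y = np.arange(n) % 2
    x = rng.normal(size=(n, n_channels, n_samples))
    x[y == 1] += 3.0 * np.sin(2 * np.pi * 20.0 * t)
    # per-channel z-scoring, as the pipeline would deliver
    x = (x - x.mean(-1, keepdims=True)) / x.std(-1, keepdims=True)
    return x, y


class TestTrain:
    def test_smoke_two_epochs(self):
        x, y = separable_dataset(n=16)
        model = build_difnet(tiny_config(), seed=0)
        history = train(model, x, y, None,
                        TrainConfig(epochs=2, batch_size=8, seed=0))
        assert len(history["loss"]) == 2
        assert history["best_epoch"] >= 0

    def test_separable_data_reaches_perfect_training_accuracy(self):
        x, y = separable_dataset()
        model = build_difnet(tiny_config(), seed=1)
        history = train(model, x, y, None,
                        TrainConfig(epochs=12, batch_size=16, seed=1))
        assert max(history["accuracy"]) == 1.0

    def test_checkpoint_restores_best_validation_epoch(self):
        x, y = separable_dataset(n=64, seed=2)
        xv, yv = x[48:], y[48:]
        x, y = x[:48], y[:48]
        model = build_difnet(tiny_config(), seed=2)
        history = train(model, x, y, None,
                        TrainConfig(epochs=6, batch_size=16, seed=2),
                        x_val=xv, y_val=yv)
        from difnet.train_eval import predict

        restored_acc = float((predict(model, xv) == yv).mean())
        assert restored_acc == pytest.approx(history["best_val_accuracy"])
        assert history["best_val_accuracy"] == max(history["val_accuracy"])

    def test_deterministic_given_seed(self):
        x, y = separable_dataset(n=16)
        outs = []
        for _ in range(2):
            model = build_difnet(tiny_config(), seed=3)
            train(model, x, y, None, TrainConfig(epochs=2, batch_size=8, seed=3))
            model.eval()
            outs.append(model.forward(x[:4][:, None]).data)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestCrossval:
    def test_two_fold_aggregation(self, small_epochs):
        plan = make_folds(small_epochs, k=2, seed=0)
        result = crossval(
            lambda s: build_difnet(tiny_config(n_channels=4, n_samples=500),
                                   seed=s),
            small_epochs, plan,
            TrainConfig(epochs=1, batch_size=16, seed=0),
        )
        assert len(result["fold_reports"]) == 2
        assert result["mean_accuracy"] == pytest.approx(
            result["fold_accuracies"].mean())
        assert result["plan_hash"] == plan.plan_hash()

    def test_demographics_are_fold_normalized(self, small_epochs):
        plan = make_folds(small_epochs, k=2, seed=1)
        result = crossval(
            lambda s: build_difnet(
                tiny_config(indicators="AY", n_channels=4, n_samples=500),
                seed=s),
            small_epochs, plan,
            TrainConfig(epochs=1, batch_size=16, seed=1),
            indicator_columns=["age", "education_years"],
        )
        assert len(result["fold_accuracies"]) == 2


class TestCompareVariants:
    def test_identical_vectors_give_p_one(self):
        acc = np.array([0.8, 0.9, 0.85])
        assert compare_variants(acc, acc) == 1.0

    def test_constant_shift_with_tiny_noise_is_significant(self):
        rng = np.random.default_rng(0)
        base = 0.9 + 0.001 * rng.normal(size=10)
        assert compare_variants(base + 0.05, base) < 1e-3

    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            compare_variants(rng.normal(size=10), rng.normal(size=10)) < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08

    def test_unpaired_or_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            compare_variants(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            compare_variants(np.ones(1), np.ones(1))
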