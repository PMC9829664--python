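"""Cross-validation, early stopping, estimator training and checkpoints."""

import numpy as np
import pytest

from fracrecon.estimator import EarlyStopping, FracReconNet
from fracrecon.training import (
    ExperimentConfig,
    augmented_training_samples,
    load_checkpoint,
    make_study_cohort,
    run_experiment,
    save_checkpoint,
    stratified_kfold,
    infer,
)

TINY = dict(
    levels=3,
    image_size=16,
    n_classes=3,
    base_channels=4,
    growth=2,
    channels_3d=2,
    up_channels=4,
    fusion_channels=4,
    fusion_convs=1,
    learning_rate=3e-3,
    max_steps=8,
    random_state=0,
)


@pytest.fixture(scope="module")
def tiny_dataset():
    cohort = make_study_cohort(n_intact=1, n_fractured=1, grid=16, seed=5)
    X = np.stack([s.arrays(3)[0] for s in cohort])
    y = np.stack([s.arrays(3)[1] for s in cohort])
    return X, y


class TestStratifiedKFold:
    def test_even_split_two_types(self):
        tags = ["intact"] * 10 + ["nondisplaced"] * 10
        folds = stratified_kfold(tags, k=5, seed=0)
        tags = np.array(tags)
        for f in range(5):
            sel = folds == f
            assert (tags[sel] == "intact").sum() == 2
            assert (tags[sel] == "nondisplaced").sum() == 2

    def test_per_type_counts_differ_by_at_most_one(self):
        tags = ["intact"] * 7 + ["nondisplaced"] * 9 + ["displaced"] * 5
        folds = stratified_kfold(tags, k=4, seed=1)
        tags = np.array(tags)
        for t in np.unique(tags):
            counts = [((folds == f) & (tags == t)).sum() for f in range(4)]
            assert max(counts) - min(counts) <= 1

    def test_deterministic(self):
        tags = ["intact"] * 6 + ["nondisplaced"] * 6
        np.testing.assert_array_equal(
            stratified_kfold(tags, 3, seed=2), stratified_kfold(tags, 3, seed=2)
        )

    def test_too_few_samples_of_a_type_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["intact"] * 10 + ["displaced"] * 2, k=5)


class TestEarlyStopping:
    def test_plateau_triggers_exactly_at_patience_exhaustion(self):
        stopper = EarlyStopping(patience=3)
        losses = [1.0, 0.8, 0.8, 0.8, 0.8]  # then 3 non-improving evaluations
        decisions = [stopper.update(v) for v in losses]
        assert decisions == [False, False, False, False, True]
        assert stopper.best == 0.8
        assert stopper.best_round == 1

    def test_improvement_resets_patience(self):
        stopper = EarlyStopping(patience=2)
        seq = [1.0, 0.9, 0.95, 0.8, 0.85, 0.9]
        decisions = [stopper.update(v) for v in seq]
        assert decisions == [False, False, False, False, False, True]

    def test_invalid_patience(self):
        with pytest.raises(ValueError):
            EarlyStopping(patience=0)


class TestFracReconNetEstimator:
    def test_smoke_fit_records_monotone_steps(self, tiny_dataset):
        X, y = tiny_dataset
        est = FracReconNet(**TINY)
        est.fit(X, y)
        steps = [r["step"] for r in est.history_]
        assert steps == list(range(len(steps)))
        assert len(est.loss_curve_) == TINY["max_steps"]
        assert np.isfinite(est.loss_curve_).all()

    def test_fit_is_deterministic_given_seed(self, tiny_dataset):
        X, y = tiny_dataset
        a = FracReconNet(**TINY).fit(X, y)
        b = FracReconNet(**TINY).fit(X, y)
        np.testing.assert_array_equal(a.loss_curve_, b.loss_curve_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_early_stopping_on_validation(self, tiny_dataset):
        X, y = tiny_dataset
        est = FracReconNet(**{**TINY, "max_steps": 40, "eval_every": 2, "patience": 2})
        est.fit(X, y, X_val=X, y_val=y)
        assert hasattr(est, "best_val_loss_")
        assert est.n_steps_ <= 40

    def test_predict_contracts(self, tiny_dataset):
        X, y = tiny_dataset
        est = FracReconNet(**TINY).fit(X, y)
        probs = est.predict_proba(X)
        assert probs.shape == (2, 3, 16, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        pred = est.predict(X)
        assert set(np.unique(pred)) <= {0, 1, 2}

    def test_unfitted_predict_rejected(self, tiny_dataset):
        X, _ = tiny_dataset
        with pytest.raises(RuntimeError):
            FracReconNet(**TINY).predict(X)

    def test_bad_input_shapes_rejected(self):
        est = FracReconNet(**TINY)
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 3, 16, 16)), np.zeros((2, 16, 16, 16)))
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 2, 8, 8)), np.zeros((2, 8, 8, 8)))

    def test_sklearn_get_set_params_round_trip(self):
        est = FracReconNet(**TINY)
        params = est.get_params()
        est2 = FracReconNet().set_params(**params)
        assert est2.get_params() == params


@pytest.fixture(scope="module")
def demo_result():
    cfg = ExperimentConfig(
        variants=("3dreconnet", "3dreconnet-ac", "fracreconnet"),
        n_intact=4,
        n_fractured=4,
        grid=16,
        folds=2,
        seed=3,
        rotational_errors=(0.0, 10.0),
        estimator_params=dict(
            levels=3, base_channels=4, growth=2, channels_3d=2,
            up_channels=4, fusion_channels=4, fusion_convs=1,
            learning_rate=3e-3, max_steps=6,
        ),
    )
    return run_experiment(cfg)


class TestRunExperiment:
    def test_emits_per_type_summary_for_every_variant(self, demo_result):
        assert set(demo_result.per_variant) == {
            "3dreconnet", "3dreconnet-ac", "fracreconnet",
        }
        for res in demo_result.per_variant.values():
            rows = list(res.summary["sample_type"])
            assert rows[0] == "Overall"
            assert {"intact", "nondisplaced"} <= set(rows)
            assert (res.summary["massd"] >= 0).all()

    def test_fold_means_and_ttests_shape(self, demo_result):
        fm = demo_result.fold_means
        assert len(fm) == 3 * 2  # variants × folds
        tt = demo_result.ttests
        assert tt is not None and {"a", "b", "metric", "t", "p"} <= set(tt.columns)

    def test_rotational_sweep_reported(self, demo_result):
        rot = demo_result.rotational
        assert rot is not None
        assert set(rot["error_deg"]) == {0.0, 10.0}

    def test_fracreconnet_gets_augmented_training_samples(self):
        cohort = make_study_cohort(n_intact=3, n_fractured=1, grid=16, seed=2)
        cfg = ExperimentConfig(n_intact=3, n_fractured=1, grid=16, seed=2)
        extra = augmented_training_samples(cohort, cfg, seed=0)
        assert len(extra) == 3  # ratio 1.0 × intact count
        assert all(s.type_tag == "nondisplaced" for s in extra)
        assert all(s.fragments.n >= 2 for s in extra)


class TestCheckpointAndInfer:
    def test_checkpoint_round_trip_reproduces_predictions(self, tiny_dataset, tmp_path):
        X, y = tiny_dataset
        est = FracReconNet(**TINY).fit(X, y)
        save_checkpoint(est, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_array_equal(est.predict(X), back.predict(X))

    def test_infer_returns_world_frame_labels(self, tiny_dataset):
        X, y = tiny_dataset
        est = FracReconNet(**TINY).fit(X, y)
        labels, probs = infer(est, X[0])
        assert labels.shape == (16, 16, 16)
        assert probs.shape == (3, 16, 16, 16)
        assert set(np.unique(labels.data)) <= {0, 1, 2}
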