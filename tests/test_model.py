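"""Network contracts, training behavior and subject-level cross-validation."""

import numpy as np
import pytest

from splenovol._nn import UNet2D, segmentation_loss
from splenovol.core import MaskVolume, TrainingDivergedError
from splenovol.model import (
    ModelConfig,
    SplitPlan,
    build_model,
    build_training_set,
    load_checkpoint,
    predict_volume,
    run_loocv,
    save_checkpoint,
    train,
    tune_learning_rate,
)
from splenovol.phantom import PhantomSpec, generate_phantom
from splenovol.preprocess import PreprocConfig
from splenovol.volumetry import dice

TINY_CFG = ModelConfig(depth=2, base_channels=4, epochs=4, batch_size=8,
                       learning_rate=3e-3, seed=0)
TINY_PRE = PreprocConfig(crop_size=48)


def _tiny_phantom(seed, semi_axes=(40.0, 32.0, 24.0)):
    spec = PhantomSpec(
        semi_axes=semi_axes,
        deform_amplitude=0.1,
        in_plane_spacing=(3.0, 3.0),
        slice_spacing=3.0,
        grid_shape=(22, 64, 64),
        body_radius=75.0,
        noise_sigma=0.03,
        seed=seed,
    )
    scan, mask, _ = generate_phantom(spec)
    return scan, mask


@pytest.fixture(scope="module")
def tiny_cohort():
    return [(i, *_tiny_phantom(seed=100 + i)) for i in range(4)]


class TestNetworkContracts:
    def test_output_shape_and_probability_range(self, rng):
        net = UNet2D(depth=3, base_channels=4, seed=0)
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (2, 1, 64, 64)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_constant_zero_input_finite(self):
        net = UNet2D(depth=3, base_channels=4, seed=1)
        out = net.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))
        assert np.all(np.isfinite(out))

    def test_parameter_count_increases_with_base_channels(self):
        counts = [
            build_model(ModelConfig(depth=2, base_channels=c)).n_params for c in (2, 4, 8)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_model(ModelConfig(depth=3), input_size=(100, 100))
        net = build_model(ModelConfig(depth=3))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 100, 100), dtype=np.float32))

    def test_resnet_style_encoder_builds_and_runs(self):
        net = build_model(ModelConfig(depth=2, base_channels=4, encoder_name="resnet34-style"))
        p = net.predict_proba(np.zeros((1, 1, 32, 32), dtype=np.float32))
        assert p.shape == (1, 1, 32, 32)

    def test_gradients_match_finite_differences(self, rng):
        net = UNet2D(depth=2, base_channels=2, seed=1)
        x = rng.standard_normal((2, 1, 8, 8)).astype(np.float32)
        y = (rng.random((2, 1, 8, 8)) > 0.7).astype(np.float32)
        loss, dldz = segmentation_loss(net.forward(x), y, "combined")
        net.backward(dldz)
        layers = net._conv_layers()
        for li in (0, len(layers) // 2, len(layers) - 1):
            layer = layers[li]
            idx = tuple(rng.integers(0, s) for s in layer.weight.shape)
            eps, orig = 1e-3, layer.weight[idx]
            layer.weight[idx] = orig + eps
            lp, _ = segmentation_loss(net.forward(x), y, "combined")
            layer.weight[idx] = orig - eps
            lm, _ = segmentation_loss(net.forward(x), y, "combined")
            layer.weight[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = layer.dweight[idx]
            assert analytic == pytest.approx(numeric, rel=0.05, abs=1e-5)


class TestTraining:
    def test_smoke_training_reaches_heldin_dice(self, tiny_cohort):
        x, y = build_training_set(tiny_cohort[:2], TINY_PRE, TINY_CFG)
        model = build_model(TINY_CFG)
        history = train(model, (x, y), TINY_CFG)
        assert len(history) == TINY_CFG.epochs
        assert history[-1]["train_dice"] >= 0.7
        assert history[-1]["loss"] < history[0]["loss"]

    def test_zero_epochs_returns_empty_history(self, tiny_cohort):
        cfg = ModelConfig(depth=2, base_channels=4, epochs=0, learning_rate=1e-3)
        x, y = build_training_set(tiny_cohort[:2], TINY_PRE, cfg)
        model = build_model(cfg)
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        assert train(model, (x, y), cfg) == []
        after = model.state_arrays()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_same_seed_identical_loss_history(self, tiny_cohort):
        cfg = ModelConfig(depth=2, base_channels=4, epochs=2, learning_rate=1e-3, seed=5)
        x, y = build_training_set(tiny_cohort[:2], TINY_PRE, cfg)
        h1 = train(build_model(cfg), (x, y), cfg)
        h2 = train(build_model(cfg), (x, y), cfg)
        assert [h["loss"] for h in h1] == [h["loss"] for h in h2]

    def test_augmented_training_set_triples(self, tiny_cohort):
        x_plain, _ = build_training_set(tiny_cohort[:1], TINY_PRE, TINY_CFG, augment=False)
        x_aug, _ = build_training_set(tiny_cohort[:1], TINY_PRE, TINY_CFG, augment=True)
        assert x_aug.shape[0] == 3 * x_plain.shape[0]


class TestPrediction:
    def test_constant_negative_head_predicts_empty_mask(self, tiny_cohort):
        model = build_model(TINY_CFG)
        model.head.bias[:] = -50.0  # force probabilities ~0 everywhere
        _, scan, _ = tiny_cohort[0]
        mp = predict_volume(model, scan, TINY_PRE, TINY_CFG)
        assert mp.voxels.sum() == 0
        assert mp.shape == scan.shape

    def test_threshold_binarization(self):
        probs = np.array([[0.2, 0.9], [0.9, 0.2]], dtype=np.float32)
        assert np.array_equal((probs >= 0.5).astype(np.uint8), np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            ModelConfig(threshold=0.0)

    def test_trained_model_segments_its_training_phantom(self, tiny_cohort):
        x, y = build_training_set(tiny_cohort[:2], TINY_PRE, TINY_CFG)
        model = build_model(TINY_CFG)
        train(model, (x, y), TINY_CFG)
        sid, scan, gt = tiny_cohort[0]
        mp = predict_volume(model, scan, TINY_PRE, TINY_CFG)
        assert dice(gt, mp) >= 0.8

    def test_checkpoint_round_trip(self, tiny_cohort, tmp_path):
        model = build_model(TINY_CFG)
        save_checkpoint(model, TINY_CFG, tmp_path / "m.ckpt")
        loaded, cfg = load_checkpoint(tmp_path / "m.ckpt")
        assert cfg == TINY_CFG
        x = np.zeros((1, 1, 48, 48), dtype=np.float32)
        assert np.array_equal(model.forward(x), loaded.forward(x))


class TestSplitPlans:
    def test_loocv_partitions_cohort(self):
        plan = SplitPlan.leave_one_out([0, 1, 2, 3])
        assert len(plan.folds) == 4
        for test_ids, train_ids in plan.folds:
            assert len(test_ids) == 1
            assert set(test_ids) | set(train_ids) == {0, 1, 2, 3}
            assert not set(test_ids) & set(train_ids)

    def test_kfold_by_subject_never_by_slice(self):
        plan = SplitPlan.k_fold(list(range(7)), k=3, seed=0)
        seen = [s for test, _ in plan.folds for s in test]
        assert sorted(seen) == list(range(7))

    def test_too_few_subjects_for_kfold(self):
        with pytest.raises(ValueError):
            SplitPlan.k_fold([0, 1], k=5)

    def test_overlapping_fold_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(folds=(((0,), (0, 1)),), scheme="k-fold")


class TestLearningRateTuning:
    def test_single_candidate_returned_unchanged(self, tiny_cohort):
        cfg = ModelConfig(depth=2, base_channels=2, epochs=1, learning_rate=1e-3)
        lr = tune_learning_rate(tiny_cohort, [3e-3], cfg, TINY_PRE, k=2, seed=0)
        assert lr == 3e-3

    def test_divergent_candidate_loses_to_sane_one(self, tiny_cohort):
        cfg = ModelConfig(depth=2, base_channels=4, epochs=2, learning_rate=1e-3)
        lr = tune_learning_rate(tiny_cohort, [3e-3, 1e6], cfg, TINY_PRE, k=2, seed=0)
        assert lr == 3e-3

    def test_fewer_subjects_than_folds_raises(self, tiny_cohort):
        cfg = ModelConfig(depth=2, base_channels=2, epochs=1, learning_rate=1e-3)
        with pytest.raises(ValueError):
            tune_learning_rate(tiny_cohort[:2], [1e-3], cfg, TINY_PRE, k=5)


class TestLeaveOneOut:
    def test_loocv_yields_one_prediction_per_subject(self, tiny_cohort):
        cohort = tiny_cohort[:3]
        preds, plan = run_loocv(cohort, TINY_CFG, TINY_PRE)
        assert [sid for sid, _ in preds] == [sid for sid, _, _ in cohort]
        assert plan.scheme == "leave-one-out"
        for (test_ids, train_ids), (sid, mp) in zip(plan.folds, preds):
            assert test_ids == (sid,)
            assert sid not in train_ids  # no leakage, augmentations included
            assert mp.shape == cohort[0][1].shape

    def test_single_subject_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            run_loocv(tiny_cohort[:1], TINY_CFG, TINY_PRE)
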