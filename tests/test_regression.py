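"""Regression variants: architecture, training, inference and pipeline."""

import numpy as np
import pytest

from gauzeloss import nn, regression as reg, synthetic as syn


def _toy_features(n=12, side=32, n_vector=16, seed=0, patient_ids=None):
    rng = np.random.default_rng(seed)
    return reg.FeatureSet(
        images=rng.uniform(size=(n, side, side, 3)).astype(np.float32),
        csv=rng.uniform(80, 200, n),
        pwcs=rng.uniform(0, 200, (n, n_vector)),
        y=rng.uniform(0.2, 9.5, n),
        gauze_ids=[f"g{i}" for i in range(n)],
        patient_ids=patient_ids or [f"p{i // 3}" for i in range(n)])


class TestBuildModel:
    def test_cs_has_more_parameters_than_base(self):
        base = reg.build_model(reg.RegressionConfig(variant="base", seed=1))
        cs = reg.build_model(reg.RegressionConfig(variant="cs", seed=1))
        pwcs = reg.build_model(reg.RegressionConfig(variant="pwcs", seed=1))
        assert cs.n_params > base.n_params
        assert pwcs.n_params > base.n_params

    def test_forward_on_zero_inputs_is_finite(self):
        model = reg.build_model(reg.RegressionConfig(variant="pwcs",
                                                     input_side=32))
        out = model.forward_raw(np.zeros((2, 32, 32, 3), dtype=np.float32),
                                np.zeros((2, 16), dtype=np.float32))
        assert out.shape == (2,)
        assert np.all(np.isfinite(out))

    def test_seeded_initialization_is_reproducible(self):
        cfg = reg.RegressionConfig(variant="cs", seed=5)
        a = reg.build_model(cfg)
        b = reg.build_model(cfg)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            reg.RegressionConfig(variant="giant")
        with pytest.raises(ValueError):
            reg.RegressionConfig(loss="huber")
        with pytest.raises(ValueError):
            reg.build_model(reg.RegressionConfig(backbone="resnet152"))


class TestLossFidelity:
    @pytest.mark.parametrize("loss", ["mae", "mse"])
    def test_recorded_loss_matches_hand_computation(self, loss):
        rng = np.random.default_rng(0)
        pred = rng.uniform(0, 10, 32)
        target = rng.uniform(0, 10, 32)
        value, _ = nn.regression_loss_grad(pred, target, loss)
        if loss == "mae":
            expected = np.abs(target - pred).mean()
        else:
            expected = ((target - pred) ** 2).mean()
        assert abs(value - expected) < 1e-6

    def test_mae_and_mse_losses_differ_on_same_batch(self):
        data = _toy_features(n=8)
        split = np.arange(8)
        tr, va = data.subset(split[:6]), data.subset(split[6:])
        histories = {}
        for loss in ("mae", "mse"):
            cfg = reg.RegressionConfig(variant="base", input_side=32,
                                       loss=loss, epochs=1, seed=3)
            _, hist = reg.train_regressor(reg.build_model(cfg), tr, va, cfg)
            histories[loss] = hist["train_loss"][0]
        assert histories["mae"] != histories["mse"]


class TestTraining:
    def test_history_deterministic_under_seed(self):
        data = _toy_features(n=10)
        tr, va = data.subset(np.arange(8)), data.subset(np.arange(8, 10))
        cfg = reg.RegressionConfig(variant="cs", input_side=32, epochs=3,
                                   seed=9)
        h1 = reg.train_regressor(reg.build_model(cfg), tr, va, cfg)[1]
        h2 = reg.train_regressor(reg.build_model(cfg), tr, va, cfg)[1]
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_validation_loss_improves_on_real_scenes(self, small_training):
        hist = small_training["history"]
        assert min(hist["val_loss"]) < hist["val_loss"][0]

    def test_missing_variant_features_error_names_gauze(self):
        data = _toy_features(n=6)
        data.csv = None
        cfg = reg.RegressionConfig(variant="cs", input_side=32, epochs=1)
        with pytest.raises(ValueError, match="cs"):
            reg.train_regressor(reg.build_model(cfg),
                                data.subset([0, 1, 2, 3]),
                                data.subset([4, 5]), cfg)

    def test_nan_feature_error_names_gauze(self):
        data = _toy_features(n=6)
        data.csv[2] = np.nan
        cfg = reg.RegressionConfig(variant="cs", input_side=32, epochs=1)
        with pytest.raises(ValueError, match="g2"):
            reg.train_regressor(reg.build_model(cfg),
                                data.subset([0, 1, 2, 3]),
                                data.subset([4, 5]), cfg)

    def test_empty_split_rejected(self):
        data = _toy_features(n=4)
        cfg = reg.RegressionConfig(variant="base", input_side=32, epochs=1)
        with pytest.raises(ValueError):
            reg.train_regressor(reg.build_model(cfg), data.subset([0, 1]),
                                data.subset([]), cfg)


class TestInference:
    def test_predictions_clamped_nonnegative(self):
        model = reg.build_model(reg.RegressionConfig(variant="base",
                                                     input_side=32))
        model.head.b[...] = -50.0  # force a negative raw output
        data = _toy_features(n=4)
        preds = model.predict(data)
        assert np.all(preds >= 0.0)

    def test_inference_is_a_pure_function(self, small_training):
        model, te = small_training["model"], small_training["test"]
        a = model.predict(te)
        b = model.predict(te)
        assert np.array_equal(a, b)

    def test_batch_order_preserved(self, small_training):
        model, te = small_training["model"], small_training["test"]
        perm = np.random.default_rng(0).permutation(len(te))
        direct = model.predict(te)[perm]
        shuffled = model.predict(te.subset(perm))
        assert np.allclose(direct, shuffled, atol=1e-5)

    def test_predictions_correlate_with_truth(self, small_training):
        model, te = small_training["model"], small_training["test"]
        preds = model.predict(te)
        r = np.corrcoef(preds, te.y)[0, 1]
        assert r > 0.5

    def test_predict_ebl_carries_ids(self, small_training):
        model, te = small_training["model"], small_training["test"]
        out = reg.predict_ebl(model, te)
        assert [p.gauze_id for p in out] == te.gauze_ids
        assert all(p.predicted_ebl_g >= 0 for p in out)

    def test_save_load_roundtrip(self, small_training, tmp_path):
        model, te = small_training["model"], small_training["test"]
        path = str(tmp_path / "model")
        model.save(path)
        model2 = reg.EBLRegressor.load(path)
        assert np.allclose(model.predict(te), model2.predict(te))


class TestMaskedInput:
    def test_output_shape_and_range(self, scene):
        out = reg.prepare_masked_input(scene.frame, scene.gauze_mask, 48)
        assert out.shape == (48, 48, 3)
        assert out.dtype == np.float32
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_empty_mask_rejected(self, scene):
        with pytest.raises(ValueError, match="no gauze"):
            reg.prepare_masked_input(scene.frame,
                                     np.zeros_like(scene.gauze_mask), 48)


class TestPipeline:
    def test_one_entry_per_frame_with_explicit_skips(self, trained_detector,
                                                     small_training):
        clf, model = trained_detector[0], small_training["model"]
        scenes = [syn.generate_scene(p) for p in
                  syn.sample_scene_params(3, seed=42)]
        frames = [s.frame for s in scenes] + \
            [syn.background_frame(256, 256, "tissue", seed=1)]
        results = reg.run_pipeline(frames, clf, model)
        assert len(results) == len(frames)
        assert not any(r.skipped for r in results[:3])
        assert results[3].skipped and "no gauze" in results[3].reason

    def test_pipeline_matches_manual_stage_composition(self, trained_detector,
                                                       small_training):
        clf, model = trained_detector[0], small_training["model"]
        scenes = [syn.generate_scene(p) for p in
                  syn.sample_scene_params(3, seed=43)]
        pipe = reg.PipelineConfig()
        results = reg.run_pipeline([s.frame for s in scenes], clf, model,
                                   pipe)
        for sc, r in zip(scenes, results):
            feats = reg.scene_features(sc.frame, clf, pipe)
            data = reg.FeatureSet(images=feats["image"][None],
                                  csv=np.array([feats["csv"]]),
                                  pwcs=feats["pwcs"][None],
                                  y=np.array([np.nan]), gauze_ids=["x"],
                                  patient_ids=[""])
            manual = float(model.predict(data)[0])
            assert r.predicted_ebl_g == pytest.approx(manual, abs=1e-9)
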