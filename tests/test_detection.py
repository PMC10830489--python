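"""Tiling, tile classification, mask assembly, patches and metrics."""

import numpy as np
import pytest

from gauzeloss import detection as det, synthetic as syn


def _tc_from_gauze_prob(prob_grid):
    """Build a TileClassification whose gauze probability is prob_grid."""
    g = np.asarray(prob_grid, dtype=float)
    probs = np.zeros(g.shape + (4,))
    probs[..., 0] = 1 - g
    probs[..., 3] = g
    return det.TileClassification(grid_rows=g.shape[0], grid_cols=g.shape[1],
                                  probs=probs, hard_label=probs.argmax(-1))


class TestTiling:
    def test_grid_counts(self):
        frame = np.zeros((256, 256, 3), dtype=np.uint8)
        assert len(det.tile_frame(frame, det.TileSpec(64, 64))) == 16
        assert len(det.tile_frame(frame, det.TileSpec(64, 32))) == 49

    def test_tiles_are_exact_crops(self):
        frame = np.arange(256 * 256 * 3, dtype=np.int64).reshape(256, 256, 3)
        for t in det.tile_frame(frame, det.TileSpec(64, 64)):
            assert np.array_equal(t.image, frame[t.r0:t.r0 + 64,
                                                 t.c0:t.c0 + 64])

    def test_remainder_tiles_dropped(self):
        frame = np.zeros((100, 130, 3), dtype=np.uint8)
        tiles = det.tile_frame(frame, det.TileSpec(64, 64))
        assert len(tiles) == 2  # 1 row x 2 cols

    def test_frame_smaller_than_tile_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            det.tile_frame(np.zeros((32, 32, 3)), det.TileSpec(64, 64))

    def test_tile_spec_validation(self):
        with pytest.raises(ValueError):
            det.TileSpec(tile_size=8)
        with pytest.raises(ValueError):
            det.TileSpec(tile_size=64, stride=65)
        with pytest.raises(ValueError):
            det.TileSpec(tile_size=64, stride=0)


class TestClassifyTiles:
    def test_hard_label_argmax_and_tie_rule(self):
        assert det.hard_labels(np.array([0.1, 0.2, 0.3, 0.4])) == 3  # soaked
        assert det.hard_labels(np.array([0.25, 0.25, 0.25, 0.25])) == 0
        assert det.hard_labels(np.array([0.1, 0.4, 0.4, 0.1])) == 1

    def test_probability_rows_on_simplex(self, trained_detector):
        clf = trained_detector[0]
        frame = syn.generate_scene(syn.SceneParams(seed=1)).frame
        tc = det.classify_tiles(clf, det.tile_frame(frame, det.TileSpec()))
        sums = tc.probs.reshape(-1, 4).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert tc.probs.min() >= 0

    def test_empty_tile_list_rejected(self, trained_detector):
        with pytest.raises(ValueError, match="empty"):
            det.classify_tiles(trained_detector[0], [])


class TestAssembleMask:
    def test_all_background_gives_empty_mask(self):
        tc = _tc_from_gauze_prob(np.zeros((4, 4)))
        mask = det.assemble_mask(tc, (256, 256), det.TileSpec())
        assert not mask.any()

    def test_all_soaked_fills_covered_area(self):
        tc = _tc_from_gauze_prob(np.ones((4, 4)))
        mask = det.assemble_mask(tc, (300, 300), det.TileSpec(),
                                 closing=False)
        assert mask[:256, :256].all()
        assert not mask[256:, :].any() and not mask[:, 256:].any()

    def test_checkerboard_labels_give_checkerboard_mask(self):
        grid = np.indices((4, 4)).sum(axis=0) % 2
        tc = _tc_from_gauze_prob(grid.astype(float))
        mask = det.assemble_mask(tc, (256, 256), det.TileSpec(),
                                 closing=False)
        expected = np.kron(grid, np.ones((64, 64))).astype(bool)
        assert np.array_equal(mask, expected)

    def test_assembly_idempotent_on_tile_aligned_mask(self):
        rng = np.random.default_rng(0)
        grid = rng.uniform(size=(4, 4)) > 0.5
        tc = _tc_from_gauze_prob(grid.astype(float))
        spec = det.TileSpec()
        mask = det.assemble_mask(tc, (256, 256), spec, closing=False)
        tc2 = _tc_from_gauze_prob(np.array(
            [[mask[i * 64:(i + 1) * 64, j * 64:(j + 1) * 64].mean()
              for j in range(4)] for i in range(4)]))
        mask2 = det.assemble_mask(tc2, (256, 256), spec, closing=False)
        assert np.array_equal(mask, mask2)


class TestMaskedImageAndPatches:
    def test_full_mask_is_identity(self):
        frame = np.random.default_rng(0).integers(
            0, 256, (64, 64, 3)).astype(np.uint8)
        mask = np.ones((64, 64), dtype=bool)
        masked, bbox = det.extract_masked_image(frame, mask)
        assert np.array_equal(masked, frame)
        assert bbox == (0, 64, 0, 64)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no gauze"):
            det.extract_masked_image(np.zeros((32, 32, 3), dtype=np.uint8),
                                     np.zeros((32, 32), dtype=bool))

    def test_nonzero_pixels_equal_mask_count(self):
        frame = np.full((64, 64, 3), 200, dtype=np.uint8)
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:30, 20:50] = True
        masked, bbox = det.extract_masked_image(frame, mask)
        assert (masked.sum(axis=-1) > 0).sum() == mask.sum()
        assert bbox == (10, 30, 20, 50)

    def test_full_mask_yields_all_tiles_as_patches(self):
        frame = np.zeros((256, 256, 3), dtype=np.uint8)
        mask = np.ones((256, 256), dtype=bool)
        tc = _tc_from_gauze_prob(np.ones((4, 4)))
        patches = det.extract_patches(frame, mask, tc, det.TileSpec())
        assert len(patches) == 16

    def test_empty_mask_yields_no_patches(self):
        frame = np.zeros((256, 256, 3), dtype=np.uint8)
        tc = _tc_from_gauze_prob(np.zeros((4, 4)))
        patches = det.extract_patches(frame, np.zeros((256, 256), bool), tc,
                                      det.TileSpec())
        assert patches == []

    def test_strict_fraction_keeps_only_fully_covered_tiles(self):
        frame = np.zeros((256, 256, 3), dtype=np.uint8)
        mask = np.zeros((256, 256), dtype=bool)
        mask[0:64, 0:64] = True         # tile (0,0) fully covered
        mask[64:128, 0:32] = True       # tile (1,0) half covered
        tc = _tc_from_gauze_prob(np.ones((4, 4)))
        patches = det.extract_patches(frame, mask, tc, det.TileSpec(),
                                      min_gauze_fraction=1.0)
        assert [(p.row, p.col) for p in patches] == [(0, 0)]
        # coverage oracle: count tiles whose mask crop is fully true
        full = sum(mask[i * 64:(i + 1) * 64, j * 64:(j + 1) * 64].all()
                   for i in range(4) for j in range(4))
        assert len(patches) == full

    def test_patch_blood_evidence_from_probs(self):
        frame = np.zeros((256, 256, 3), dtype=np.uint8)
        mask = np.ones((256, 256), dtype=bool)
        probs = np.zeros((4, 4, 4))
        probs[..., 1] = 0.2
        probs[..., 2] = 0.3
        probs[..., 3] = 0.5
        tc = det.TileClassification(4, 4, probs, probs.argmax(-1))
        patches = det.extract_patches(frame, mask, tc, det.TileSpec())
        assert all(abs(p.blood_evidence - 0.8) < 1e-12 for p in patches)


class TestDetectionMetrics:
    def test_reference_confusion_reproduces_reported_rates(self):
        truth = np.array([True] * 200 + [False] * 200)
        pred = truth.copy()
        pred[:7] = False     # 193 of 200 gauze correct
        pred[200:204] = True  # 196 of 200 background correct
        m = det.detection_metrics(pred, truth)
        assert m.sensitivity == pytest.approx(96.5)
        assert m.specificity == pytest.approx(98.0)

    def test_perfect_prediction(self):
        truth = np.array(["background", "clean", "soaked", "stained"])
        m = det.detection_metrics(truth, truth)
        assert (m.sensitivity, m.specificity, m.precision) == (100, 100, 100)

    def test_degenerate_all_background(self):
        truth = np.array([True, True, False])
        pred = np.array([False, False, False])
        m = det.detection_metrics(pred, truth)
        assert m.sensitivity == 0.0
        assert m.precision is None

    def test_no_positives_sensitivity_missing(self):
        truth = np.array([False, False])
        m = det.detection_metrics(np.array([False, True]), truth)
        assert m.sensitivity is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            det.detection_metrics([True], [True, False])


class TestClassifierTraining:
    def test_single_class_rejected(self):
        imgs = [np.zeros((24, 24, 3), dtype=np.uint8)] * 8
        with pytest.raises(ValueError, match="single class"):
            det.train_tile_classifier(imgs, ["clean"] * 8, epochs=1)

    def test_separable_tiles_reach_perfect_validation(self):
        rng = np.random.default_rng(0)
        imgs, labels = [], []
        for _ in range(40):
            red = np.zeros((24, 24, 3), dtype=np.uint8)
            red[..., 0] = rng.integers(200, 255)
            imgs.append(red)
            labels.append("soaked")
            gray = np.full((24, 24, 3), rng.integers(90, 130),
                           dtype=np.uint8)
            imgs.append(gray)
            labels.append("background")
        clf, hist = det.train_tile_classifier(imgs, labels, epochs=5, seed=0)
        assert hist["val_acc"][-1] == 1.0
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        imgs = [rng.integers(0, 256, (24, 24, 3)).astype(np.uint8)
                for _ in range(24)]
        labels = (["background", "clean", "stained"] * 8)
        h1 = det.train_tile_classifier(imgs, labels, epochs=3, seed=7)[1]
        h2 = det.train_tile_classifier(imgs, labels, epochs=3, seed=7)[1]
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_learning_reduces_loss(self, trained_detector):
        hist = trained_detector[1]
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_save_load_roundtrip(self, trained_detector, tmp_path):
        clf = trained_detector[0]
        path = str(tmp_path / "det")
        clf.save(path)
        clf2 = det.TileClassifier.load(path)
        img = [np.zeros((32, 32, 3), dtype=np.uint8)]
        assert np.allclose(clf.predict_proba(img), clf2.predict_proba(img))


class TestMaskQuality:
    def test_assembled_masks_recover_ground_truth(self, trained_detector):
        """Pixel-level sensitivity/specificity vs the true mask >= 90%."""
        clf = trained_detector[0]
        spec = det.TileSpec(tile_size=32, stride=16)
        sens, specs = [], []
        for p in syn.sample_scene_params(8, seed=77):
            sc = syn.generate_scene(p)
            tc = det.classify_tiles(clf, det.tile_frame(sc.frame, spec))
            mask = det.assemble_mask(tc, sc.frame.shape[:2], spec)
            tp = (mask & sc.gauze_mask).sum()
            fn = (~mask & sc.gauze_mask).sum()
            tn = (~mask & ~sc.gauze_mask).sum()
            fp = (mask & ~sc.gauze_mask).sum()
            sens.append(100 * tp / (tp + fn))
            specs.append(100 * tn / (tn + fp))
        assert np.mean(sens) >= 90.0
        assert np.mean(specs) >= 90.0
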