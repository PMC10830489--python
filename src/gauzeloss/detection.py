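"""Tile-based gauze detection: tiling, classification, masking, patches.

Frames are tiled on a regular grid, each tile classified into one of four
states — background tissue, clean gauze, stained gauze, soaked gauze — by a
small CNN.  Tile probabilities are fused into a binary gauze mask (mean gauze
probability >= 0.5 per pixel, optional morphological closing), from which the
masked gauze image and the gauze patches for texture analysis are produced.
The stained+soaked probability of a patch is reused downstream as its
blood-evidence weight.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize

from . import nn
from .synthetic import SceneSample, derive_seed

CLASSES = ("background", "clean", "stained", "soaked")


@dataclass(frozen=True)
class TileSpec:
    tile_size: int = 64
    stride: int = 64
    input_resize: int = 24

    def __post_init__(self) -> None:
        if self.tile_size < 16:
            raise ValueError("tile_size must be >= 16")
        if not 1 <= self.stride <= self.tile_size:
            raise ValueError("stride must satisfy 1 <= stride <= tile_size")

    def grid_shape(self, frame_h: int, frame_w: int) -> tuple[int, int]:
        if frame_h < self.tile_size or frame_w < self.tile_size:
            raise ValueError("frame smaller than one tile")
        return ((frame_h - self.tile_size) // self.stride + 1,
                (frame_w - self.tile_size) // self.stride + 1)


@dataclass
class Tile:
    row: int
    col: int
    r0: int
    c0: int
    image: np.ndarray  # (tile_size, tile_size[, 3]) crop


@dataclass
class GauzePatch:
    row: int
    col: int
    r0: int
    c0: int
    image: np.ndarray
    mask: np.ndarray
    blood_evidence: float      # stained + soaked probability, in [0, 1]
    mass_g: float | None = None  # ground truth, synthetic scenes only


@dataclass
class TileClassification:
    grid_rows: int
    grid_cols: int
    probs: np.ndarray       # (rows, cols, 4) rows on the simplex
    hard_label: np.ndarray  # (rows, cols) argmax index, ties -> lower index


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    precision: float | None


def tile_frame(frame: np.ndarray, spec: TileSpec) -> list[Tile]:
    """Enumerate tiles row-major over half-open ranges [r0, r0+size).

    Right/bottom remainder strips not covered by a full tile are dropped.
    """
    rows, cols = spec.grid_shape(frame.shape[0], frame.shape[1])
    tiles = []
    for i in range(rows):
        for j in range(cols):
            r0, c0 = i * spec.stride, j * spec.stride
            tiles.append(Tile(row=i, col=j, r0=r0, c0=c0,
                              image=frame[r0:r0 + spec.tile_size,
                                          c0:c0 + spec.tile_size]))
    return tiles


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

class TileClassifier:
    """Small CNN over resized tiles with a 4-way softmax head."""

    def __init__(self, backbone: str = "small_cnn", input_resize: int = 24,
                 seed: int = 0, dtype=nn.DEFAULT_DTYPE) -> None:
        rng = np.random.default_rng(derive_seed(seed, "detector-init"))
        bb, feat = nn.make_backbone(backbone, 3, rng, dtype=dtype)
        self.net = nn.Sequential([bb, nn.Dense(feat, len(CLASSES), rng,
                                               dtype=dtype)])
        self.backbone = backbone
        self.input_resize = input_resize
        self.norm_mean = np.zeros(3, dtype=np.float64)
        self.norm_std = np.ones(3, dtype=np.float64)
        self.dtype = dtype

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        s = self.input_resize
        x = np.empty((len(images), s, s, 3), dtype=np.float64)
        for i, im in enumerate(images):
            im = np.asarray(im)
            if im.ndim == 2:
                im = np.stack([im] * 3, axis=-1)
            if im.shape[0] != s or im.shape[1] != s:
                im = resize(im.astype(np.float64), (s, s),
                            preserve_range=True, anti_aliasing=True)
            x[i] = im
        x = (x / 255.0 - self.norm_mean) / self.norm_std
        return x.astype(self.dtype)

    def predict_proba(self, images) -> np.ndarray:
        logits = self.net.forward(self._prepare(images), train=False)
        return nn.softmax(logits.astype(np.float64))

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.net.parameters())}
        np.savez(path + ".npz", **arrays)
        meta = {"backbone": self.backbone, "input_resize": self.input_resize,
                "classes": list(CLASSES),
                "norm_mean": self.norm_mean.tolist(),
                "norm_std": self.norm_std.tolist()}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "TileClassifier":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        obj = cls(backbone=meta["backbone"],
                  input_resize=meta["input_resize"])
        data = np.load(path + ".npz")
        for i, (p, _) in enumerate(obj.net.parameters()):
            p[...] = data[f"p{i}"]
        obj.norm_mean = np.array(meta["norm_mean"])
        obj.norm_std = np.array(meta["norm_std"])
        return obj


def _per_class_split(labels: np.ndarray, ratio: tuple[int, int, int],
                     rng: np.random.Generator) -> np.ndarray:
    """3:1:1-style split applied independently within every class."""
    total = sum(ratio)
    out = np.empty(len(labels), dtype=object)
    names = np.array(["train", "val", "test"])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        exact = np.array([n * r / total for r in ratio])
        counts = np.floor(exact).astype(int)
        order = np.argsort(-(exact - counts), kind="stable")
        for i in order[: n - counts.sum()]:
            counts[i] += 1
        out[idx] = np.repeat(names, counts)
    return out.astype(str)


def train_tile_classifier(images, labels, backbone: str = "small_cnn",
                          input_resize: int = 24, epochs: int = 8,
                          batch_size: int = 32, learning_rate: float = 2e-3,
                          seed: int = 0,
                          ) -> tuple[TileClassifier, dict]:
    """Train the tile classifier; returns (classifier, history).

    ``labels`` are class names from ``CLASSES`` or integer indices.  Tiles
    are split 3:1:1 (train/val/test) within each class; the weights with the
    best validation loss are retained.  History holds per-epoch train/val
    loss and validation accuracy, plus the test-split indices for later
    evaluation.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        y = np.array([CLASSES.index(l) for l in labels])
    else:
        y = labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(derive_seed(seed, "detector-train"))
    split = _per_class_split(y, (3, 1, 1), rng)
    clf = TileClassifier(backbone=backbone, input_resize=input_resize,
                         seed=seed)

    # normalization constants from the training split
    raw = clf._prepare(np.asarray(images, dtype=object)
                       if isinstance(images, list) else images)
    tr_idx = np.flatnonzero(split == "train")
    va_idx = np.flatnonzero(split == "val")
    clf.norm_mean = np.asarray(
        [float(raw[tr_idx, :, :, c].mean()) for c in range(3)])
    clf.norm_std = np.asarray(
        [max(float(raw[tr_idx, :, :, c].std()), 1e-6) for c in range(3)])
    x = ((raw.astype(np.float64) - clf.norm_mean)
         / clf.norm_std).astype(clf.dtype)

    opt = nn.Adam(clf.net.parameters(), lr=learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_acc": [],
               "split": split}
    best_loss, best_state = np.inf, nn.get_state(clf.net)
    for _ in range(epochs):
        perm = rng.permutation(tr_idx)
        losses = []
        for b0 in range(0, len(perm), batch_size):
            bidx = perm[b0:b0 + batch_size]
            logits = clf.net.forward(x[bidx], train=True)
            loss, g = nn.cross_entropy_grad(logits, y[bidx])
            if not np.isfinite(loss):
                raise RuntimeError("non-finite training loss; aborting "
                                   f"(lr={learning_rate}, batch at {b0})")
            clf.net.backward(g)
            opt.step()
            losses.append(loss)
        vl_logits = clf.net.forward(x[va_idx], train=False)
        val_loss, _ = nn.cross_entropy_grad(vl_logits, y[va_idx])
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(
            float((vl_logits.argmax(axis=1) == y[va_idx]).mean()))
        if val_loss < best_loss:
            best_loss, best_state = val_loss, nn.get_state(clf.net)
    nn.set_state(clf.net, best_state)
    return clf, history


def hard_labels(probs: np.ndarray) -> np.ndarray:
    """Argmax class per probability row; ties break toward the lower index
    in the fixed order (background, clean, stained, soaked)."""
    return np.asarray(probs).argmax(axis=-1)


def classify_tiles(classifier: TileClassifier,
                   tiles: list[Tile]) -> TileClassification:
    """Classify a frame's tiles; rows of ``probs`` lie on the 4-simplex."""
    if not tiles:
        raise ValueError("empty tile list")
    rows = max(t.row for t in tiles) + 1
    cols = max(t.col for t in tiles) + 1
    probs_flat = classifier.predict_proba([t.image for t in tiles])
    probs = np.zeros((rows, cols, len(CLASSES)))
    for t, p in zip(tiles, probs_flat):
        probs[t.row, t.col] = p
    hard = hard_labels(probs)
    return TileClassification(grid_rows=rows, grid_cols=cols, probs=probs,
                              hard_label=hard)


def assemble_mask(tc: TileClassification, frame_dims: tuple[int, int],
                  spec: TileSpec, closing: bool = True,
                  closing_radius: int = 5) -> np.ndarray:
    """Fuse tile probabilities into a binary gauze mask.

    A pixel is gauze iff the mean gauze probability (clean+stained+soaked)
    over all tiles covering it is >= 0.5.  Pixels covered by no tile
    (remainder strips) are background.  Optional binary closing (default on,
    5 px disk) removes tile-grid artifacts.
    """
    h, w = frame_dims
    gauze_prob = tc.probs[:, :, 1:].sum(axis=-1)
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for i in range(tc.grid_rows):
        for j in range(tc.grid_cols):
            r0, c0 = i * spec.stride, j * spec.stride
            acc[r0:r0 + spec.tile_size, c0:c0 + spec.tile_size] += \
                gauze_prob[i, j]
            cnt[r0:r0 + spec.tile_size, c0:c0 + spec.tile_size] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mask = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0) >= 0.5
    if closing and mask.any():
        mask = ndimage.binary_closing(mask, structure=disk(closing_radius))
    return mask


def extract_masked_image(frame: np.ndarray, gauze_mask: np.ndarray,
                         ) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Frame with non-gauze pixels zeroed, plus the mask's tight bbox.

    The bbox is (r0, r1, c0, c1) with half-open ranges.
    """
    if frame.shape[:2] != gauze_mask.shape:
        raise ValueError("frame and mask shapes differ")
    if not gauze_mask.any():
        raise ValueError("no gauze detected")
    masked = np.zeros_like(frame)
    masked[gauze_mask] = frame[gauze_mask]
    rows = np.flatnonzero(gauze_mask.any(axis=1))
    cols = np.flatnonzero(gauze_mask.any(axis=0))
    bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    return masked, bbox


def extract_patches(frame: np.ndarray, gauze_mask: np.ndarray,
                    tc: TileClassification, spec: TileSpec,
                    min_gauze_fraction: float = 0.5,
                    mass_map: np.ndarray | None = None) -> list[GauzePatch]:
    """Detection tiles with mask coverage >= min_gauze_fraction, as patches.

    Each patch carries its image and mask crops and a blood-evidence score
    (stained + soaked probability of its tile).  If a ground-truth mass map
    is supplied (synthetic scenes), the per-patch mass is recorded too.
    """
    if not 0.0 < min_gauze_fraction <= 1.0:
        raise ValueError("min_gauze_fraction must lie in (0, 1]")
    patches = []
    for i in range(tc.grid_rows):
        for j in range(tc.grid_cols):
            r0, c0 = i * spec.stride, j * spec.stride
            sl = np.s_[r0:r0 + spec.tile_size, c0:c0 + spec.tile_size]
            cover = float(gauze_mask[sl].mean())
            if cover < min_gauze_fraction:
                continue
            evidence = float(tc.probs[i, j, 2] + tc.probs[i, j, 3])
            mass = float(mass_map[sl].sum()) if mass_map is not None else None
            patches.append(GauzePatch(row=i, col=j, r0=r0, c0=c0,
                                      image=frame[sl], mask=gauze_mask[sl],
                                      blood_evidence=evidence, mass_g=mass))
    return patches


def detection_metrics(predicted, truth) -> DetectionMetrics:
    """Binary gauze-vs-background metrics in percent.

    Inputs are per-tile labels: booleans (True = gauze) or 4-class names /
    indices, binarized as gauze = anything but background.  Undefined ratios
    (empty denominator) are reported as None, never as 0.
    """
    def binarize(a):
        a = np.asarray(a)
        if a.dtype == bool:
            return a
        if a.dtype.kind in "US":
            return a != "background"
        return a.astype(int) != 0

    p, t = binarize(predicted), binarize(truth)
    if p.shape != t.shape:
        raise ValueError("label lists differ in length")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    return DetectionMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                            sensitivity=ratio(tp, tp + fn),
                            specificity=ratio(tn, tn + fp),
                            precision=ratio(tp, tp + fp))


# ---------------------------------------------------------------------------
# synthetic-scene tile harvesting (training data for the classifier)
# ---------------------------------------------------------------------------

def tiles_from_scene(scene: SceneSample, spec: TileSpec,
                     clean_below: float = 0.05, soaked_above: float = 0.5,
                     ) -> tuple[list[np.ndarray], list[str]]:
    """Harvest labeled tiles from a synthetic scene using its ground truth.

    Tiles with < 10% gauze coverage are background; tiles with >= 50%
    coverage are labeled by the stained fraction of their gauze pixels
    (clean / stained / soaked); ambiguous edge tiles are skipped.
    """
    images, labels = [], []
    for t in tile_frame(scene.frame, spec):
        sl = np.s_[t.r0:t.r0 + spec.tile_size, t.c0:t.c0 + spec.tile_size]
        cover = float(scene.gauze_mask[sl].mean())
        if cover <= 0.10:
            images.append(t.image)
            labels.append("background")
        elif cover >= 0.5:
            gm = scene.gauze_mask[sl]
            stained = float((scene.blood_mass_map[sl][gm] > 0).mean())
            if stained < clean_below:
                labels.append("clean")
            elif stained < soaked_above:
                labels.append("stained")
            else:
                labels.append("soaked")
            images.append(t.image)
    return images, labels
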