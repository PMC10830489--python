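"""Blood-mass regression from masked gauze images and crumple features.

Three fusion variants share one contract:

* ``base``  — image backbone on the masked gauze image, global average
  pooling, fully connected head with a linear (default) or ReLU output
  activation;
* ``cs``    — the scalar crumpled-state value (CSV) of the whole gauze
  region is passed through an MLP and concatenated with the image feature
  before the head;
* ``pwcs``  — the MLP instead consumes the fixed-length vector of per-patch
  CSVs weighted by blood evidence (patch-wise crumpled state).

Training minimizes MAE (default) or MSE with Adam at the stated setup
(batch size 32, learning rate 5e-3), retains the best-validation-loss
weights, and is deterministic under a fixed seed.  Predictions are clamped
to >= 0 grams at output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import nn
from . import detection as det
from . import texture as tx
from .synthetic import SceneSample, derive_seed

VARIANTS = ("base", "cs", "pwcs")


@dataclass(frozen=True)
class RegressionConfig:
    variant: str = "base"
    backbone: str = "small_cnn"
    head_activation: str = "linear"   # or "relu"
    loss: str = "mae"                 # or "mse"
    mlp_hidden: tuple[int, ...] = (32, 16)
    n_vector: int = 16                # length of the patch-wise CSV vector
    input_side: int = 64
    batch_size: int = 32
    learning_rate: float = 5e-3
    epochs: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.head_activation not in ("linear", "relu"):
            raise ValueError("head_activation must be 'linear' or 'relu'")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")


@dataclass
class EBLPrediction:
    gauze_id: str
    predicted_ebl_g: float
    true_ebl_g: float | None = None
    patient_id: str = ""


@dataclass
class FeatureSet:
    """Per-gauze inputs for the regressors (one row per gauze)."""

    images: np.ndarray                  # (N, S, S, 3) float32 in [0, 1]
    csv: np.ndarray | None              # (N,) global CSV, for variant "cs"
    pwcs: np.ndarray | None             # (N, n_vector), for variant "pwcs"
    y: np.ndarray                       # (N,) true grams
    gauze_ids: list[str]
    patient_ids: list[str]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        idx = (np.flatnonzero(idx) if idx.dtype == bool
               else idx.astype(np.int64))
        return FeatureSet(
            images=self.images[idx],
            csv=None if self.csv is None else self.csv[idx],
            pwcs=None if self.pwcs is None else self.pwcs[idx],
            y=self.y[idx],
            gauze_ids=[self.gauze_ids[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx])


def prepare_masked_input(frame: np.ndarray, gauze_mask: np.ndarray,
                         input_side: int) -> np.ndarray:
    """Masked gauze image -> bbox crop -> centered square pad -> resize.

    Returns a float32 (S, S, 3) array in [0, 1].
    """
    masked, (r0, r1, c0, c1) = det.extract_masked_image(frame, gauze_mask)
    crop = masked[r0:r1, c0:c1].astype(np.float64)
    h, w = crop.shape[:2]
    side = max(h, w)
    sq = np.zeros((side, side, 3))
    oy, ox = (side - h) // 2, (side - w) // 2
    sq[oy:oy + h, ox:ox + w] = crop
    out = resize(sq, (input_side, input_side), preserve_range=True,
                 anti_aliasing=True)
    return (out / 255.0).astype(np.float32)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class EBLRegressor:
    """Image backbone (+ optional feature MLP) fused into a scalar head."""

    def __init__(self, config: RegressionConfig,
                 dtype=nn.DEFAULT_DTYPE) -> None:
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(derive_seed(config.seed, "regressor"))
        self.backbone, feat_dim = nn.make_backbone(config.backbone, 3, rng,
                                                   dtype=dtype)
        self.feat_in = {"base": 0, "cs": 1, "pwcs": config.n_vector}[
            config.variant]
        if self.feat_in:
            self.feat_mlp, mlp_out = nn.make_mlp(self.feat_in,
                                                 config.mlp_hidden, rng,
                                                 dtype=dtype)
        else:
            self.feat_mlp, mlp_out = None, 0
        self.head = nn.Dense(feat_dim + mlp_out, 1, rng, dtype=dtype)
        self._feat_dim = feat_dim
        # normalization constants, filled from the training split
        self.img_mean = np.zeros(3)
        self.img_std = np.ones(3)
        self.feat_mean = np.zeros(max(self.feat_in, 1))
        self.feat_std = np.ones(max(self.feat_in, 1))

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        params = self.backbone.parameters()
        if self.feat_mlp is not None:
            params = params + self.feat_mlp.parameters()
        return params + self.head.parameters()

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def _prep_images(self, images: np.ndarray) -> np.ndarray:
        x = (images.astype(np.float64) - self.img_mean) / self.img_std
        return x.astype(self.dtype)

    def _prep_feats(self, feats: np.ndarray | None) -> np.ndarray | None:
        if self.feat_in == 0:
            return None
        if feats is None:
            raise ValueError(
                f"variant {self.config.variant!r} requires CSV features")
        f = np.asarray(feats, dtype=np.float64).reshape(len(feats),
                                                        self.feat_in)
        return ((f - self.feat_mean) / self.feat_std).astype(self.dtype)

    def fit_normalization(self, train: FeatureSet) -> None:
        imgs = train.images.astype(np.float64)
        self.img_mean = imgs.mean(axis=(0, 1, 2))
        self.img_std = np.maximum(imgs.std(axis=(0, 1, 2)), 1e-6)
        if self.feat_in:
            f = self._variant_feats(train)
            f = np.asarray(f, dtype=np.float64).reshape(len(f), self.feat_in)
            if self.feat_in == 1:
                self.feat_mean = f.mean(axis=0)
                self.feat_std = np.maximum(f.std(axis=0), 1e-6)
            else:
                # shared scalar statistics: per-dimension scaling would blow
                # up the rarely-occupied tail of the zero-padded sorted
                # patch vector (tiny variance -> huge z-scores)
                self.feat_mean = np.full(self.feat_in, f.mean())
                self.feat_std = np.full(self.feat_in,
                                        max(float(f.std()), 1e-6))

    def _variant_feats(self, data: FeatureSet) -> np.ndarray | None:
        if self.config.variant == "base":
            return None
        feats = data.csv if self.config.variant == "cs" else data.pwcs
        if feats is None:
            raise ValueError(f"feature set lacks {self.config.variant!r} "
                             "features")
        bad = np.flatnonzero(~np.isfinite(
            np.asarray(feats, dtype=np.float64).reshape(len(feats), -1)
        ).all(axis=1))
        if bad.size:
            names = [data.gauze_ids[i] for i in bad[:5]]
            raise ValueError(f"missing CSV features for gauzes {names}")
        return np.asarray(feats)

    # -- forward / backward ------------------------------------------------
    def forward_raw(self, x_img: np.ndarray, x_feat: np.ndarray | None,
                    train: bool = False) -> np.ndarray:
        f = self.backbone.forward(x_img, train=train)
        if self.feat_mlp is not None:
            g = self.feat_mlp.forward(x_feat, train=train)
            f = np.concatenate([f, g], axis=1)
        raw = self.head.forward(f, train=train)[:, 0]
        if self.config.head_activation == "relu":
            if train:
                self._relu_mask = raw > 0
            raw = np.maximum(raw, 0)
        return raw

    def backward(self, grad_out: np.ndarray) -> None:
        if self.config.head_activation == "relu":
            grad_out = grad_out * self._relu_mask
        g = self.head.backward(grad_out[:, None].astype(self.dtype))
        g_img = np.ascontiguousarray(g[:, :self._feat_dim])
        self.backbone.backward(g_img)
        if self.feat_mlp is not None:
            self.feat_mlp.backward(
                np.ascontiguousarray(g[:, self._feat_dim:]))

    def predict(self, data: FeatureSet) -> np.ndarray:
        """Nonnegative gram predictions, input order preserved."""
        x = self._prep_images(data.images)
        z = self._prep_feats(self._variant_feats(data))
        raw = self.forward_raw(x, z, train=False)
        return np.maximum(raw.astype(np.float64), 0.0)

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        np.savez(path + ".npz",
                 **{f"p{i}": p for i, (p, _) in enumerate(self.parameters())})
        cfg = self.config
        meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in cfg.__dict__.items()},
                "img_mean": self.img_mean.tolist(),
                "img_std": self.img_std.tolist(),
                "feat_mean": np.asarray(self.feat_mean).tolist(),
                "feat_std": np.asarray(self.feat_std).tolist()}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "EBLRegressor":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        cfgd = dict(meta["config"])
        cfgd["mlp_hidden"] = tuple(cfgd["mlp_hidden"])
        obj = cls(RegressionConfig(**cfgd))
        data = np.load(path + ".npz")
        for i, (p, _) in enumerate(obj.parameters()):
            p[...] = data[f"p{i}"]
        obj.img_mean = np.array(meta["img_mean"])
        obj.img_std = np.array(meta["img_std"])
        obj.feat_mean = np.array(meta["feat_mean"])
        obj.feat_std = np.array(meta["feat_std"])
        return obj


def build_model(config: RegressionConfig) -> EBLRegressor:
    """Construct the regressor for the configured variant and backbone."""
    return EBLRegressor(config)


def train_regressor(model: EBLRegressor, train: FeatureSet, val: FeatureSet,
                    config: RegressionConfig | None = None,
                    ) -> tuple[EBLRegressor, dict]:
    """Minimize the configured loss on the train split; keep best-val weights.

    History records the per-epoch mean train loss and validation loss (both
    on the gram scale of the configured loss).  Deterministic given the
    config seed.
    """
    config = config or model.config
    if len(train) < 1 or len(val) < 1:
        raise ValueError("need at least one train and one val sample")
    model.fit_normalization(train)
    xtr = model._prep_images(train.images)
    ztr = model._prep_feats(model._variant_feats(train))
    xva = model._prep_images(val.images)
    zva = model._prep_feats(model._variant_feats(val))
    ytr = train.y.astype(np.float64)
    yva = val.y.astype(np.float64)

    rng = np.random.default_rng(derive_seed(config.seed, "regressor-train"))
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, [p.copy() for p, _ in model.parameters()])
    for _ in range(config.epochs):
        perm = rng.permutation(len(train))
        losses = []
        for b0 in range(0, len(perm), config.batch_size):
            idx = perm[b0:b0 + config.batch_size]
            raw = model.forward_raw(xtr[idx],
                                    None if ztr is None else ztr[idx],
                                    train=True)
            loss, g = nn.regression_loss_grad(raw, ytr[idx], config.loss)
            if not np.isfinite(loss):
                raise RuntimeError("non-finite training loss; aborting")
            model.backward(g)
            opt.step()
            losses.append(loss)
        pv = model.forward_raw(xva, zva, train=False)
        val_loss, _ = nn.regression_loss_grad(pv, yva, config.loss)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, [p.copy() for p, _ in model.parameters()])
    for (p, _), s in zip(model.parameters(), best[1]):
        p[...] = s
    history["best_val_loss"] = best[0]
    return model, history


def predict_ebl(model: EBLRegressor, data: FeatureSet) -> list[EBLPrediction]:
    """Batch inference; clamped to >= 0 g, order preserved."""
    preds = model.predict(data)
    return [EBLPrediction(gauze_id=g, predicted_ebl_g=float(p),
                          true_ebl_g=(float(t) if t is not None else None),
                          patient_id=pid)
            for g, p, t, pid in zip(data.gauze_ids, preds, data.y,
                                    data.patient_ids)]


# ---------------------------------------------------------------------------
# feature extraction and the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Stage wiring for detect -> mask -> patches -> CSV -> regress."""

    mask_tile_spec: det.TileSpec = field(
        default_factory=lambda: det.TileSpec(tile_size=32, stride=16,
                                             input_resize=24))
    patch_tile_spec: det.TileSpec = field(default_factory=det.TileSpec)
    lbp: tx.LBPConfig = field(default_factory=tx.LBPConfig)
    min_gauze_fraction: float = 0.5
    patch_weighting: str = "blood_evidence"
    input_side: int = 64
    n_vector: int = 16


def scene_features(frame: np.ndarray, classifier: det.TileClassifier,
                   pipe: PipelineConfig,
                   mass_map: np.ndarray | None = None,
                   ) -> dict | None:
    """Run detection and texture analysis on one frame.

    Returns a dict with the masked-image tensor, global CSV and the
    patch-wise weighted CSV vector, or None when no gauze is detected.
    """
    tc_mask = det.classify_tiles(
        classifier, det.tile_frame(frame, pipe.mask_tile_spec))
    mask = det.assemble_mask(tc_mask, frame.shape[:2], pipe.mask_tile_spec)
    if not mask.any():
        return None
    image = prepare_masked_input(frame, mask, pipe.input_side)

    gray = tx.to_gray(frame)
    lbp = tx.lbp_map(gray, pipe.lbp)
    region = mask & lbp.valid_mask
    if not region.any():
        return None
    csv = tx.compute_csv(lbp, mask).csv

    tc_patch = det.classify_tiles(
        classifier, det.tile_frame(frame, pipe.patch_tile_spec))
    patches = det.extract_patches(frame, mask, tc_patch,
                                  pipe.patch_tile_spec,
                                  pipe.min_gauze_fraction, mass_map=mass_map)
    _, vec = tx.patch_descriptors(patches, pipe.lbp,
                                  weighting=pipe.patch_weighting,
                                  n_vector=pipe.n_vector)
    return {"image": image, "csv": csv, "pwcs": vec, "mask": mask,
            "n_patches": len(patches)}


def extract_features(scenes: list[SceneSample],
                     classifier: det.TileClassifier,
                     pipe: PipelineConfig | None = None) -> FeatureSet:
    """FeatureSet for a list of synthetic scenes (detector-produced masks)."""
    pipe = pipe or PipelineConfig()
    images, csvs, vecs, ys, gids, pids = [], [], [], [], [], []
    for sc in scenes:
        feats = scene_features(sc.frame, classifier, pipe,
                               mass_map=sc.blood_mass_map)
        if feats is None:  # fall back to ground-truth mask region
            image = prepare_masked_input(sc.frame, sc.gauze_mask,
                                         pipe.input_side)
            feats = {"image": image, "csv": 0.0,
                     "pwcs": np.zeros(pipe.n_vector)}
        images.append(feats["image"])
        csvs.append(feats["csv"])
        vecs.append(feats["pwcs"])
        ys.append(sc.ebl_label_g)
        gids.append(sc.gauze_id)
        pids.append(sc.patient_id)
    return FeatureSet(images=np.stack(images), csv=np.array(csvs),
                      pwcs=np.stack(vecs), y=np.array(ys),
                      gauze_ids=gids, patient_ids=pids)


@dataclass
class PipelineResult:
    gauze_id: str
    predicted_ebl_g: float | None
    skipped: bool = False
    reason: str = ""


def run_pipeline(frames: list[np.ndarray], detector: det.TileClassifier,
                 regressor: EBLRegressor,
                 pipe: PipelineConfig | None = None,
                 gauze_ids: list[str] | None = None) -> list[PipelineResult]:
    """Detect -> mask -> patches -> LBP/CSV -> regress, one entry per frame.

    Frames where no gauze is detected are reported as skipped with a reason,
    never silently dropped; output order matches input order.
    """
    pipe = pipe or PipelineConfig()
    if gauze_ids is None:
        gauze_ids = [f"frame{i:04d}" for i in range(len(frames))]
    results: list[PipelineResult] = []
    for gid, frame in zip(gauze_ids, frames):
        feats = scene_features(frame, detector, pipe)
        if feats is None:
            results.append(PipelineResult(gauze_id=gid, predicted_ebl_g=None,
                                          skipped=True,
                                          reason="no gauze detected"))
            continue
        data = FeatureSet(images=feats["image"][None],
                          csv=np.array([feats["csv"]]),
                          pwcs=feats["pwcs"][None],
                          y=np.array([np.nan]), gauze_ids=[gid],
                          patient_ids=[""])
        pred = float(regressor.predict(data)[0])
        results.append(PipelineResult(gauze_id=gid, predicted_ebl_g=pred))
    return results
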