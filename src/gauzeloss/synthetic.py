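"""Synthetic laparoscopic gauze scenes with known blood mass.

Generates frames that carry the statistical structure the estimation method
assumes, with exact ground truth at every stage:

* a woven gauze texture confined to a connected blob on a tissue-like (or
  dark-cavity) background, with a known binary gauze mask;
* a crumple field — band-limited multi-scale noise — rendered as a smooth
  displacement warp of the weave plus multiplicative shading, so folds both
  look shaded and perturb the texture geometry;
* red blood staining whose placement probability increases with local crumple
  (blood pools in folds) and whose per-pixel mass capacity also increases with
  local crumple, so that stained *extent* alone under-determines mass — the
  confound that makes crumple features informative;
* a per-pixel blood-mass map summing exactly to the scene's gram label.

Default mass labels emulate the reported intraoperative per-gauze range
0.13–9.98 g with mean 4.17 g.
"""

from __future__ import annotations

import dataclasses
import os
import zlib
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

# Mass range/mean of the per-gauze blood-loss distribution being emulated.
MASS_RANGE_G = (0.13, 9.98)
MASS_MEAN_G = 4.17

# Baseline whole-gauze absorption capacity (grams) when completely flat; local
# capacity grows by GAMMA per unit of local crumple amplitude.
GAUZE_CAPACITY_G = 12.0
CRUMPLE_CAPACITY_GAIN = 0.8

BACKGROUND_KINDS = ("tissue", "dark_cavity")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed from a single global seed (< 2**31)."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene."""

    image_height: int = 256
    image_width: int = 256
    gauze_area_fraction: float = 0.35
    crumple_intensity: float = 1.0
    blood_mass_g: float = MASS_MEAN_G
    stain_spread: float = 1.0
    background_kind: str = "tissue"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image dimensions must be at least 32 px")
        if not 0.0 < self.gauze_area_fraction < 1.0:
            raise ValueError("gauze_area_fraction must lie strictly in (0, 1)")
        if self.crumple_intensity < 0:
            raise ValueError("crumple_intensity must be >= 0")
        if self.blood_mass_g < 0:
            raise ValueError("blood_mass_g must be >= 0")
        if self.stain_spread <= 0:
            raise ValueError("stain_spread must be > 0")
        if self.background_kind not in BACKGROUND_KINDS:
            raise ValueError(f"background_kind must be one of {BACKGROUND_KINDS}")


@dataclass
class SceneSample:
    """One rendered scene with full ground truth."""

    frame: np.ndarray            # (H, W, 3) uint8
    gauze_mask: np.ndarray       # (H, W) bool
    blood_mass_map: np.ndarray   # (H, W) float64 grams, sums to ebl_label_g
    ebl_label_g: float
    crumple_field: np.ndarray    # (H, W) float64 fold amplitude >= 0
    gauze_id: str = "g0"
    patient_id: str = ""
    params: SceneParams | None = None


# ---------------------------------------------------------------------------
# stage 1: weave texture on a connected blob
# ---------------------------------------------------------------------------

def generate_gauze_texture(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Render the clean woven-gauze texture confined to a connected region.

    Returns (texture, mask): an 8-bit grayscale weave (zero outside the mask)
    and the boolean gauze mask, a star-shaped (hence connected) blob whose
    area is ``gauze_area_fraction`` of the frame to within +-0.05.
    """
    h, w = params.image_height, params.image_width
    rng = np.random.default_rng(derive_seed(params.seed, "texture"))

    cy = h / 2 + rng.uniform(-0.04, 0.04) * h
    cx = w / 2 + rng.uniform(-0.04, 0.04) * w
    # star-shaped boundary: r(theta) = r0 * (1 + low-order harmonic wobble)
    k = np.arange(2, 6)
    amp = rng.uniform(-1, 1, size=k.size) * 0.18 / k
    phase = rng.uniform(0, 2 * np.pi, size=k.size)

    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = np.zeros_like(theta)
    for a, kk, ph in zip(amp, k, phase):
        wobble += a * np.cos(kk * theta + ph)
    # area of r(th) = r0 (1 + f(th)) is (r0^2 / 2) * integral (1+f)^2 dth
    th_grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    f_grid = np.zeros_like(th_grid)
    for a, kk, ph in zip(amp, k, phase):
        f_grid += a * np.cos(kk * th_grid + ph)
    integral = np.mean((1 + f_grid) ** 2) * 2 * np.pi
    target_area = params.gauze_area_fraction * h * w
    r0 = np.sqrt(2 * target_area / integral)

    dist = np.hypot(yy - cy, xx - cx)
    mask = dist <= r0 * (1 + wobble)

    # orthogonal-weave pattern with slight orientation jitter and fiber noise
    ang = rng.uniform(-0.3, 0.3)
    period = 8.0
    u = (xx * np.cos(ang) + yy * np.sin(ang)) / period
    v = (-xx * np.sin(ang) + yy * np.cos(ang)) / period
    weave = 0.5 * (np.sin(2 * np.pi * u) + np.sin(2 * np.pi * v))
    fiber = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.0)
    tex = 190 + 28 * weave + 10 * fiber
    tex = np.clip(np.rint(tex), 0, 255).astype(np.uint8)
    tex[~mask] = 0
    return tex, mask


# ---------------------------------------------------------------------------
# stage 2: crumpling
# ---------------------------------------------------------------------------

def _band_limited(rng: np.random.Generator, shape: tuple[int, int],
                  sigmas=(4.0, 10.0), weights=(0.6, 0.4)) -> np.ndarray:
    """Unit-std multi-scale smooth noise field."""
    out = np.zeros(shape)
    for s, w in zip(sigmas, weights):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), s)
        out += w * f / max(f.std(), 1e-12)
    return out / max(out.std(), 1e-12)


def apply_crumple(texture: np.ndarray, mask: np.ndarray, intensity: float,
                  seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Fold the gauze: warp the weave and shade it with a smooth fold field.

    The fold field is band-limited noise; its positive-normalized form scaled
    by ``intensity`` is returned as the per-pixel crumple amplitude.  Shading
    is multiplicative (local contrast grows with intensity) and the weave is
    resampled through a smooth displacement so fold geometry perturbs the
    texture itself.  ``intensity=0`` returns the input untouched.
    """
    if intensity < 0:
        raise ValueError("crumple intensity must be >= 0")
    texture = np.asarray(texture)
    h, w = texture.shape
    if intensity == 0:
        return texture.copy(), np.zeros((h, w))

    rng = np.random.default_rng(derive_seed(seed, "crumple"))
    raw = _band_limited(rng, (h, w))
    field01 = (raw - raw.min()) / max(np.ptp(raw), 1e-12)
    crumple_field = intensity * field01

    # smooth displacement (px) and shading derived from independent fields;
    # nearest-neighbor resampling distorts fold geometry without low-pass
    # smoothing, so local contrast stays monotone in the fold amplitude
    dy = _band_limited(rng, (h, w), sigmas=(6.0,), weights=(1.0,))
    dx = _band_limited(rng, (h, w), sigmas=(6.0,), weights=(1.0,))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    amp = 1.6 * intensity
    warped = ndimage.map_coordinates(texture.astype(float),
                                     [yy + amp * dy, xx + amp * dx],
                                     order=0, mode="nearest")
    fine = _band_limited(rng, (h, w), sigmas=(2.0,), weights=(1.0,))
    shade = 1.0 + 0.18 * intensity * (2 * field01 - 1) \
        + 0.04 * intensity * fine
    out_f = warped * np.clip(shade, 0.1, None)
    out = texture.copy()
    out[mask] = np.clip(np.rint(out_f[mask]), 0, 255).astype(np.uint8)
    return out, crumple_field


# ---------------------------------------------------------------------------
# stage 3: blood staining
# ---------------------------------------------------------------------------

def _background(kind: str, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    shading = ndimage.gaussian_filter(rng.standard_normal((h, w)), 12.0)
    shading /= max(shading.std(), 1e-12)
    grain = rng.normal(0, 4, size=(h, w))
    if kind == "tissue":
        base = np.array([168.0, 92.0, 88.0])
    else:  # dark_cavity
        base = np.array([52.0, 30.0, 30.0])
    img = base[None, None, :] + (26 * shading + grain)[:, :, None]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def apply_blood_stain(texture: np.ndarray, mask: np.ndarray,
                      crumple_field: np.ndarray, blood_mass_g: float,
                      stain_spread: float, seed: int,
                      background_kind: str = "tissue",
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Deposit blood on the crumpled gauze and compose the RGB frame.

    Stain placement follows a score field dominated by the crumple amplitude
    (blood pools in folds; ``stain_spread`` mixes in a smooth random field to
    disperse it).  Pixels are stained in score order until their cumulative
    absorption capacity — rho0 * (1 + gain * crumple) per pixel — reaches the
    requested mass, which the returned mass map sums to exactly.
    """
    if blood_mass_g < 0:
        raise ValueError("blood_mass_g must be >= 0")
    if not mask.any():
        raise ValueError("no gauze region")
    h, w = texture.shape
    rng = np.random.default_rng(derive_seed(seed, "stain"))

    frame = _background(background_kind, h, w, rng)
    tex = texture.astype(float)
    gauze_rgb = np.stack([tex, tex, tex * 0.96], axis=-1)
    frame = frame.astype(float)
    frame[mask] = gauze_rgb[mask]

    mass_map = np.zeros((h, w), dtype=np.float64)
    if blood_mass_g > 0:
        n_mask = int(mask.sum())
        rho0 = GAUZE_CAPACITY_G / n_mask
        capacity = rho0 * (1.0 + CRUMPLE_CAPACITY_GAIN * crumple_field)

        disp = _band_limited(rng, (h, w), sigmas=(5.0,), weights=(1.0,))
        wmix = stain_spread / (1.0 + stain_spread)
        cf = crumple_field[mask]
        cf = (cf - cf.mean()) / max(cf.std(), 1e-12)
        score = (1 - wmix) * cf + wmix * disp[mask]

        order = np.argsort(-score, kind="stable")
        cap_m = capacity[mask][order]
        cum = np.cumsum(cap_m)
        if blood_mass_g >= cum[-1]:
            k = n_mask  # saturated gauze: stain everything, scale density up
        else:
            k = int(np.searchsorted(cum, blood_mass_g)) + 1
        chosen = order[:k]
        masses = cap_m[:k] * (blood_mass_g / cum[k - 1])
        idx_r, idx_c = np.nonzero(mask)
        mass_map[idx_r[chosen], idx_c[chosen]] = masses

        # render: semi-transparent dark red that keeps the weave visible
        stained = mass_map > 0
        alpha = np.where(stained, 0.72, 0.0)[:, :, None]
        blood = np.array([125.0, 18.0, 24.0])[None, None, :] * \
            (0.55 + 0.45 * tex / 255.0)[:, :, None]
        frame = (1 - alpha) * frame + alpha * blood

    return np.clip(np.rint(frame), 0, 255).astype(np.uint8), mass_map


def background_frame(height: int, width: int, kind: str = "tissue",
                     seed: int = 0) -> np.ndarray:
    """A gauze-free frame (pure background), e.g. to exercise skip paths."""
    if kind not in BACKGROUND_KINDS:
        raise ValueError(f"background kind must be one of {BACKGROUND_KINDS}")
    rng = np.random.default_rng(derive_seed(seed, "bgframe"))
    return _background(kind, height, width, rng)


# ---------------------------------------------------------------------------
# scene and dataset assembly
# ---------------------------------------------------------------------------

def generate_scene(params: SceneParams, gauze_id: str = "g0",
                   patient_id: str = "") -> SceneSample:
    """Render a complete scene from parameters (deterministic in the seed)."""
    tex, mask = generate_gauze_texture(params)
    crumpled, cfield = apply_crumple(tex, mask, params.crumple_intensity,
                                     params.seed)
    frame, mass_map = apply_blood_stain(crumpled, mask, cfield,
                                        params.blood_mass_g,
                                        params.stain_spread, params.seed,
                                        params.background_kind)
    # enforce exact label consistency (float64 summation residual only)
    return SceneSample(frame=frame, gauze_mask=mask, blood_mass_map=mass_map,
                       ebl_label_g=float(mass_map.sum()),
                       crumple_field=cfield, gauze_id=gauze_id,
                       patient_id=patient_id, params=params)


def sample_masses(n: int, rng: np.random.Generator,
                  low: float = MASS_RANGE_G[0], high: float = MASS_RANGE_G[1],
                  mean: float = MASS_MEAN_G) -> np.ndarray:
    """Per-gauze masses: scaled Beta matching the emulated range and mean."""
    a = 2.0
    m = (mean - low) / (high - low)
    b = a * (1 - m) / m
    return low + (high - low) * rng.beta(a, b, size=n)


def sample_scene_params(n: int, seed: int, image_size: int = 256,
                        background_kind: str | None = None,
                        ) -> list[SceneParams]:
    """Draw n scene-parameter sets spanning the study conditions."""
    rng = np.random.default_rng(derive_seed(seed, "params"))
    masses = sample_masses(n, rng)
    out = []
    for i in range(n):
        bg = background_kind or ("dark_cavity" if rng.uniform() < 0.2
                                 else "tissue")
        out.append(SceneParams(
            image_height=image_size, image_width=image_size,
            gauze_area_fraction=float(rng.uniform(0.28, 0.42)),
            crumple_intensity=float(rng.uniform(0.25, 2.25)),
            blood_mass_g=float(masses[i]),
            stain_spread=float(rng.uniform(0.6, 1.4)),
            background_kind=bg,
            seed=derive_seed(seed, f"scene{i}"),
        ))
    return out


def assign_patients(n: int, seed: int) -> list[str]:
    """Group consecutive gauzes into synthetic patients of 1–10 gauzes."""
    rng = np.random.default_rng(derive_seed(seed, "patients"))
    ids: list[str] = []
    p = 0
    while len(ids) < n:
        p += 1
        ids.extend([f"p{p:04d}"] * int(rng.integers(1, 11)))
    return ids[:n]


def assign_splits(ebl: np.ndarray, ratio: tuple[int, int, int] = (3, 1, 1),
                  seed: int = 0) -> np.ndarray:
    """Stratified train/val/test split covering the whole mass range.

    Samples are ordered by label and split labels dealt block-wise in the
    requested ratio, so each split spans the full weight distribution.  Split
    sizes follow the exact ratio (largest-remainder rounding).
    """
    if any(r <= 0 for r in ratio):
        raise ValueError("split ratio components must be positive")
    n = len(ebl)
    names = np.array(["train", "val", "test"])
    total = sum(ratio)
    exact = np.array([n * r / total for r in ratio])
    counts = np.floor(exact).astype(int)
    rem = np.argsort(-(exact - counts), kind="stable")
    for i in rem[: n - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(derive_seed(seed, "split"))
    order = np.argsort(np.asarray(ebl), kind="stable")
    labels = np.empty(n, dtype=object)
    remaining = counts.copy()
    pattern = np.repeat(np.arange(3), ratio)
    pos = 0
    while pos < n:
        block = min(total, n - pos)
        if block == total and np.all(remaining >= ratio):
            blk = pattern.copy()
            remaining -= np.asarray(ratio)
        else:  # tail: deal whatever quota is left
            blk = np.repeat(np.arange(3), remaining)[:block]
            cnt = np.bincount(blk, minlength=3)
            remaining -= cnt
        rng.shuffle(blk)
        labels[order[pos:pos + block]] = names[blk]
        pos += block
    return labels.astype(str)


def generate_dataset(out_dir: str, n: int, seed: int,
                     split_ratio: tuple[int, int, int] = (3, 1, 1),
                     image_size: int = 256,
                     write_massmaps: bool = True) -> pd.DataFrame:
    """Render n scenes to disk with a manifest CSV; returns the manifest.

    Layout: frames/<id>.png (RGB), masks/<id>.png (0/255), massmaps/<id>.npy
    (float64 grams) and manifest.csv with one row per gauze.
    """
    if n < 5:
        raise ValueError("need at least 5 scenes to split 3:1:1")
    os.makedirs(out_dir, exist_ok=True)
    for sub in ("frames", "masks", "massmaps" if write_massmaps else ""):
        if sub:
            os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

    params = sample_scene_params(n, seed, image_size=image_size)
    patients = assign_patients(n, seed)
    rows = []
    ebl = []
    for i, p in enumerate(params):
        gid = f"g{i:04d}"
        scene = generate_scene(p, gauze_id=gid, patient_id=patients[i])
        fpath = os.path.join("frames", f"{gid}.png")
        mpath = os.path.join("masks", f"{gid}.png")
        iio.imwrite(os.path.join(out_dir, fpath), scene.frame)
        iio.imwrite(os.path.join(out_dir, mpath),
                    (scene.gauze_mask * 255).astype(np.uint8))
        mmpath = ""
        if write_massmaps:
            mmpath = os.path.join("massmaps", f"{gid}.npy")
            np.save(os.path.join(out_dir, mmpath), scene.blood_mass_map)
        rows.append({"frame_path": fpath, "mask_path": mpath,
                     "massmap_path": mmpath, "gauze_id": gid,
                     "patient_id": patients[i],
                     "ebl_g": scene.ebl_label_g})
        ebl.append(scene.ebl_label_g)

    manifest = pd.DataFrame(rows)
    manifest["split"] = assign_splits(np.array(ebl), split_ratio, seed)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
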