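"""Local binary patterns and the crumpled-state value (CSV) of gauze.

The LBP code of a center pixel c thresholds P neighbors sampled on a circle
of radius r against the center intensity:

    LBP_{P,R}(c) = sum_{p=0}^{P-1} s(g_p - g_c) * 2^p,   s(x) = 1 iff x >= 0

with neighbor p at angle 2*pi*p/P counterclockwise from the +column axis,
i.e. offset (drow, dcol) = (-r sin, +r cos).  Non-integer sample positions
are resolved by bilinear interpolation (default) or nearest-pixel rounding;
interpolated values within 1e-6 of an integer are snapped to it before the
comparison, so integer images behave exactly (s(0) = 1 on constant regions).

The crumpled-state value is the mean LBP code over the detected gauze region,
a scalar in [0, 2^P - 1] summarizing how crumpled the gauze appears; the
patch-wise variant weights each gauze patch's CSV by a blood-evidence score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GRAY_WEIGHTS = (0.299, 0.587, 0.114)
_SNAP_EPS = 1e-6

WEIGHTING_MODES = ("blood_evidence", "uniform", "ground_truth_mass")


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Luminance grayscale (0.299 R + 0.587 G + 0.114 B) as float64."""
    if frame.ndim == 2:
        return frame.astype(np.float64)
    r, g, b = GRAY_WEIGHTS
    return (r * frame[..., 0] + g * frame[..., 1]
            + b * frame[..., 2]).astype(np.float64)


@dataclass(frozen=True)
class LBPConfig:
    radius: float = 3.0
    neighbors: int = 8
    sampling: str = "bilinear"  # or "nearest"

    def __post_init__(self) -> None:
        if self.neighbors < 4:
            raise ValueError("neighbors must be >= 4")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.sampling not in ("bilinear", "nearest"):
            raise ValueError("sampling must be 'bilinear' or 'nearest'")


@dataclass
class LBPMap:
    codes: np.ndarray       # int32 grid, valid entries in [0, 2^P - 1]
    valid_mask: np.ndarray  # bool grid: full neighborhood inside the image
    config: LBPConfig


@dataclass
class CrumpleStateValue:
    csv: float
    region_pixel_count: int


@dataclass
class PatchDescriptor:
    patch_csv: CrumpleStateValue
    weight: float
    weighted_csv: float
    row: int = 0
    col: int = 0


def _neighbor_offsets(config: LBPConfig) -> np.ndarray:
    p = np.arange(config.neighbors)
    th = 2 * np.pi * p / config.neighbors
    off = np.stack([-config.radius * np.sin(th),
                    config.radius * np.cos(th)], axis=1)
    snap = np.rint(off)
    off[np.abs(off - snap) < 1e-9] = snap[np.abs(off - snap) < 1e-9]
    return off


def _snap(values: np.ndarray) -> np.ndarray:
    r = np.rint(values)
    near = np.abs(values - r) < _SNAP_EPS
    return np.where(near, r, values)


def lbp_map(gray: np.ndarray, config: LBPConfig = LBPConfig()) -> LBPMap:
    """Per-pixel LBP codes with a validity mask excluding border pixels.

    ``gray`` must be single-channel; multi-channel frames should be converted
    with :func:`to_gray` first.  Codes are only meaningful where
    ``valid_mask`` is True (the full sampling circle lies inside the image);
    invalid entries are set to -1, never silently zero.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("lbp_map expects a single-channel image; convert "
                         "RGB frames to grayscale first (see to_gray)")
    margin = int(np.ceil(config.radius))
    h, w = gray.shape
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError("image too small for the requested LBP radius")

    g = gray.astype(np.float64)
    codes = np.zeros((h, w), dtype=np.int32)
    hi, wi = h - 2 * margin, w - 2 * margin
    center = g[margin:margin + hi, margin:margin + wi]

    for p, (dr, dc) in enumerate(_neighbor_offsets(config)):
        if config.sampling == "nearest":
            r0, c0 = int(np.rint(dr)), int(np.rint(dc))
            sample = g[margin + r0:margin + r0 + hi,
                       margin + c0:margin + c0 + wi]
        else:
            fr0, fc0 = int(np.floor(dr)), int(np.floor(dc))
            tr, tc = dr - fr0, dc - fc0
            fr1 = fr0 + 1 if tr > 0 else fr0
            fc1 = fc0 + 1 if tc > 0 else fc0

            def shifted(ro: int, co: int) -> np.ndarray:
                return g[margin + ro:margin + ro + hi,
                         margin + co:margin + co + wi]

            sample = ((1 - tr) * (1 - tc) * shifted(fr0, fc0)
                      + (1 - tr) * tc * shifted(fr0, fc1)
                      + tr * (1 - tc) * shifted(fr1, fc0)
                      + tr * tc * shifted(fr1, fc1))
            sample = _snap(sample)
        bit = (sample - center) >= 0
        codes[margin:margin + hi, margin:margin + wi] += \
            bit.astype(np.int32) << p

    valid = np.zeros((h, w), dtype=bool)
    valid[margin:margin + hi, margin:margin + wi] = True
    codes[~valid] = -1
    return LBPMap(codes=codes, valid_mask=valid, config=config)


def compute_csv(lbp: LBPMap, gauze_mask: np.ndarray) -> CrumpleStateValue:
    """Mean LBP code over the gauze region (valid pixels only).

    The denominator is the count of gauze pixels with valid codes; border
    pixels whose sampling circle leaves the image are excluded from both the
    numerator and the denominator.
    """
    region = np.asarray(gauze_mask, dtype=bool) & lbp.valid_mask
    n = int(region.sum())
    if n == 0:
        raise ValueError("no valid gauze pixels")
    total = float(lbp.codes[region].sum(dtype=np.int64))
    return CrumpleStateValue(csv=total / n, region_pixel_count=n)


def patch_descriptors(patches: Sequence, config: LBPConfig = LBPConfig(),
                      weighting: str = "blood_evidence",
                      n_vector: int = 16,
                      ) -> tuple[list[PatchDescriptor], np.ndarray]:
    """Per-patch weighted CSVs and the fixed-length fusion vector.

    Each patch must expose ``image`` (RGB or gray crop), ``mask`` (bool crop)
    and, depending on the weighting mode, ``blood_evidence`` (stained+soaked
    probability from the tile classifier, in [0, 1]) or ``mass_g`` (simulated
    per-patch blood mass; simulation-only oracle mode, normalized to [0, 1]
    across the patch set).  The fusion vector holds the first ``n_vector``
    weighted CSVs after a descending sort, zero-padded — an empty patch list
    yields an all-zero vector (clean-gauze frames still regress).
    """
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}")
    patches = list(patches)
    if not patches:
        logger.warning("patch_descriptors: no patches; emitting zero vector")
        return [], np.zeros(n_vector, dtype=np.float64)

    if weighting == "ground_truth_mass":
        masses = np.array([float(p.mass_g) for p in patches])
        norm = masses.max()
        weights = masses / norm if norm > 0 else np.zeros_like(masses)
    elif weighting == "uniform":
        weights = np.ones(len(patches))
    else:
        weights = np.array([float(p.blood_evidence) for p in patches])

    descs: list[PatchDescriptor] = []
    for patch, wgt in zip(patches, weights):
        gray = to_gray(patch.image)
        lbp = lbp_map(gray, config)
        region = np.asarray(patch.mask, dtype=bool) & lbp.valid_mask
        if region.any():
            csv = compute_csv(lbp, patch.mask)
        else:
            logger.warning("patch with no valid gauze pixels; csv set to 0")
            csv = CrumpleStateValue(csv=0.0, region_pixel_count=0)
        descs.append(PatchDescriptor(
            patch_csv=csv, weight=float(wgt),
            weighted_csv=float(wgt) * csv.csv,
            row=getattr(patch, "row", 0), col=getattr(patch, "col", 0)))

    vec = np.zeros(n_vector, dtype=np.float64)
    vals = sorted((d.weighted_csv for d in descs), reverse=True)[:n_vector]
    vec[:len(vals)] = vals
    return descs, vec
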