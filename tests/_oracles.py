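"""Independent brute-force oracles used by the tests.

These re-derive expected values by direct enumeration, without calling the
package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_lbp(img: np.ndarray, radius: float = 3.0, neighbors: int = 8,
              sampling: str = "bilinear") -> np.ndarray:
    """Per-pixel LBP codes by a literal double loop; -1 where invalid.

    Convention: neighbor p sits at angle 2*pi*p/P counterclockwise from the
    +column axis, i.e. offset (drow, dcol) = (-r sin, +r cos); bit p is 1
    iff sample - center >= 0; interpolated samples within 1e-6 of an integer
    are snapped before comparison.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    margin = int(math.ceil(radius))
    out = np.full((h, w), -1, dtype=np.int64)
    for i in range(margin, h - margin):
        for j in range(margin, w - margin):
            code = 0
            for p in range(neighbors):
                th = 2 * math.pi * p / neighbors
                dr, dc = -radius * math.sin(th), radius * math.cos(th)
                if abs(dr - round(dr)) < 1e-9:
                    dr = round(dr)
                if abs(dc - round(dc)) < 1e-9:
                    dc = round(dc)
                rr, cc = i + dr, j + dc
                if sampling == "nearest":
                    v = img[int(round(rr)), int(round(cc))]
                else:
                    r0, c0 = int(math.floor(rr)), int(math.floor(cc))
                    fr, fc = rr - r0, cc - c0
                    r1 = r0 + 1 if fr > 0 else r0
                    c1 = c0 + 1 if fc > 0 else c0
                    v = ((1 - fr) * (1 - fc) * img[r0, c0]
                         + (1 - fr) * fc * img[r0, c1]
                         + fr * (1 - fc) * img[r1, c0]
                         + fr * fc * img[r1, c1])
                    if abs(v - round(v)) < 1e-6:
                        v = round(v)
                if v - img[i, j] >= 0:
                    code += 2 ** p
            out[i, j] = code
    return out


def naive_mae(pred, true) -> float:
    total = 0.0
    for p, t in zip(pred, true):
        total += abs(t - p)
    return total / len(pred)


def naive_mape(pred, true) -> float:
    total = 0.0
    for p, t in zip(pred, true):
        total += abs((t - p) / t)
    return total / len(pred) * 100.0


def naive_mse(pred, true) -> float:
    total = 0.0
    for p, t in zip(pred, true):
        total += (t - p) ** 2
    return total / len(pred)
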