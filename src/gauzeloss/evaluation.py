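"""Evaluation protocol: MAE/MAPE/MSE, strata, patients, agreement, CV.

Errors are reported in grams (MAE), grams squared (MSE) and percent (MAPE),
stratified by the true per-gauze blood mass (<= 3 g, 3–5 g, > 5 g) and at
two aggregation levels: per gauze, and per patient after summing each
patient's predicted and true totals.  Per-patient agreement is summarized by
a Bland–Altman bias and 1.96-sd limits of agreement.  Cross-validation folds
group by patient (no patient spans folds) and are stratified by patient
total mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

STRATA_NAMES = ("le3g", "g3to5", "gt5g")
DEFAULT_STRATA = (3.0, 5.0)


@dataclass
class MetricsReport:
    n: int
    mae_g: float | None
    mape_pct: float | None
    mse_g2: float | None
    stratum: str = "all"
    level: str = "per_gauze"


@dataclass
class BlandAltmanSummary:
    bias_g: float
    loa_low_g: float
    loa_high_g: float
    sd_g: float
    n: int


def _check_lengths(pred, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(true, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("pred and true must be 1-D and equal length")
    if p.size == 0:
        raise ValueError("empty prediction list")
    return p, t


def mae(pred, true) -> float:
    """Mean absolute error, grams: (1/n) * sum |y_i - yhat_i|."""
    p, t = _check_lengths(pred, true)
    return float(np.abs(t - p).mean())


def mse(pred, true) -> float:
    """Mean squared error, grams^2: (1/n) * sum (y_i - yhat_i)^2."""
    p, t = _check_lengths(pred, true)
    return float(((t - p) ** 2).mean())


def mape(pred, true, zero_floor: float = 0.01, ids=None) -> float:
    """Mean absolute percentage error: (1/n) * sum |(y - yhat)/y| * 100.

    Any |y_i| below ``zero_floor`` (default 0.01 g, below the smallest
    per-gauze mass the protocol emulates) raises an error naming the
    offending samples rather than returning an exploding percentage.
    """
    p, t = _check_lengths(pred, true)
    bad = np.flatnonzero(np.abs(t) < zero_floor)
    if bad.size:
        names = ([ids[i] for i in bad[:10]] if ids is not None
                 else bad[:10].tolist())
        raise ValueError(f"true values below zero_floor={zero_floor} g for "
                         f"samples {names}")
    return float((np.abs((t - p) / t)).mean() * 100.0)


def _report(pred: np.ndarray, true: np.ndarray, stratum: str,
            level: str) -> MetricsReport:
    if len(pred) == 0:
        return MetricsReport(n=0, mae_g=None, mape_pct=None, mse_g2=None,
                             stratum=stratum, level=level)
    return MetricsReport(n=len(pred), mae_g=mae(pred, true),
                         mape_pct=mape(pred, true), mse_g2=mse(pred, true),
                         stratum=stratum, level=level)


def stratified_report(pred, true, strata: tuple[float, float] = DEFAULT_STRATA,
                      level: str = "per_gauze", overall: str = "pooled",
                      ) -> dict[str, MetricsReport]:
    """Metrics within true-mass strata plus an overall row.

    The overall row pools all samples (not the mean of stratum means);
    ``overall='both'`` additionally emits the unweighted stratum-mean row
    under the key ``"all_stratum_mean"``.  Empty strata are reported with
    n=0 and missing metrics.
    """
    lo, hi = strata
    if not lo < hi:
        raise ValueError("strata bounds must be strictly increasing")
    p, t = _check_lengths(pred, true)
    masks = {"le3g": t <= lo, "g3to5": (t > lo) & (t <= hi), "gt5g": t > hi}
    out = {name: _report(p[m], t[m], name, level)
           for name, m in masks.items()}
    out["all"] = _report(p, t, "all", level)
    if overall == "both":
        vals = [(r.mae_g, r.mape_pct, r.mse_g2)
                for r in (out[n] for n in STRATA_NAMES) if r.n > 0]
        m = np.array(vals, dtype=np.float64)
        out["all_stratum_mean"] = MetricsReport(
            n=out["all"].n, mae_g=float(m[:, 0].mean()),
            mape_pct=float(m[:, 1].mean()), mse_g2=float(m[:, 2].mean()),
            stratum="all_stratum_mean", level=level)
    return out


def per_patient_totals(predictions) -> pd.DataFrame:
    """Sum per-gauze predictions and labels within each patient."""
    rows = [{"patient_id": p.patient_id, "pred": p.predicted_ebl_g,
             "true": p.true_ebl_g} for p in predictions]
    df = pd.DataFrame(rows)
    if df["patient_id"].eq("").any() or df["true"].isna().any():
        raise ValueError("per-patient evaluation requires patient_id and "
                         "true label on every prediction")
    return df.groupby("patient_id", sort=True).sum().reset_index()


def bland_altman(pred_totals, true_totals) -> BlandAltmanSummary:
    """Bias (pred - true) and 1.96-sd limits of agreement."""
    p, t = _check_lengths(pred_totals, true_totals)
    d = p - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return BlandAltmanSummary(bias_g=bias, loa_low_g=bias - 1.96 * sd,
                              loa_high_g=bias + 1.96 * sd, sd_g=sd,
                              n=len(d))


def per_patient_report(predictions,
                       strata: tuple[float, float] = DEFAULT_STRATA,
                       ) -> tuple[MetricsReport, BlandAltmanSummary,
                                  pd.DataFrame]:
    """Per-patient metrics over summed totals plus Bland–Altman agreement."""
    totals = per_patient_totals(predictions)
    rep = _report(totals["pred"].to_numpy(), totals["true"].to_numpy(),
                  "all", "per_patient")
    ba = bland_altman(totals["pred"].to_numpy(), totals["true"].to_numpy())
    return rep, ba, totals


def bland_altman_plot(pred_totals, true_totals, out_path: str) -> None:
    """Save a per-patient Bland–Altman plot (difference vs mean of totals)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p, t = _check_lengths(pred_totals, true_totals)
    ba = bland_altman(p, t)
    mean = (p + t) / 2
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, p - t, s=14, alpha=0.7)
    for yv, style in [(ba.bias_g, "-"), (ba.loa_low_g, "--"),
                      (ba.loa_high_g, "--")]:
        ax.axhline(yv, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of predicted and true patient EBL (g)")
    ax.set_ylabel("Predicted - true (g)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def relative_improvement(metric_ref: float, metric_new: float) -> float:
    """Percent improvement of ``metric_new`` over ``metric_ref``, 2 decimals."""
    if metric_ref <= 0:
        raise ValueError("reference metric must be > 0")
    return round(100.0 * (metric_ref - metric_new) / metric_ref, 2)


def kfold_cv(manifest: pd.DataFrame, k: int,
             train_fn: Callable[[pd.DataFrame, int], object],
             eval_fn: Callable[[object, pd.DataFrame], MetricsReport],
             seed: int = 0) -> dict:
    """Patient-grouped, mass-stratified k-fold cross-validation.

    ``manifest`` needs columns ``patient_id`` and ``ebl_g``.  Patients are
    ranked by total mass and dealt round-robin into k folds (fold sizes
    differ by at most one patient; no patient spans folds).  Returns per-fold
    reports, their mean/sd, and the patient->fold assignment.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    totals = manifest.groupby("patient_id")["ebl_g"].sum()
    patients = totals.index.to_numpy()
    if len(patients) < k:
        raise ValueError(f"only {len(patients)} patients for {k} folds")
    rng = np.random.default_rng(seed)
    order = np.argsort(totals.to_numpy(), kind="stable")
    # random fold offset per stratified block keeps assignment seed-dependent
    fold_of: dict[str, int] = {}
    pos = 0
    while pos < len(patients):
        block = order[pos:pos + k]
        folds = rng.permutation(k)[: len(block)]
        for pi, f in zip(block, folds):
            fold_of[str(patients[pi])] = int(f)
        pos += k

    reports = []
    for f in range(k):
        test_pat = {p for p, ff in fold_of.items() if ff == f}
        test_df = manifest[manifest["patient_id"].isin(test_pat)]
        train_df = manifest[~manifest["patient_id"].isin(test_pat)]
        model = train_fn(train_df, f)
        reports.append(eval_fn(model, test_df))

    def agg(fn):
        return {m: float(fn([getattr(r, m) for r in reports]))
                for m in ("mae_g", "mape_pct", "mse_g2")}

    return {"folds": reports, "mean": agg(np.mean), "sd": agg(np.std),
            "fold_of": fold_of}
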