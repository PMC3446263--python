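"""QC-anchored loess signal correction (QC-RLSC) and QC-based QA filtering.

Pooled QC injections are repeated measurements of the same material, so any
smooth change in their measured peak area over injection order is instrument
drift.  QC-RLSC fits a robust locally weighted regression of QC intensity on
injection order per feature, interpolates the trend at every injection, and
divides each measurement by the trend (rescaling to a reference level so
corrected values stay in peak-area units).

The QA filter then keeps only features that behave well in the QCs: detected
in more than ``detection_threshold`` of QC injections from injection
``qc_from_injection`` onwards (the first injections condition the column and
are excluded) and with a relative standard deviation across those QCs below
``rsd_threshold`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import StageError, TrendFitError
from .peaktable import FeatureTable

MIN_QC_POINTS = 4


@dataclass
class TrendCurve:
    """Fitted drift trend for one feature, evaluated at every injection."""

    feature_id: str
    orders: np.ndarray
    values: np.ndarray   # strictly positive
    span: float


@dataclass
class QAReport:
    """Per-feature QC detection/RSD metrics plus run-level counts."""

    metrics: pd.DataFrame          # qc_detection_fraction, qc_rsd_percent, passed
    n_in: int
    n_retained: int
    n_removed: int

    def __post_init__(self) -> None:
        assert self.n_in == self.n_retained + self.n_removed


def fit_qc_trend(qc_orders, qc_intensities, all_orders, span: float = 0.6,
                 feature_id: str = "", robust_iters: int = 3) -> TrendCurve:
    """Robust loess of QC intensity on injection order, interpolated everywhere.

    Outside the span of QC injection orders the nearest fitted value is held
    constant; fitted values are clipped to stay positive so division is safe.
    Raises :class:`TrendFitError` with fewer than four usable QC points.
    """
    qc_orders = np.asarray(qc_orders, dtype=float)
    qc_intensities = np.asarray(qc_intensities, dtype=float)
    ok = np.isfinite(qc_intensities) & (qc_intensities > 0)
    if ok.sum() < MIN_QC_POINTS:
        raise TrendFitError(
            f"feature {feature_id!r}: only {int(ok.sum())} usable QC points "
            f"(need >= {MIN_QC_POINTS})"
        )
    x, y = qc_orders[ok], qc_intensities[ok]
    fitted = lowess(y, x, frac=span, it=robust_iters, return_sorted=True)
    all_orders = np.asarray(all_orders, dtype=float)
    # np.interp holds endpoints constant outside the QC range
    values = np.interp(all_orders, fitted[:, 0], fitted[:, 1])
    floor = 1e-9 * float(np.median(y))
    values = np.maximum(values, floor)
    return TrendCurve(feature_id, all_orders.astype(int), values, span)


def qc_rlsc_correct(table: FeatureTable, span: float = 0.6,
                    reference: pd.Series | None = None):
    """Divide every feature by its QC-anchored drift trend and rescale.

    ``corrected = raw / trend * reference`` with the reference defaulting to
    the feature's median raw QC intensity, so corrected values keep the
    original scale.  Missing values stay missing.  Features whose trend
    cannot be fitted (fewer than four usable QC points) are dropped and
    returned with reasons.

    Returns ``(corrected_table, dropped)`` where ``dropped`` is a list of
    (feature_id, reason) pairs.
    """
    manifest = table.manifest
    qc_mask = manifest.is_qc()
    if not qc_mask.any():
        raise StageError("run contains no QC injections; QC-RLSC is impossible")
    orders = manifest.entries["injection_order"]
    qc_ids = manifest.entries.index[qc_mask]
    qc_orders = orders[qc_ids].to_numpy()
    all_orders = orders[table.intensities.columns].to_numpy()

    corrected = {}
    dropped = []
    for fid, row in table.intensities.iterrows():
        qc_vals = row[qc_ids].to_numpy(dtype=float)
        try:
            trend = fit_qc_trend(qc_orders, qc_vals, all_orders, span=span, feature_id=fid)
        except TrendFitError as exc:
            dropped.append((fid, str(exc)))
            continue
        ref = (
            float(reference[fid]) if reference is not None
            else float(np.nanmedian(np.where(qc_vals > 0, qc_vals, np.nan)))
        )
        corrected[fid] = row.to_numpy(dtype=float) / trend.values * ref
    if not corrected:
        raise StageError("no feature had enough QC observations for trend fitting")
    kept = [fid for fid in table.intensities.index if fid in corrected]
    out = FeatureTable(
        table.features.loc[kept].copy(),
        pd.DataFrame.from_dict(corrected, orient="index",
                               columns=table.intensities.columns).loc[kept],
        manifest,
    )
    return out, dropped


def qc_detection_and_rsd(table: FeatureTable, qc_from_injection: int = 8):
    """Per-feature QC detection fraction and RSD% in the assessment window.

    Detection means a non-missing, strictly positive peak area.  RSD uses the
    sample standard deviation over non-missing window-QC intensities.
    """
    manifest = table.manifest
    window = manifest.is_qc() & (manifest.entries["injection_order"] >= qc_from_injection)
    qc_ids = manifest.entries.index[window]
    if len(qc_ids) == 0:
        raise StageError(
            f"no QC injections at or after injection {qc_from_injection}"
        )
    qc = table.intensities[qc_ids]
    detected = qc.notna() & (qc > 0)
    frac = detected.sum(axis=1) / len(qc_ids)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    return frac, rsd


def qa_filter(table: FeatureTable, detection_threshold: float = 0.60,
              rsd_threshold: float = 20.0, qc_from_injection: int = 8):
    """Retain features detected in >60% of window QCs with QC RSD < 20%.

    Both inequalities are strict; everything else is removed.  Returns the
    filtered table and a :class:`QAReport`.
    """
    frac, rsd = qc_detection_and_rsd(table, qc_from_injection)
    passed = (frac > detection_threshold) & (rsd < rsd_threshold)
    passed &= rsd.notna()
    metrics = pd.DataFrame({
        "qc_detection_fraction": frac,
        "qc_rsd_percent": rsd,
        "passed": passed,
    })
    kept = metrics.index[metrics["passed"]]
    report = QAReport(metrics, n_in=len(metrics), n_retained=len(kept),
                      n_removed=len(metrics) - len(kept))
    return table.subset_features(kept), report


def qc_rsd_summary(table: FeatureTable, qc_from_injection: int = 8) -> pd.Series:
    """Median-ready per-feature QC RSD%, for before/after correction checks."""
    _, rsd = qc_detection_and_rsd(table, qc_from_injection)
    return rsd
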