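"""Per-sample LRR signal quality statistics and sample exclusion rules.

Two signal statistics are computed per sample:

* **DLRS** (derivative log ratio spread): a robust spread of successive
  within-chromosome LRR differences.  With ``d`` the pooled first
  differences (never spanning a chromosome boundary),

      DLRS = 1.4826 * median(|d - median(d)|) / sqrt(2)

  For i.i.d. Gaussian noise of standard deviation sigma this estimates
  sigma: differences have spread sigma*sqrt(2), and 1.4826*MAD is the
  consistent Gaussian scale estimate.  A plain-SD variant is available.

* **GCWF** (GC-wave factor): the least-squares slope of windowed median
  LRR on window mean GC content (centred), using non-overlapping 1 Mb
  windows.  A signal free of GC waves has GCWF near 0; the sign gives the
  wave direction.

Samples are excluded when array metadata (call rate, Dish QC) falls below
fixed thresholds or when DLRS / |GCWF| are robust outliers within the
cohort (above median + k*IQR, k = 3 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedStatisticError",
    "QCThresholds",
    "compute_dlrs",
    "compute_gcwf",
    "filter_samples",
    "qc_report",
]


class UndefinedStatisticError(ValueError):
    """Raised when a QC statistic is undefined for the given input."""


def _pooled_differences(series_per_chromosome) -> np.ndarray:
    if isinstance(series_per_chromosome, Mapping):
        chunks: Iterable = series_per_chromosome.values()
    elif isinstance(series_per_chromosome, np.ndarray) and series_per_chromosome.ndim == 1:
        chunks = [series_per_chromosome]
    else:
        chunks = series_per_chromosome
    diffs = [np.diff(np.asarray(chunk, dtype=float)) for chunk in chunks]
    diffs = [d for d in diffs if d.size]
    if not diffs:
        raise UndefinedStatisticError(
            "DLRS undefined: no chromosome has at least 2 markers"
        )
    return np.concatenate(diffs)


def compute_dlrs(series_per_chromosome, robust: bool = True) -> float:
    """Derivative log ratio spread of an LRR signal.

    ``series_per_chromosome`` is a mapping or sequence of per-chromosome
    LRR arrays (a single 1-D array is treated as one chromosome).
    Differences are taken within chromosomes only, so a level step at a
    chromosome boundary does not contribute.

    With ``robust=False`` the MAD-based spread is replaced by the plain
    standard deviation of the differences (divided by sqrt(2)).
    """
    d = _pooled_differences(series_per_chromosome)
    if robust:
        mad = float(np.median(np.abs(d - np.median(d))))
        return 1.4826 * mad / math.sqrt(2.0)
    return float(np.std(d, ddof=1)) / math.sqrt(2.0) if d.size > 1 else 0.0


def compute_gcwf(
    lrr: np.ndarray,
    gc: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray | None = None,
    window_size: int = 1_000_000,
) -> float:
    """GC-wave factor: slope of windowed median LRR on centred mean GC.

    Markers are binned into non-overlapping ``window_size``-bp windows per
    chromosome.  Each window contributes its median LRR and mean GC; GCWF
    is the ordinary-least-squares slope of median LRR on
    (mean GC - grand mean GC).

    Requires GC for at least 90% of markers and at least 3 usable windows.
    """
    lrr = np.asarray(lrr, dtype=float)
    gc = np.asarray(gc, dtype=float)
    positions = np.asarray(positions)
    if chroms is None:
        chroms = np.zeros(len(lrr), dtype=int)
    chroms = np.asarray(chroms)
    ok = np.isfinite(gc)
    if ok.mean() < 0.9:
        raise UndefinedStatisticError(
            f"GCWF undefined: GC available for only {ok.mean():.0%} of markers"
        )

    med_lrr: list[float] = []
    mean_gc: list[float] = []
    for chrom in pd.unique(chroms):
        mask = (chroms == chrom) & ok & np.isfinite(lrr)
        if not mask.any():
            continue
        win = positions[mask] // window_size
        frame = pd.DataFrame({"win": win, "lrr": lrr[mask], "gc": gc[mask]})
        grouped = frame.groupby("win")
        med_lrr.extend(grouped["lrr"].median())
        mean_gc.extend(grouped["gc"].mean())
    if len(med_lrr) < 3:
        raise UndefinedStatisticError(
            f"GCWF undefined: only {len(med_lrr)} usable windows (need >= 3)"
        )
    y = np.asarray(med_lrr)
    x = np.asarray(mean_gc)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    return float(np.dot(x, y - y.mean()) / denom)


@dataclass(frozen=True)
class QCThresholds:
    """Sample-exclusion thresholds.

    ``call_rate`` and ``dqc`` are hard minimums on array metadata.
    ``dlrs_fence`` / ``gcwf_fence`` are robust-outlier multipliers: a sample
    is excluded when DLRS (or |GCWF|) exceeds the cohort median plus
    fence * IQR of that statistic.
    """

    call_rate: float = 0.97
    dqc: float = 0.82
    dlrs_fence: float = 3.0
    gcwf_fence: float = 3.0


def _robust_upper_fence(values: pd.Series, fence: float) -> float:
    v = values.dropna()
    if v.empty:
        return math.inf
    q1, q3 = np.percentile(v, [25, 75])
    return float(np.median(v) + fence * (q3 - q1))


def filter_samples(
    records: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply exclusion rules; return retained sample ids and a full report.

    ``records`` must have columns ``sample, call_rate, dqc`` and may have
    ``dlrs`` and ``gcwf``.  The report adds boolean ``excluded`` and a
    semicolon-joined ``reason`` column.
    """
    thresholds = thresholds or QCThresholds()
    if records.empty:
        raise ValueError("cannot QC-filter an empty cohort")
    for col in ("sample", "call_rate", "dqc"):
        if col not in records.columns:
            raise ValueError(f"QC records missing required column {col!r}")
        if col != "sample" and records[col].isna().any():
            raise ValueError(f"QC records contain missing values in {col!r}")

    report = records.copy()
    reasons: list[list[str]] = [[] for _ in range(len(report))]
    cr = report["call_rate"].to_numpy(dtype=float)
    dq = report["dqc"].to_numpy(dtype=float)
    for i in np.flatnonzero(cr < thresholds.call_rate):
        reasons[i].append(f"call_rate<{thresholds.call_rate}")
    for i in np.flatnonzero(dq < thresholds.dqc):
        reasons[i].append(f"dqc<{thresholds.dqc}")

    if "dlrs" in report.columns and report["dlrs"].notna().any():
        fence = _robust_upper_fence(report["dlrs"], thresholds.dlrs_fence)
        for i in np.flatnonzero(report["dlrs"].to_numpy(dtype=float) > fence):
            reasons[i].append("high_dlrs")
    if "gcwf" in report.columns and report["gcwf"].notna().any():
        abs_gcwf = report["gcwf"].abs()
        fence = _robust_upper_fence(abs_gcwf, thresholds.gcwf_fence)
        for i in np.flatnonzero(abs_gcwf.to_numpy(dtype=float) > fence):
            reasons[i].append("high_gcwf")

    report["excluded"] = [bool(r) for r in reasons]
    report["reason"] = [";".join(r) for r in reasons]
    retained = report.loc[~report["excluded"], "sample"].tolist()
    return retained, report


def qc_report(
    marker_map: pd.DataFrame,
    lrr: pd.DataFrame,
    metadata: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    window_size: int = 1_000_000,
) -> tuple[list[str], pd.DataFrame]:
    """Compute DLRS/GCWF for every sample, merge metadata and filter.

    ``lrr`` is the markers x samples matrix aligned row-wise with
    ``marker_map``.  Returns ``(retained sample ids, report DataFrame)``.
    """
    chroms = marker_map["chrom"].to_numpy()
    positions = marker_map["pos"].to_numpy()
    gc = marker_map["gc"].to_numpy() if "gc" in marker_map.columns else None

    chrom_slices = [
        np.flatnonzero(chroms == c) for c in pd.unique(chroms)
    ]
    rows = []
    for sample in lrr.columns:
        values = lrr[sample].to_numpy(dtype=float)
        dlrs = compute_dlrs([values[idx] for idx in chrom_slices])
        if gc is not None:
            gcwf = compute_gcwf(values, gc, positions, chroms, window_size)
        else:
            gcwf = np.nan
        rows.append({"sample": sample, "dlrs": dlrs, "gcwf": gcwf})
    stats = pd.DataFrame(rows)
    merged = metadata.merge(stats, on="sample", how="left", validate="one_to_one")
    return filter_samples(merged, thresholds)
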