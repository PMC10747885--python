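"""Validation of image heights (IPH) against field measurements (FPH).

The field plant height (FPH) for a scan footprint is the maximum of the
manual stem measurements taken that day.  Residuals are ``FPH − IPH``;
accuracy is summarised by the population-form error metrics

    bias    = mean(IPH − FPH)
    RMSE    = sqrt( mean( (IPH − FPH)² ) )
    RMSE_B  = sqrt( mean( (IPH − FPH − bias)² ) )

which satisfy the exact decomposition ``RMSE² = RMSE_B² + bias²``
(RMSE_B is the population standard deviation of the residuals).  The
coefficient of determination is the squared Pearson correlation of IPH
vs FPH.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import PhenoroofError
from .height import HeightSummary

__all__ = [
    "ValidationRecord",
    "ValidationSummary",
    "ValidationReport",
    "rmse",
    "rmse_bias_adjusted",
    "r_squared",
    "match_field_log",
    "validate_run",
]


class DegenerateValidationError(PhenoroofError):
    """Constant FPH (or too few pairs): correlation undefined."""


@dataclass(frozen=True)
class ValidationRecord:
    scan_time: pd.Timestamp
    crop: Optional[str]
    fph_cm: float
    iph_cm: float

    @property
    def residual_cm(self) -> float:
        """FPH − IPH."""
        return self.fph_cm - self.iph_cm


@dataclass(frozen=True)
class ValidationSummary:
    n: int
    bias_cm: float
    rmse_cm: float
    rmse_b_cm: float
    r_squared: Optional[float]


def _as_arrays(pairs) -> Tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("empty pair list")
    return arr[:, 0], arr[:, 1]


def rmse(pairs: Sequence[Tuple[float, float]]) -> float:
    """Root mean squared error of (IPH, FPH) pairs, divide-by-n form."""
    iph, fph = _as_arrays(pairs)
    return float(np.sqrt(np.mean((iph - fph) ** 2)))


def rmse_bias_adjusted(pairs: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """(bias, RMSE_B): mean residual and the bias-adjusted RMSE.

    RMSE_B equals the population standard deviation of ``IPH − FPH``.
    """
    iph, fph = _as_arrays(pairs)
    resid = iph - fph
    bias = float(resid.mean())
    rmse_b = float(np.sqrt(np.mean((resid - bias) ** 2)))
    return bias, rmse_b


def r_squared(pairs: Sequence[Tuple[float, float]]) -> float:
    """Squared Pearson correlation of IPH vs FPH."""
    iph, fph = _as_arrays(pairs)
    if iph.size < 2:
        raise DegenerateValidationError("need at least 2 pairs for R²")
    if np.ptp(fph) == 0 or np.ptp(iph) == 0:
        raise DegenerateValidationError("constant axis: correlation undefined")
    r = np.corrcoef(iph, fph)[0, 1]
    return float(r * r)


def match_field_log(
    summaries: Sequence[HeightSummary],
    field_log: pd.DataFrame,
    max_gap_days: int = 2,
) -> Tuple[List[Tuple[HeightSummary, pd.Series]], List[HeightSummary]]:
    """Pair each scan summary with its field-log row.

    Matching is by crop label and calendar date, with a nearest-day
    fallback up to ``max_gap_days`` (weekly campaigns drift by a day or
    two).  Returns (matched, unmatched); unmatched scans are surfaced,
    never silently dropped.

    ``field_log`` columns: ``date``, ``crop``, ``fph_cm``.
    """
    log = field_log.copy()
    log["date"] = pd.to_datetime(log["date"])
    matched, unmatched = [], []
    for s in summaries:
        cand = log if s.label is None else log[log["crop"] == s.label]
        if len(cand) == 0:
            unmatched.append(s)
            continue
        gaps = (cand["date"] - pd.Timestamp(s.scan_time).normalize()).abs()
        i = gaps.idxmin()
        if gaps.loc[i] <= pd.Timedelta(days=max_gap_days):
            matched.append((s, log.loc[i]))
        else:
            unmatched.append(s)
    return matched, unmatched


@dataclass
class ValidationReport:
    """Crop × (percentile × metric) error table plus bookkeeping."""

    table: pd.DataFrame  # index: crop; columns: MultiIndex (percentile, metric)
    records: Dict[int, List[ValidationRecord]]
    unmatched: List[HeightSummary]
    summaries: Dict[Tuple[str, int], ValidationSummary]

    def to_csv(self, path) -> None:
        flat = self.table.copy()
        flat.columns = [f"p{p}_{m}" for p, m in flat.columns]
        flat.to_csv(path, float_format="%.6f")


def validate_run(
    summaries: Sequence[HeightSummary],
    field_log: pd.DataFrame,
    percentiles: Sequence[int] = (98, 99, 100),
    max_gap_days: int = 2,
) -> ValidationReport:
    """Error report shaped like a crop-wise accuracy table.

    Rows are crops, columns are percentile × {bias, rmse, rmse_b}
    (plus R² where the crop has ≥ 2 scans with varying FPH).
    """
    matched, unmatched = match_field_log(summaries, field_log, max_gap_days)
    records: Dict[int, List[ValidationRecord]] = {p: [] for p in percentiles}
    for s, row in matched:
        for p in percentiles:
            if p not in s.percentiles:
                raise KeyError(f"summary lacks percentile {p}")
            records[p].append(ValidationRecord(
                scan_time=s.scan_time, crop=s.label,
                fph_cm=float(row["fph_cm"]), iph_cm=s.percentiles[p],
            ))
    crops = sorted({r.crop or "all" for p in percentiles for r in records[p]})
    cols = pd.MultiIndex.from_product([percentiles, ["bias", "rmse", "rmse_b", "r2"]])
    table = pd.DataFrame(index=crops, columns=cols, dtype=float)
    cellsums: Dict[Tuple[str, int], ValidationSummary] = {}
    for p in percentiles:
        by_crop: Dict[str, list] = {}
        for r in records[p]:
            by_crop.setdefault(r.crop or "all", []).append(r)
        for crop, recs in by_crop.items():
            pairs = [(r.iph_cm, r.fph_cm) for r in recs]
            bias, rb = rmse_bias_adjusted(pairs)
            rm = rmse(pairs)
            try:
                r2 = r_squared(pairs)
            except DegenerateValidationError:
                r2 = np.nan
            table.loc[crop, (p, "bias")] = bias
            table.loc[crop, (p, "rmse")] = rm
            table.loc[crop, (p, "rmse_b")] = rb
            table.loc[crop, (p, "r2")] = r2
            cellsums[(crop, p)] = ValidationSummary(
                n=len(recs), bias_cm=bias, rmse_cm=rm, rmse_b_cm=rb,
                r_squared=None if np.isnan(r2) else r2,
            )
    return ValidationReport(table=table, records=records,
                            unmatched=list(unmatched), summaries=cellsums)
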