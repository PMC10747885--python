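"""Crop-wise rooftop thermal analytics.

A vegetated (productive) roof is compared against a bare concrete
control through temperature loggers above each plant bed (15 cm and
60 cm above soil, 15-min cadence), a probe in the substrate (10-min
cadence) and a meteorological station.  The analytics are:

* daily means — calendar-day (local midnight-to-midnight) averages, a
  day counting only when enough of its expected readings arrived;
* diurnal profiles — the 24 mean-hourly values over a month;
* cooling effect — per-day ``control mean − crop mean``; positive means
  the planted bed ran cooler than the concrete;
* substrate attenuation — per-day ``15 cm air mean − substrate mean``;
  positive means the substrate stayed cooler than the air just above it
  (negative days, e.g. dry-soil events, are retained and reported);
* monthly climate table — mean of daily means / max / min per variable.

Series of different cadences are never resampled onto a common grid:
each is aggregated on its own timestamps, so no readings are invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import PhenoroofError

__all__ = [
    "SensorSeries",
    "DailyMeans",
    "DiurnalProfile",
    "CoolingSummary",
    "daily_means",
    "diurnal_profile",
    "cooling_effect",
    "diurnal_cooling",
    "substrate_attenuation",
    "climate_table",
]

ROLES = ("crop-15cm", "crop-60cm", "substrate", "control", "met")


class NoOverlapError(PhenoroofError):
    """Two series share no (complete) days or no month overlap."""


@dataclass
class SensorSeries:
    """Timestamped readings from one logical station.

    ``values`` is a float Series with a strictly increasing
    DatetimeIndex; ``extra`` may carry companion columns (humidity,
    moisture) on the same index.
    """

    station: str
    role: str
    values: pd.Series
    crop: Optional[str] = None
    variable: str = "temperature"
    extra: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PhenoroofError(f"unknown role {self.role!r}; expected one of {ROLES}")
        v = self.values
        if not isinstance(v.index, pd.DatetimeIndex):
            raise PhenoroofError("values must be indexed by timestamps")
        if len(v) and not v.index.is_monotonic_increasing:
            raise PhenoroofError("timestamps must be increasing")
        if len(v) and v.index.has_duplicates:
            raise PhenoroofError("duplicate timestamps")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise PhenoroofError("non-finite sensor values")

    def cadence_minutes(self) -> float:
        """Modal step between consecutive readings, in minutes."""
        if len(self.values) < 2:
            raise PhenoroofError("cannot infer cadence from < 2 readings")
        steps = self.values.index.to_series().diff().dropna()
        return steps.mode().iloc[0].total_seconds() / 60.0


@dataclass
class DailyMeans:
    """Complete-day means plus the days excluded as incomplete."""

    means: pd.Series           # index: date (Timestamp, midnight)
    counts: pd.Series
    expected_per_day: int
    excluded_days: List[pd.Timestamp]


def daily_means(series: SensorSeries, completeness_min: float = 0.8) -> DailyMeans:
    """Calendar-day averages of a series.

    A day is kept when it holds at least ``completeness_min`` of the
    readings its cadence implies for 24 h; incomplete days (gaps,
    partial first/last days) are excluded and reported.
    """
    if len(series.values) == 0:
        raise PhenoroofError("empty series")
    cadence = series.cadence_minutes()
    expected = int(round(24 * 60 / cadence))
    grouped = series.values.groupby(series.values.index.normalize())
    means = grouped.mean()
    counts = grouped.size()
    complete = counts >= completeness_min * expected
    excluded = list(counts.index[~complete])
    return DailyMeans(
        means=means[complete], counts=counts[complete],
        expected_per_day=expected, excluded_days=excluded,
    )


@dataclass
class DiurnalProfile:
    """Mean-hourly temperatures of one station over one month."""

    month: pd.Period
    station: str
    hourly_mean: np.ndarray     # 24 values, NaN where no data
    hourly_n: np.ndarray        # 24 counts

    @property
    def peak_hour(self) -> int:
        return int(np.nanargmax(self.hourly_mean))


def _month_slice(series: SensorSeries, month) -> pd.Series:
    period = pd.Period(month, freq="M")
    idx = series.values.index
    sel = series.values[(idx.year == period.year) & (idx.month == period.month)]
    if len(sel) == 0:
        raise NoOverlapError(f"{series.station} has no data in {period}")
    return sel


def diurnal_profile(series: SensorSeries, month) -> DiurnalProfile:
    """24 mean-hourly values over all the month's days.

    Hour ``h`` aggregates every reading whose local clock hour is ``h``;
    hours with no readings are NaN with count 0.
    """
    sel = _month_slice(series, month)
    mean = np.full(24, np.nan)
    n = np.zeros(24, dtype=int)
    g = sel.groupby(sel.index.hour)
    mean[g.mean().index] = g.mean().to_numpy()
    n[g.size().index] = g.size().to_numpy()
    return DiurnalProfile(month=pd.Period(month, freq="M"),
                          station=series.station, hourly_mean=mean, hourly_n=n)


@dataclass
class CoolingSummary:
    """Distribution of per-day temperature differences (°C).

    Box-whisker statistics follow the Tukey convention: quartiles by
    linear interpolation, whiskers at the most extreme values within
    1.5×IQR of the quartiles, points beyond listed as outliers.
    """

    crop: Optional[str]
    level: str
    daily_deltas: pd.Series
    mean: float
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    max: float
    outliers: np.ndarray
    n_days: int

    @classmethod
    def from_deltas(cls, deltas: pd.Series, crop=None, level="15cm") -> "CoolingSummary":
        x = deltas.to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
        outliers = x[(x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)]
        return cls(
            crop=crop, level=level, daily_deltas=deltas,
            mean=float(x.mean()), median=float(med),
            q1=float(q1), q3=float(q3),
            whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
            max=float(x.max()), outliers=outliers, n_days=len(x),
        )

    def row(self) -> dict:
        return {"crop": self.crop, "level": self.level, "n_days": self.n_days,
                "mean_C": self.mean, "median_C": self.median,
                "q1_C": self.q1, "q3_C": self.q3,
                "whisker_lo_C": self.whisker_lo, "whisker_hi_C": self.whisker_hi,
                "max_C": self.max, "n_outliers": len(self.outliers)}


def _shared_daily_deltas(a: SensorSeries, b: SensorSeries,
                         completeness_min: float) -> pd.Series:
    """Per-day ``a − b`` over days complete in both series."""
    da = daily_means(a, completeness_min).means
    db = daily_means(b, completeness_min).means
    shared = da.index.intersection(db.index)
    if len(shared) == 0:
        raise NoOverlapError(
            f"{a.station} and {b.station} share no complete days")
    return (da[shared] - db[shared]).rename("delta_C")


def cooling_effect(control: SensorSeries, crop: SensorSeries,
                   completeness_min: float = 0.8) -> CoolingSummary:
    """Mean daily cooling of a planted bed vs the concrete control.

    Per-day delta = control daily mean − crop daily mean, over days both
    stations recorded completely.  Positive deltas mean cooling.
    """
    deltas = _shared_daily_deltas(control, crop, completeness_min)
    level = crop.role.replace("crop-", "") if crop.role.startswith("crop-") else crop.role
    return CoolingSummary.from_deltas(deltas, crop=crop.crop or crop.station,
                                      level=level)


def diurnal_cooling(control: SensorSeries, crop: SensorSeries, month) -> pd.Series:
    """Hour-wise cooling profile for one month.

    Control's diurnal profile minus the crop's; the index hour of the
    maximum is the peak-cooling hour statistic.
    """
    pc = diurnal_profile(control, month)
    pp = diurnal_profile(crop, month)
    return pd.Series(pc.hourly_mean - pp.hourly_mean,
                     index=pd.RangeIndex(24, name="hour"), name="cooling_C")


def substrate_attenuation(substrate: SensorSeries, canopy15: SensorSeries,
                          completeness_min: float = 0.8) -> CoolingSummary:
    """Mean daily temperature drop in the substrate vs 15 cm air.

    Per-day delta = 15 cm air daily mean − substrate daily mean;
    positive means further cooling below the plant layer.  Days where
    the substrate ran warmer (dry-soil events) come out negative and are
    retained.
    """
    deltas = _shared_daily_deltas(canopy15, substrate, completeness_min)
    return CoolingSummary.from_deltas(
        deltas, crop=substrate.crop or substrate.station, level="substrate")


def climate_table(met: Iterable[SensorSeries],
                  completeness_min: float = 0.8) -> pd.DataFrame:
    """Monthly climate summary across meteorological variables.

    For each month × variable: the mean of daily means plus the raw
    maximum and minimum readings.  Months with no complete days for a
    variable are omitted.  Result index: (month, variable).
    """
    rows = []
    for s in met:
        dm = daily_means(s, completeness_min)
        if len(dm.means) == 0:
            continue
        by_month = dm.means.groupby(dm.means.index.to_period("M"))
        raw_by_month = s.values.groupby(s.values.index.to_period("M"))
        for month, mean_of_daily in by_month.mean().items():
            raw = raw_by_month.get_group(month)
            rows.append({"month": month, "variable": s.variable,
                         "mean": float(mean_of_daily),
                         "max": float(raw.max()), "min": float(raw.min())})
    if not rows:
        raise PhenoroofError("no complete data for any month/variable")
    df = pd.DataFrame(rows).set_index(["month", "variable"]).sort_index()
    return df
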