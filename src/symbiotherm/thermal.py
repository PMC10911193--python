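"""Temperature-logger summaries and experimental degree heating weeks (eDHW).

Seawater temperature loggers record every 15–120 s per container. Analyses
operate on 24 h (calendar-day) means: treatment comparisons, the
container-vs-bath offset correction, and the accumulated thermal dose.

eDHW follows the degree-heating-week convention adapted to a tank
experiment: sum |daily mean − MMM| over all days whose daily mean exceeds
MMM + 1 °C, then divide the accumulated °C-days by 7 to express the dose in
°C-weeks. The mean monthly maximum (MMM) baseline is the pre-experiment
holding temperature (25 °C by default).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "DailySummary",
    "HeatExposure",
    "daily_means",
    "apply_container_offset",
    "compute_edhw",
    "read_logger_csv",
    "write_exposure_table",
]

TEMP_BOUNDS_C = (10.0, 45.0)


@dataclass(frozen=True)
class TemperatureSeries:
    """One logger's timestamped seawater temperatures.

    ``timestamps`` are timezone-naive instants in the logger's local clock,
    strictly increasing; ``temps_c`` are finite °C readings within the
    plausible seawater range.
    """

    logger_id: str
    treatment: str
    timestamps: pd.DatetimeIndex
    temps_c: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        temps = np.asarray(self.temps_c, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "temps_c", temps)
        if len(ts) == 0:
            raise ValueError("temperature series must contain at least one reading")
        if len(ts) != len(temps):
            raise ValueError("timestamps and temps_c lengths differ")
        if len(ts) > 1 and not (np.diff(ts.asi8) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if not np.isfinite(temps).all():
            raise ValueError("temperatures must be finite")
        lo, hi = TEMP_BOUNDS_C
        if (temps < lo).any() or (temps > hi).any():
            raise ValueError(f"temperatures outside plausible range [{lo}, {hi}] °C")

    def __len__(self) -> int:
        return len(self.temps_c)


@dataclass(frozen=True)
class DailySummary:
    """24 h summary of one calendar day of logger readings."""

    date: _dt.date
    mean_c: float
    min_c: float
    max_c: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        if not (self.min_c <= self.mean_c <= self.max_c):
            raise ValueError("require min_c <= mean_c <= max_c")


@dataclass(frozen=True)
class HeatExposure:
    """Accumulated thermal dose for one treatment."""

    treatment: str
    edhw_c_week: float
    mmm_c: float
    threshold_c: float
    hot_days: int

    def __post_init__(self) -> None:
        if self.edhw_c_week < 0:
            raise ValueError("eDHW cannot be negative")
        if (self.edhw_c_week == 0) != (self.hot_days == 0):
            raise ValueError("eDHW is zero exactly when no day exceeded the threshold")


def daily_means(series: TemperatureSeries) -> list[DailySummary]:
    """Summarize a logger series into per-calendar-day means.

    Every reading whose timestamp falls within a calendar day (logger local
    clock) contributes to that day's arithmetic mean; partial first/last
    days are included, with ``n_obs`` recording coverage.
    """
    df = pd.DataFrame({"temp": series.temps_c}, index=series.timestamps)
    grouped = df.groupby(df.index.date)["temp"]
    out = []
    for day, g in grouped:
        lo, hi = float(g.min()), float(g.max())
        # clamp: summation rounding can push the mean of a constant day
        # one ulp outside [min, max]
        mean = min(max(float(g.mean()), lo), hi)
        out.append(
            DailySummary(date=day, mean_c=mean, min_c=lo, max_c=hi, n_obs=int(g.size))
        )
    out.sort(key=lambda s: s.date)
    return out


def apply_container_offset(
    tank: TemperatureSeries,
    paired: Sequence[tuple[float, float]],
) -> TemperatureSeries:
    """Correct a bath (tank) logger series to container temperature.

    ``paired`` holds simultaneous (tank, container) spot measurements; the
    pooled mean difference ``mean(t_tank − t_container)`` is subtracted from
    every reading. The applied offset is stored in the output metadata.
    """
    if len(paired) == 0:
        raise ValueError("need at least one paired (tank, container) measurement")
    pairs = np.asarray(paired, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired must be a sequence of (t_tank, t_container) tuples")
    offset = float(np.mean(pairs[:, 0] - pairs[:, 1]))
    meta = dict(tank.meta)
    meta["container_offset_c"] = offset
    meta["n_offset_pairs"] = int(len(pairs))
    return TemperatureSeries(
        logger_id=tank.logger_id,
        treatment=tank.treatment,
        timestamps=tank.timestamps,
        temps_c=tank.temps_c - offset,
        meta=meta,
    )


def compute_edhw(
    daily: Sequence[DailySummary],
    mmm_c: float = 25.0,
    threshold_c: float = 26.0,
    days_per_week: float = 7.0,
    treatment: str = "",
) -> HeatExposure:
    """Accumulate experimental degree heating weeks over daily summaries.

    Days whose 24 h mean strictly exceeds ``threshold_c`` contribute
    |mean − mmm_c| °C-days; the total is divided by ``days_per_week`` to
    give °C-weeks. By default the threshold sits 1 °C above the MMM
    baseline, the standard bleaching-stress accumulation rule.
    """
    if len(daily) == 0:
        raise ValueError("daily summaries must be non-empty")
    if threshold_c < mmm_c:
        raise ValueError("threshold_c must be >= mmm_c")
    # sequential accumulation in day order (day counts are tiny)
    accum_c_days = 0.0
    hot_count = 0
    for d in daily:
        if d.mean_c > threshold_c:
            accum_c_days += abs(d.mean_c - mmm_c)
            hot_count += 1
    return HeatExposure(
        treatment=treatment,
        edhw_c_week=accum_c_days / days_per_week,
        mmm_c=mmm_c,
        threshold_c=threshold_c,
        hot_days=hot_count,
    )


def read_logger_csv(path, logger_id_col: str = "logger_id") -> list[TemperatureSeries]:
    """Read a logger CSV export into one series per (logger, treatment).

    Expected columns: ``timestamp`` (ISO-8601), ``temperature`` (°C),
    ``logger_id``; a ``treatment`` column is used when present. Extra
    columns are ignored.
    """
    df = pd.read_csv(path)
    required = {"timestamp", "temperature", logger_id_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"logger CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    has_treatment = "treatment" in df.columns
    series = []
    for logger, g in df.groupby(logger_id_col, sort=True):
        g = g.sort_values("timestamp")
        treatment = str(g["treatment"].iloc[0]) if has_treatment else ""
        series.append(
            TemperatureSeries(
                logger_id=str(logger),
                treatment=treatment,
                timestamps=pd.DatetimeIndex(g["timestamp"]),
                temps_c=g["temperature"].to_numpy(dtype=float),
            )
        )
    return series


def write_exposure_table(path, exposures: Iterable[HeatExposure], daily_by_treatment=None) -> pd.DataFrame:
    """Write the per-treatment exposure table as CSV and return it.

    ``daily_by_treatment`` optionally maps treatment label to its
    DailySummary list, used to fill the overall mean and the maximum daily
    mean columns.
    """
    rows = []
    for exp in exposures:
        mean_c = max_daily = np.nan
        if daily_by_treatment and exp.treatment in daily_by_treatment:
            means = [d.mean_c for d in daily_by_treatment[exp.treatment]]
            mean_c = float(np.mean(means))
            max_daily = float(np.max(means))
        rows.append(
            {
                "treatment": exp.treatment,
                "mean_c": mean_c,
                "max_daily_mean_c": max_daily,
                "edhw_c_week": exp.edhw_c_week,
                "hot_days": exp.hot_days,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(path, index=False)
    return table
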