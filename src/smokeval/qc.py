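"""Monitor quality control: hourly PM2.5 to midnight-to-midnight daily means.

An hourly value is invalidated when the sampler filter pressure exceeds 60%
(overloaded filter). A civil date's 24-hour average is set to missing when at
least 6 of the 24 hourly values are missing in total, or at least 3 are
missing consecutively; hours absent from the input count as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DailyValue",
    "apply_pressure_filter",
    "daily_average",
    "daily_averages",
    "PRESSURE_THRESHOLD_PCT",
    "TOTAL_MISSING_MAX",
    "CONSECUTIVE_MISSING_MAX",
]

PRESSURE_THRESHOLD_PCT = 60.0
#: a day fails when missing hours >= TOTAL_MISSING_MAX
TOTAL_MISSING_MAX = 6
#: a day fails when the longest missing run >= CONSECUTIVE_MISSING_MAX
CONSECUTIVE_MISSING_MAX = 3

MISSING_REASONS = ("none", "total_missing", "consecutive_missing",
                   "insufficient_hours")


@dataclass(frozen=True)
class DailyValue:
    """QC'd daily mean for one monitor-date."""

    monitor_id: str
    date: object
    value: float | None
    n_valid_hours: int
    missing_reason: str

    def __post_init__(self) -> None:
        if self.missing_reason not in MISSING_REASONS:
            raise ValueError(f"unknown missing_reason {self.missing_reason!r}")
        if (self.value is None) == (self.missing_reason == "none"):
            raise ValueError("value must be present exactly when reason is 'none'")
        if not (0 <= self.n_valid_hours <= 24):
            raise ValueError("n_valid_hours must lie in [0, 24]")


def apply_pressure_filter(
    records: pd.DataFrame, threshold_pct: float = PRESSURE_THRESHOLD_PCT
) -> pd.DataFrame:
    """Invalidate hourly PM2.5 where filter pressure strictly exceeds the threshold.

    Parameters
    ----------
    records : DataFrame
        Columns monitor_id, timestamp, pm25, and optionally
        filter_pressure_pct. Other columns pass through unchanged.

    Returns
    -------
    DataFrame
        Copy with pm25 set to NaN wherever filter_pressure_pct > threshold.
        A missing pressure channel leaves the series unchanged (with a warning).
    """
    out = records.copy()
    if "filter_pressure_pct" not in out.columns:
        logger.warning("no filter_pressure_pct channel; pressure filter skipped")
        return out
    mask = out["filter_pressure_pct"] > threshold_pct  # NaN pressure -> False
    n = int(mask.sum())
    if n:
        out.loc[mask, "pm25"] = np.nan
        logger.info("pressure filter invalidated %d hourly values", n)
    return out


def _max_missing_run(missing: np.ndarray) -> int:
    """Length of the longest run of True in a boolean vector."""
    best = run = 0
    for m in missing:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def daily_average(
    values_by_hour: "pd.Series | np.ndarray",
    monitor_id: str = "",
    date: object = None,
    total_missing_max: int = TOTAL_MISSING_MAX,
    consecutive_missing_max: int = CONSECUTIVE_MISSING_MAX,
) -> DailyValue:
    """Compute one monitor-date's QC'd daily mean from its 24 hourly values.

    Parameters
    ----------
    values_by_hour : array-like of length 24
        PM2.5 for civil hours 0..23; NaN marks a missing hour. Shorter input
        is allowed only as a 24-length array; callers with sparse records
        should use :func:`daily_averages`.
    """
    v = np.asarray(values_by_hour, dtype=float)
    if v.shape != (24,):
        raise ValueError("daily_average expects exactly 24 hourly slots")
    missing = np.isnan(v)
    n_missing = int(missing.sum())
    n_valid = 24 - n_missing
    if n_valid == 0:
        return DailyValue(monitor_id, date, None, 0, "total_missing")
    if n_missing >= total_missing_max:
        return DailyValue(monitor_id, date, None, n_valid, "total_missing")
    if _max_missing_run(missing) >= consecutive_missing_max:
        return DailyValue(monitor_id, date, None, n_valid, "consecutive_missing")
    return DailyValue(monitor_id, date, float(np.nanmean(v)), n_valid, "none")


def daily_averages(
    records: pd.DataFrame,
    total_missing_max: int = TOTAL_MISSING_MAX,
    consecutive_missing_max: int = CONSECUTIVE_MISSING_MAX,
) -> pd.DataFrame:
    """QC'd daily means for every monitor-date present in an hourly table.

    Parameters
    ----------
    records : DataFrame
        Columns monitor_id, timestamp (datetime-like), pm25. Apply
        :func:`apply_pressure_filter` beforehand if a pressure channel exists.

    Returns
    -------
    DataFrame with columns monitor_id, date, value, n_valid_hours,
    missing_reason — one row per monitor-date appearing in the input.

    Raises
    ------
    ValueError
        On duplicate (monitor_id, timestamp) pairs: data-integrity error.
    """
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if df.duplicated(subset=["monitor_id", "timestamp"]).any():
        raise ValueError("duplicate (monitor_id, timestamp) records")
    df["date"] = df["timestamp"].dt.date
    df["hour"] = df["timestamp"].dt.hour

    rows = []
    for (mon, date), grp in df.groupby(["monitor_id", "date"], sort=True):
        slots = np.full(24, np.nan)
        slots[grp["hour"].to_numpy()] = grp["pm25"].to_numpy()
        dv = daily_average(slots, monitor_id=mon, date=date,
                           total_missing_max=total_missing_max,
                           consecutive_missing_max=consecutive_missing_max)
        rows.append((mon, date, np.nan if dv.value is None else dv.value,
                     dv.n_valid_hours, dv.missing_reason))
    out = pd.DataFrame(
        rows, columns=["monitor_id", "date", "value", "n_valid_hours",
                       "missing_reason"]
    )
    n_bad = int((out["missing_reason"] != "none").sum())
    if n_bad:
        logger.info("daily QC set %d of %d monitor-days to missing", n_bad, len(out))
    return out
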