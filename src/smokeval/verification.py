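"""Forecast-observation agreement statistics.

Continuous agreement between forecast and monitor PM2.5 is summarised by
Willmott's index of agreement (IOA), Pearson's r, normalized RMSE and
fractional bias, computed globally, per day across locations ("spatial") or
per location across days ("temporal"). Plume agreement is the figure of merit
in space (FMS): intersection area over union area of two plume sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .datatypes import PlumeSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalStats", "EvalSummary", "ioa", "pearson_r", "nrmse",
    "fractional_bias", "evaluate", "bland_altman", "fms",
]


def _as_pair(observed, forecast) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(forecast, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and forecast must be 1-D arrays of equal length")
    if o.size == 0:
        raise ValueError("empty input")
    if np.isnan(o).any() or np.isnan(p).any():
        raise ValueError("inputs must not contain NaN; pair the series first")
    return o, p


def ioa(observed, forecast) -> float:
    """Willmott's index of agreement d in [0, 1] (1 = perfect match).

    d = 1 - sum (O_i - P_i)^2 / sum (|P_i - Obar| + |O_i - Obar|)^2.
    A zero denominator (all values identical) returns 1.
    """
    o, p = _as_pair(observed, forecast)
    obar = o.mean()
    num = float(np.sum((o - p) ** 2))
    den = float(np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2))
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def pearson_r(observed, forecast) -> float:
    """Pearson product-moment correlation; NaN (with warning) if degenerate."""
    o, p = _as_pair(observed, forecast)
    if o.size < 2:
        raise ValueError("pearson_r requires at least 2 pairs")
    if np.std(o) == 0.0 or np.std(p) == 0.0:
        logger.warning("pearson_r: zero variance in a series; returning NaN")
        return math.nan
    return float(_st.pearsonr(o, p).statistic)


def nrmse(observed, forecast, normalizer: str = "range") -> float:
    """Normalized RMSE in percent: 100 * RMSE / N.

    N is the observed range (default), mean, or standard deviation.
    """
    o, p = _as_pair(observed, forecast)
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))
    if normalizer == "range":
        n = float(o.max() - o.min())
    elif normalizer == "mean":
        n = float(o.mean())
    elif normalizer == "sd":
        n = float(o.std(ddof=0))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if n == 0.0:
        logger.warning("nrmse: zero %s normalizer; returning NaN", normalizer)
        return math.nan
    return 100.0 * rmse / n


def fractional_bias(observed, forecast) -> float:
    """FB = (Obar - Pbar) / ((Obar + Pbar)/2); negative = overprediction.

    Bounded in [-2, 2] for non-negative data; NaN when both means are zero.
    """
    o, p = _as_pair(observed, forecast)
    obar, pbar = float(o.mean()), float(p.mean())
    if obar + pbar == 0.0:
        logger.warning("fractional_bias: both means zero; returning NaN")
        return math.nan
    return (obar - pbar) / ((obar + pbar) / 2.0)


@dataclass(frozen=True)
class EvalStats:
    """Agreement statistics for one slice of paired data."""

    ioa: float
    pearson_r: float
    nrmse: float  # percent
    fb: float
    n_pairs: int


@dataclass
class EvalSummary:
    """Global statistics, or per-slice statistics with mean and range."""

    mode: str  # "global", "spatial" or "temporal"
    global_stats: EvalStats | None
    slices: pd.DataFrame | None  # slice_id, ioa, pearson_r, nrmse, fb, n_pairs
    normalizer: str = "range"

    def mean_and_range(self) -> dict[str, tuple[float, float, float]]:
        """Per statistic: (mean over slices, min, max), NaN slices excluded."""
        if self.slices is None or self.slices.empty:
            return {}
        out = {}
        for col in ("ioa", "pearson_r", "nrmse", "fb"):
            v = self.slices[col].dropna()
            if v.empty:
                out[col] = (math.nan, math.nan, math.nan)
            else:
                out[col] = (float(v.mean()), float(v.min()), float(v.max()))
        return out


def _slice_stats(o: np.ndarray, p: np.ndarray, normalizer: str) -> EvalStats:
    return EvalStats(
        ioa=ioa(o, p),
        pearson_r=pearson_r(o, p) if o.size >= 2 and np.std(o) > 0 and np.std(p) > 0
        else math.nan,
        nrmse=nrmse(o, p, normalizer),
        fb=fractional_bias(o, p),
        n_pairs=int(o.size),
    )


def evaluate(pairs: pd.DataFrame, mode: str = "global",
             normalizer: str = "range") -> EvalSummary:
    """Agreement statistics over a paired series.

    Parameters
    ----------
    pairs : DataFrame
        Columns location_id, day, observed, forecast; one row per pair, no
        missing values (pair the series with complete cases first).
    mode : {"global", "spatial", "temporal"}
        global pools every pair; spatial slices by day (across locations);
        temporal slices by location (across days). Slices with fewer than 2
        pairs are skipped with a log entry.
    """
    required = {"location_id", "day", "observed", "forecast"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs must have columns {sorted(required)}")
    if pairs.duplicated(subset=["location_id", "day"]).any():
        raise ValueError("duplicate (location_id, day) pairs")
    df = pairs.dropna(subset=["observed", "forecast"])
    if df.empty:
        raise ValueError("no valid pairs")

    if mode == "global":
        st = _slice_stats(df["observed"].to_numpy(), df["forecast"].to_numpy(),
                          normalizer)
        return EvalSummary(mode=mode, global_stats=st, slices=None,
                           normalizer=normalizer)
    if mode == "spatial":
        key = "day"
    elif mode == "temporal":
        key = "location_id"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows, skipped = [], 0
    for sid, grp in df.groupby(key, sort=True):
        if len(grp) < 2:
            skipped += 1
            continue
        st = _slice_stats(grp["observed"].to_numpy(),
                          grp["forecast"].to_numpy(), normalizer)
        rows.append((sid, st.ioa, st.pearson_r, st.nrmse, st.fb, st.n_pairs))
    if skipped:
        logger.info("evaluate(%s): skipped %d slices with < 2 pairs", mode, skipped)
    if not rows:
        raise ValueError(f"no {mode} slice with >= 2 pairs")
    slices = pd.DataFrame(
        rows, columns=["slice_id", "ioa", "pearson_r", "nrmse", "fb", "n_pairs"]
    )
    return EvalSummary(mode=mode, global_stats=None, slices=slices,
                       normalizer=normalizer)


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman summary; differences are forecast - observed, so points
    above zero are overpredictions."""

    means: np.ndarray
    differences: np.ndarray
    bias: float
    limits: tuple[float, float]  # bias -/+ 2 SD of differences


def bland_altman(pairs: pd.DataFrame) -> BlandAltman:
    """Bland-Altman agreement summary, excluding pairs with zero forecast."""
    df = pairs.dropna(subset=["observed", "forecast"])
    df = df[df["forecast"] > 0.0]
    if len(df) < 2:
        raise ValueError("bland_altman requires >= 2 pairs with positive forecast")
    o = df["observed"].to_numpy(dtype=float)
    p = df["forecast"].to_numpy(dtype=float)
    diff = p - o
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return BlandAltman(means=(o + p) / 2.0, differences=diff, bias=bias,
                       limits=(bias - 2.0 * sd, bias + 2.0 * sd))


def fms(plume_a: PlumeSet, plume_b: PlumeSet) -> float:
    """Figure of merit in space: area(A intersect B) / area(A union B).

    Returned as a fraction in [0, 1]. Both sets empty -> NaN (no plumes to
    compare); exactly one empty -> 0.
    """
    if plume_a.day != plume_b.day:
        raise ValueError("plume sets must share a day")
    ga, gb = plume_a.union(), plume_b.union()
    if not ga.is_valid or not gb.is_valid:
        from shapely.validation import make_valid

        ga, gb = make_valid(ga), make_valid(gb)
        if not (ga.is_valid and gb.is_valid):
            raise ValueError("invalid plume geometry after cleaning")
    a_empty, b_empty = ga.is_empty or ga.area == 0, gb.is_empty or gb.area == 0
    if a_empty and b_empty:
        return math.nan
    if a_empty or b_empty:
        return 0.0
    inter = ga.intersection(gb).area
    union = ga.union(gb).area
    return float(inter / union)
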