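"""Health-association models: lagged exposure effects on area-day counts.

Rate ratios relating each smoke exposure to daily health-indicator counts are
estimated by Poisson GEE with an exchangeable working correlation over areas,
a log-population offset, and adjustment for same-day maximum temperature,
day of week, holidays and study week. Continuous effects are reported per
30 ug/m3 (roughly 2 SD of daily monitor PM2.5); binary effects compare
plume-covered with uncovered area-days. Optionally, extreme forecast values
are truncated (default cap 300 ug/m3) before lag-averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import lag01
from .gee import PoissonGEE

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "DesignMatrices", "RateRatioResult", "build_design",
    "truncate_exposure", "fit_poisson_gee", "rr_per_increment",
    "stratify_smokiness", "fit_exposure_model", "run_health_models",
]

DEFAULT_TRUNCATION_CAP = 300.0
DEFAULT_INCREMENT = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """One exposure-outcome model of the Table-2 style analysis."""

    outcome: str
    exposure_column: str  # daily column of the exposure table
    exposure_type: str  # "continuous" or "binary"
    increment: float = DEFAULT_INCREMENT  # ug/m3 (ignored for binary)
    truncation_cap: float | None = None
    cluster: str = "area_id"

    def __post_init__(self) -> None:
        if self.exposure_type not in ("continuous", "binary"):
            raise ValueError("exposure_type must be continuous or binary")
        if self.increment <= 0:
            raise ValueError("increment must be positive")
        if self.truncation_cap is not None and self.truncation_cap <= 0:
            raise ValueError("truncation_cap must be positive")

    @property
    def label(self) -> str:
        cap = f"_trunc{self.truncation_cap:g}" if self.truncation_cap else ""
        return f"{self.outcome}~{self.exposure_column}{cap}"


@dataclass
class DesignMatrices:
    """Model-ready arrays for one exposure-outcome fit."""

    X: pd.DataFrame
    y: np.ndarray
    offset: np.ndarray
    clusters: np.ndarray
    exposure_term: str
    n_dropped: int
    rows: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class RateRatioResult:
    """Rate ratio with 95% CI for a stated exposure contrast."""

    rr: float
    ci_low: float
    ci_high: float
    contrast: str

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("require 0 < ci_low <= rr <= ci_high")


def truncate_exposure(values, cap: float = DEFAULT_TRUNCATION_CAP) -> np.ndarray:
    """Cap exposure values elementwise at ``cap`` (NaN passes through)."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    v = np.asarray(values, dtype=float)
    n = int(np.sum(v > cap))
    if n:
        logger.info("truncated %d exposure values at %g", n, cap)
    return np.where(v > cap, cap, v)  # NaN > cap is False: missing stays missing


def build_design(panel: pd.DataFrame, exposures: pd.DataFrame,
                 spec: ModelSpec) -> DesignMatrices:
    """Join the health panel with exposures and assemble the model design.

    The lag 0-1 exposure is recomputed from the daily column (after optional
    truncation). Adjustment columns: tmax (linear), day-of-week indicators,
    holiday indicator, study-week indicators. Rows with missing exposure or
    covariates are dropped (complete case) and counted.
    """
    if spec.exposure_column not in exposures.columns:
        raise ValueError(f"exposure column {spec.exposure_column!r} not found")
    sub = panel[panel["outcome"] == spec.outcome]
    if sub.empty:
        raise ValueError(f"no panel rows for outcome {spec.outcome!r}")

    expo = exposures[["area_id", "day", spec.exposure_column]].copy()
    daily = expo[spec.exposure_column].to_numpy(dtype=float)
    if spec.truncation_cap is not None:
        daily = truncate_exposure(daily, spec.truncation_cap)
    expo["_daily"] = daily
    expo = expo.sort_values(["area_id", "day"], kind="stable")
    expo["exposure"] = expo.groupby("area_id", sort=False)["_daily"].transform(
        lambda s: lag01(s.to_numpy(), kind=spec.exposure_type))

    df = sub.merge(expo[["area_id", "day", "exposure"]], on=["area_id", "day"],
                   how="left")
    n0 = len(df)
    df = df.dropna(subset=["exposure", "tmax", "population", "count"])
    n_dropped = n0 - len(df)
    if df.empty:
        raise ValueError("all rows dropped as incomplete")
    if n_dropped:
        logger.info("%s: dropped %d of %d incomplete area-days",
                    spec.label, n_dropped, n0)
    if spec.exposure_type == "binary":
        bad = ~df["exposure"].isin([0.0, 1.0])
        if bad.any():
            raise ValueError("binary exposure column contains non-binary values")

    X = pd.DataFrame({"exposure": df["exposure"].to_numpy(dtype=float),
                      "tmax": df["tmax"].to_numpy(dtype=float)})
    for d in range(1, 7):  # Monday (0) is the reference
        X[f"dow_{d}"] = (df["day_of_week"] == d).astype(float).to_numpy()
    X["holiday"] = df["holiday_flag"].astype(float).to_numpy()
    for w in sorted(df["study_week"].unique())[1:]:  # first week is reference
        X[f"week_{w}"] = (df["study_week"] == w).astype(float).to_numpy()

    # adjustment indicators without variation (e.g. no holiday in the study
    # window) carry no information and would make the design singular
    constant = [c for c in X.columns
                if c != "exposure" and X[c].nunique() <= 1]
    if constant:
        logger.info("%s: dropping constant adjustment columns %s",
                    spec.label, constant)
        X = X.drop(columns=constant)

    return DesignMatrices(
        X=X,
        y=df["count"].to_numpy(dtype=float),
        offset=np.log(df["population"].to_numpy(dtype=float)),
        clusters=df[spec.cluster].to_numpy(),
        exposure_term="exposure",
        n_dropped=n_dropped,
        rows=df.reset_index(drop=True),
    )


def fit_poisson_gee(design: DesignMatrices,
                    correlation: str = "exchangeable",
                    **kwargs) -> PoissonGEE:
    """Fit the Poisson GEE on assembled design matrices."""
    model = PoissonGEE(correlation=correlation, fit_intercept=True, **kwargs)
    return model.fit(design.X, design.y, clusters=design.clusters,
                     offset=design.offset)


def rr_per_increment(fit: PoissonGEE, exposure_term: str = "exposure",
                     increment: float = DEFAULT_INCREMENT,
                     exposure_type: str = "continuous") -> RateRatioResult:
    """Rate ratio (95% CI, sandwich SE) for the stated exposure contrast.

    Continuous: per ``increment`` ug/m3; binary: covered vs uncovered
    (increment fixed at 1). The critical value is a t quantile at the fit's
    Satterthwaite effective df when available (smoke exposure concentrates
    information in few areas, so a normal reference undercovers), otherwise
    the normal 1.96.
    """
    if exposure_term not in fit.params_.index:
        raise ValueError(f"term {exposure_term!r} not in fitted model")
    inc = 1.0 if exposure_type == "binary" else float(increment)
    beta = float(fit.params_[exposure_term])
    se = float(fit.robust_se()[exposure_term])
    dfs = getattr(fit, "satterthwaite_df_", None)
    crit = (float(stats.t.ppf(0.975, float(dfs[exposure_term])))
            if dfs is not None else 1.96)
    rr = math.exp(inc * beta)
    lo = math.exp(inc * (beta - crit * se))
    hi = math.exp(inc * (beta + crit * se))
    contrast = ("plume covered vs not covered" if exposure_type == "binary"
                else f"+{inc:g} ug/m3")
    return RateRatioResult(rr=rr, ci_low=lo, ci_high=hi, contrast=contrast)


def stratify_smokiness(exposures: pd.DataFrame,
                       threshold_days: "int | str" = "mean",
                       flag_column: str = "observed_plume") -> pd.DataFrame:
    """Label areas very_smoky / less_smoky by observed-plume coverage days.

    ``threshold_days="mean"`` uses the rounded mean coverage-day count across
    areas; areas with count >= threshold are very_smoky.
    """
    if flag_column not in exposures.columns:
        raise ValueError(f"column {flag_column!r} not in exposure table")
    counts = (exposures.groupby("area_id", sort=True)[flag_column]
              .sum(min_count=1).fillna(0.0))
    if threshold_days == "mean":
        threshold = int(round(float(counts.mean())))
    else:
        threshold = int(threshold_days)
    out = pd.DataFrame({
        "area_id": counts.index,
        "coverage_days": counts.to_numpy(dtype=float),
        "stratum": np.where(counts.to_numpy() >= threshold,
                            "very_smoky", "less_smoky"),
    }).reset_index(drop=True)
    if out["stratum"].nunique() == 1:
        logger.warning("smokiness stratification produced a single stratum")
    out.attrs["threshold_days"] = threshold
    return out


def fit_exposure_model(panel: pd.DataFrame, exposures: pd.DataFrame,
                       spec: ModelSpec, correlation: str = "exchangeable",
                       area_subset: "list | None" = None) -> dict:
    """Fit one exposure-outcome model and summarise it as a result row."""
    if area_subset is not None:
        panel = panel[panel["area_id"].isin(area_subset)]
        exposures = exposures[exposures["area_id"].isin(area_subset)]
    design = build_design(panel, exposures, spec)
    fit = fit_poisson_gee(design, correlation=correlation)
    rr = rr_per_increment(fit, design.exposure_term, spec.increment,
                          spec.exposure_type)
    return {
        "outcome": spec.outcome,
        "exposure": spec.exposure_column,
        "truncation_cap": spec.truncation_cap,
        "rr": rr.rr, "ci_low": rr.ci_low, "ci_high": rr.ci_high,
        "contrast": rr.contrast,
        "n_obs": fit.n_obs_, "n_clusters": fit.n_clusters_,
        "n_dropped": design.n_dropped,
        "exposure_df": float(fit.satterthwaite_df_[design.exposure_term]),
        "alpha": fit.alpha_, "scale": fit.scale_,
        "converged": fit.converged_,
        "fit": fit,
    }


def default_model_specs(outcomes: "list[str]",
                        truncation_cap: float = DEFAULT_TRUNCATION_CAP
                        ) -> list[ModelSpec]:
    """The standard battery: four exposures plus the truncated forecast."""
    specs = []
    for outcome in outcomes:
        specs += [
            ModelSpec(outcome, "forecast_pm25", "continuous"),
            ModelSpec(outcome, "forecast_pm25", "continuous",
                      truncation_cap=truncation_cap),
            ModelSpec(outcome, "monitor_pm25", "continuous"),
            ModelSpec(outcome, "forecast_plume", "binary"),
            ModelSpec(outcome, "observed_plume", "binary"),
        ]
    return specs


def run_health_models(panel: pd.DataFrame, exposures: pd.DataFrame,
                      specs: "list[ModelSpec] | None" = None,
                      stratify: bool = True,
                      stratify_threshold: "int | str" = "mean",
                      correlation: str = "exchangeable") -> pd.DataFrame:
    """Fit the model battery, overall and by smokiness stratum.

    Returns one row per (outcome, exposure, stratum) with RR, 95% CI, data
    accounting and working-correlation diagnostics.
    """
    if specs is None:
        specs = default_model_specs(sorted(panel["outcome"].unique()))
    strata: dict[str, "list | None"] = {"all": None}
    if stratify:
        labels = stratify_smokiness(exposures, stratify_threshold)
        for name, grp in labels.groupby("stratum"):
            strata[name] = grp["area_id"].tolist()

    rows = []
    for spec in specs:
        for stratum, subset in strata.items():
            try:
                res = fit_exposure_model(panel, exposures, spec,
                                         correlation=correlation,
                                         area_subset=subset)
            except ValueError as exc:
                logger.warning("skipping %s in stratum %s: %s",
                               spec.label, stratum, exc)
                continue
            res.pop("fit")
            res["stratum"] = stratum
            rows.append(res)
    out = pd.DataFrame(rows)
    cols = ["outcome", "exposure", "truncation_cap", "stratum", "rr",
            "ci_low", "ci_high", "contrast", "n_obs", "n_clusters",
            "n_dropped", "exposure_df", "alpha", "scale", "converged"]
    return out[cols]
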