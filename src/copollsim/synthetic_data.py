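"""Synthetic exposure panels, health covariates, and baseline ED counts.

No public exposure or emergency-department dataset accompanies the study
design this package implements, so everything downstream is exercised
against a generator that makes the analysis assumptions literally true:

* The central-site (CS) daily series of each pollutant is a seasonal mean
  plus a stationary AR(1) deviation, jointly Gaussian across pollutants with
  a configured correlation; CS is identical across ZIP areas by definition
  (a single monitor represents the whole metro area).
* The air-quality-model metric (AQ) is built from CS by a ZIP-specific
  linear calibration ``AQ = theta1 + theta2 * CS + eps`` with (theta1,
  theta2) drawn once per ZIP (additive and multiplicative bias constant
  across days) and residuals drawn jointly across pollutants with the
  configured error correlation.  The population-exposure metric (PE) is
  built from AQ the same way.
* Covariates (calendar, weather, hospital reporting windows) follow the
  confounder structure of the health model; weather is shared across ZIPs.
* Baseline counts are Poisson draws from a known coefficient vector so the
  baseline fit is testable by parameter recovery.

Concentrations are *not* truncated at zero: the linear error model lives on
the raw scale and truncation would distort the covariance structure the
analysis relies on.  Negative values are counted and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import METRICS, START_DATE, ScenarioConfig
from .health_model import HealthDesign, build_design_matrix, fit_poisson

logger = logging.getLogger(__name__)

__all__ = [
    "generate_exposure_panel",
    "generate_covariates",
    "make_baseline_coefficients",
    "simulate_baseline_counts",
    "fit_baseline_coefficients",
    "panel_to_csv",
    "panel_from_csv",
    "covariates_to_csv",
    "covariates_from_csv",
    "counts_to_csv",
    "counts_from_csv",
    "PANEL_COLUMNS",
]

#: Canonical long-format exposure panel columns.
PANEL_COLUMNS = ["zip_id", "day", "pollutant", "metric", "value"]

#: Ten fixed holiday dates per calendar year (month, day).
HOLIDAYS = [
    (1, 1), (1, 18), (2, 15), (5, 30), (7, 4),
    (9, 6), (10, 11), (11, 11), (11, 25), (12, 25),
]

_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}

_DOW_NAMES = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent substream per generator stage for one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Exposure panel
# ---------------------------------------------------------------------------

def _simulate_cs(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Daily CS concentrations, shape (n_days, n_pollutants)."""
    names = config.pollutant_names
    n_days, n_pol = config.n_days, len(names)
    corr = config.concentration_correlation
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_pol))
    shocks = rng.standard_normal((n_days, n_pol)) @ chol.T

    phi = np.array([config.concentration_params[p].ar1 for p in names])
    sd = np.array([config.concentration_params[p].daily_sd for p in names])
    z = np.empty((n_days, n_pol))
    z[0] = sd * shocks[0]
    innov_scale = sd * np.sqrt(1.0 - phi**2)
    for t in range(1, n_days):
        z[t] = phi * z[t - 1] + innov_scale * shocks[t]

    doy = (np.arange(n_days) % 365.25)[:, None]
    level = np.array([config.concentration_params[p].level for p in names])
    amp = np.array([config.concentration_params[p].seasonal_amplitude for p in names])
    peak = np.array([config.concentration_params[p].peak_day for p in names])
    seasonal = amp * np.cos(2 * np.pi * (doy - peak) / 365.25)
    return level + seasonal + z


def _apply_calibration(
    base: np.ndarray,
    config: ScenarioConfig,
    stage: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One calibration stage: refined[k] = theta1_k + theta2_k * base[k] + eps.

    ``base`` has shape (n_zips, n_days, n_pollutants).  Residuals are drawn
    jointly across pollutants with the configured error correlation,
    independently across ZIPs and days.  Returns the refined metric and the
    realized per-ZIP theta draws (for recovery tests).
    """
    names = config.pollutant_names
    n_zips, n_days, n_pol = base.shape
    resid_sd = np.array(
        [config.calibration_params[p][stage].resid_sd for p in names]
    )
    cov = np.outer(resid_sd, resid_sd) * config.error_correlation
    # eigendecomposition handles exactly-zero residual SDs (singular cov)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    truth_rows = []
    refined = np.empty_like(base)
    for k in range(n_zips):
        t1 = np.array(
            [
                rng.normal(
                    config.calibration_params[p][stage].theta1_mean,
                    config.calibration_params[p][stage].theta1_sd,
                )
                for p in names
            ]
        )
        t2 = np.array(
            [
                rng.normal(
                    config.calibration_params[p][stage].theta2_mean,
                    config.calibration_params[p][stage].theta2_sd,
                )
                for p in names
            ]
        )
        eps = rng.standard_normal((n_days, n_pol)) @ root.T
        refined[k] = t1 + t2 * base[k] + eps
        for j, p in enumerate(names):
            truth_rows.append(
                {"zip_id": k, "pollutant": p, "stage": stage,
                 "theta1": t1[j], "theta2": t2[j]}
            )
    return refined, pd.DataFrame(truth_rows)


def generate_exposure_panel(
    config: ScenarioConfig,
    seed: int | None = None,
    return_truth: bool = False,
):
    """Generate a long-format CS/AQ/PE exposure panel.

    Returns a DataFrame with columns ``zip_id, day, pollutant, metric,
    value`` (one row per combination).  With ``return_truth=True`` also
    returns the realized per-ZIP calibration coefficients used by the
    generator, for parameter-recovery tests.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    names = config.pollutant_names
    n_zips, n_days = config.n_zips, config.n_days

    cs_daily = _simulate_cs(config, rng)  # (days, pol)
    cs = np.broadcast_to(cs_daily, (n_zips, n_days, len(names))).copy()
    aq, truth_aq = _apply_calibration(cs, config, "spatial", rng)
    pe, truth_pe = _apply_calibration(aq, config, "population", rng)

    n_neg = int((cs < 0).sum() + (aq < 0).sum() + (pe < 0).sum())
    if n_neg:
        logger.info(
            "generated panel contains %d negative concentration values "
            "(retained; linear error model is on the raw scale)", n_neg
        )

    zips = np.arange(n_zips)
    days = np.arange(n_days)
    frames = []
    for metric, arr in zip(METRICS, (cs, aq, pe)):
        wide = pd.DataFrame(
            arr.reshape(n_zips * n_days, len(names)),
            columns=names,
        )
        wide["zip_id"] = np.repeat(zips, n_days)
        wide["day"] = np.tile(days, n_zips)
        long = wide.melt(
            id_vars=["zip_id", "day"], var_name="pollutant", value_name="value"
        )
        long["metric"] = metric
        frames.append(long)
    panel = (
        pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]
        .sort_values(["zip_id", "day", "pollutant", "metric"])
        .reset_index(drop=True)
    )
    if return_truth:
        truth = pd.concat([truth_aq, truth_pe], ignore_index=True)
        return panel, truth
    return panel


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def generate_covariates(
    config: ScenarioConfig,
    seed: int | None = None,
    start_date: str = START_DATE,
) -> pd.DataFrame:
    """Generate the per-(zip, day) confounder table.

    Weather (max/min temperature, dew point) and calendar fields are shared
    across ZIPs on a given day, as in a single-metro study.  Each hospital
    reports over one contiguous random window covering at least half the
    study period (hospitals enter and leave the study at different times).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 2)
    n_days, n_zips = config.n_days, config.n_zips

    dates = pd.date_range(start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    # weather: summer-peaked sinusoid + noise; ints for the binned max temp
    max_temp = np.round(
        21.0 + 9.0 * np.cos(2 * np.pi * (doy - 196) / 365.25)
        + rng.normal(0, 2.5, n_days)
    ).astype(int)
    spread = np.clip(8.0 + rng.normal(0, 2.0, n_days), 1.0, None)
    min_temp = max_temp - spread
    dew_point = min_temp - 2.0 + rng.normal(0, 2.0, n_days)

    holiday = np.array(
        [(d.month, d.day) in set(HOLIDAYS) for d in dates], dtype=bool
    )
    season = np.array([_SEASON_BY_MONTH[m] for m in dates.month])
    dow = np.array([_DOW_NAMES[d] for d in dates.dayofweek])

    hospitals = np.zeros((n_days, config.n_hospitals), dtype=int)
    for h in range(config.n_hospitals):
        frac = rng.uniform(0.5, 0.95)
        length = max(1, int(round(frac * n_days)))
        start = int(rng.integers(0, n_days - length + 1))
        hospitals[start : start + length, h] = 1

    daily = pd.DataFrame(
        {
            "day": np.arange(n_days),
            "date": dates,
            "day_of_week": dow,
            "holiday": holiday,
            "time": np.arange(n_days),
            "max_temperature": max_temp,
            "min_temperature": min_temp,
            "dew_point": dew_point,
            "season": season,
        }
    )
    for h in range(config.n_hospitals):
        daily[f"hospital_{h + 1}"] = hospitals[:, h]

    out = daily.loc[np.tile(np.arange(n_days), n_zips)].reset_index(drop=True)
    out.insert(0, "zip_id", np.repeat(np.arange(n_zips), n_days))
    return out


# ---------------------------------------------------------------------------
# Baseline counts and coefficients
# ---------------------------------------------------------------------------

def make_baseline_coefficients(
    design: HealthDesign,
    baseline_rate: float,
    rng: np.random.Generator,
    effect_scale: float = 0.03,
) -> pd.Series:
    """Construct a plausible 'true' baseline coefficient vector B*.

    Each non-intercept coefficient contributes ``N(0, effect_scale^2)`` to
    the linear predictor after scaling by its column's standard deviation;
    the intercept is then solved so the mean Poisson rate equals
    ``baseline_rate``.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    B = np.zeros(design.n_cols)
    i0 = design.blocks["intercept"][0]
    for j in range(design.n_cols):
        if j == i0:
            continue
        sd = design.X[:, j].std()
        if sd > 1e-12:
            B[j] = rng.normal(0.0, effect_scale) / sd
    eta = design.X @ B
    B[i0] = np.log(baseline_rate) - np.log(np.mean(np.exp(eta)))
    return pd.Series(B, index=design.columns)


def simulate_baseline_counts(
    design: HealthDesign,
    B: np.ndarray | pd.Series,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson baseline counts (no pollutant effect), aligned to the design."""
    mu = np.exp(design.X @ np.asarray(B, dtype=float))
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite baseline Poisson mean")
    return rng.poisson(mu)


def fit_baseline_coefficients(
    covariates: pd.DataFrame,
    counts: np.ndarray | pd.Series,
    design: HealthDesign | None = None,
) -> pd.Series:
    """Fit the health model without pollutant terms; return coefficients B.

    ``counts`` must be aligned to the design's (zip, day) row order.  Passing
    a pre-built ``design`` avoids re-assembly.  Raises on all-zero counts
    (the intercept diverges) and on IRLS non-convergence.
    """
    if design is None:
        design = build_design_matrix(covariates)
    counts = np.asarray(counts)
    if counts.shape != (design.n_rows,):
        raise ValueError("counts not aligned to design rows")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if counts.sum() == 0:
        raise ValueError(
            "degenerate input: all counts are zero (intercept MLE is -inf)"
        )
    res = fit_poisson(design.X, counts)
    if not bool(getattr(res, "converged", True)):
        raise RuntimeError(
            "baseline Poisson fit did not converge: "
            f"fit history {getattr(res, 'fit_history', {})}"
        )
    return pd.Series(res.params, index=design.columns)


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def _day_to_date(day: np.ndarray, start_date: str) -> pd.Series:
    origin = pd.Timestamp(start_date)
    return pd.Series(origin + pd.to_timedelta(day, unit="D")).dt.strftime("%Y-%m-%d")


def panel_to_csv(panel: pd.DataFrame, path, start_date: str = START_DATE) -> None:
    """Write an exposure panel with header zip_id, date, pollutant, metric, value."""
    out = panel.copy()
    out["date"] = _day_to_date(out.pop("day").to_numpy(), start_date)
    out[["zip_id", "date", "pollutant", "metric", "value"]].to_csv(path, index=False)


def panel_from_csv(path, start_date: str = START_DATE) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    df["day"] = (df.pop("date") - pd.Timestamp(start_date)).dt.days
    return (
        df[PANEL_COLUMNS]
        .sort_values(["zip_id", "day", "pollutant", "metric"])
        .reset_index(drop=True)
    )


def covariates_to_csv(cov: pd.DataFrame, path) -> None:
    out = cov.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def covariates_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def counts_to_csv(
    design: HealthDesign, counts: np.ndarray, path, start_date: str = START_DATE
) -> None:
    out = design.index.copy()
    out["date"] = _day_to_date(out.pop("day").to_numpy(), start_date)
    out["count"] = np.asarray(counts)
    out.to_csv(path, index=False)


def counts_from_csv(path, start_date: str = START_DATE) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    df["day"] = (df.pop("date") - pd.Timestamp(start_date)).dt.days
    return df[["zip_id", "day", "count"]]
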