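"""Exposure-error decomposition and ZIP-level calibration estimation.

Three error components are defined as differences between exposure metrics:

* ``spatial = AQ - CS`` — error from assigning a single central-site value
  to every ZIP area,
* ``population = PE - AQ`` — error from ignoring human activity,
  commuting and infiltration,
* ``total = PE - CS`` — both combined (so spatial + population = total
  identically).

For each error type, ordinary least squares is fitted per (ZIP, pollutant)
regressing the refined metric on the unrefined one,

    refined_kt = theta_k1 + theta_k2 * unrefined_kt + eps_kt,

capturing additive (theta1) and multiplicative (theta2) bias.  The
unrefined predictor is CS for spatial and total error and AQ for population
error.  The asymptotic covariance of (theta1, theta2) is the homoskedastic
OLS form ``sigma^2 (X'X)^{-1}``; the cross-pollutant residual covariance per
ZIP pairs the residuals of the separate single-pollutant fits by day.
These estimates drive the true-exposure simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ERROR_TYPES

__all__ = [
    "ErrorModelError",
    "CalibrationSet",
    "compute_error_panel",
    "fit_calibrations",
    "UNREFINED_METRIC",
    "REFINED_METRIC",
]


class ErrorModelError(ValueError):
    """Raised for incomplete panels or unidentifiable calibrations."""


#: Predictor (unrefined) and response (refined) metric per error type.
UNREFINED_METRIC = {"spatial": "CS", "population": "AQ", "total": "CS"}
REFINED_METRIC = {"spatial": "AQ", "population": "PE", "total": "PE"}


def compute_error_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Compute all three error components for every (zip, day, pollutant).

    Returns a long-format frame with columns ``zip_id, day, pollutant,
    error_type, delta``.  Raises :class:`ErrorModelError` naming the first
    incomplete (zip, day, pollutant) tuple if any metric is missing.
    """
    wide = panel.pivot_table(
        index=["zip_id", "day", "pollutant"],
        columns="metric",
        values="value",
        aggfunc="first",
    )
    missing_cols = {"CS", "AQ", "PE"} - set(wide.columns)
    if missing_cols or wide.isna().any().any():
        if missing_cols:
            raise ErrorModelError(
                f"panel is missing metric(s) {sorted(missing_cols)} entirely"
            )
        bad = wide[wide.isna().any(axis=1)].index[0]
        raise ErrorModelError(
            f"incomplete metrics for zip={bad[0]}, day={bad[1]}, "
            f"pollutant={bad[2]!r}"
        )
    deltas = pd.DataFrame(
        {
            "spatial": wide["AQ"] - wide["CS"],
            "population": wide["PE"] - wide["AQ"],
            "total": wide["PE"] - wide["CS"],
        }
    )
    out = (
        deltas.reset_index()
        .melt(
            id_vars=["zip_id", "day", "pollutant"],
            var_name="error_type",
            value_name="delta",
        )
        .sort_values(["zip_id", "day", "pollutant", "error_type"])
        .reset_index(drop=True)
    )
    return out


@dataclass
class CalibrationSet:
    """Per-ZIP calibration structure for one error type.

    ``theta`` has one row per (zip_id, pollutant) with columns ``theta1,
    theta2`` plus the flattened 2x2 asymptotic covariance (``cov11, cov12,
    cov22``).  ``resid_cov[zip_id]`` is the pollutant x pollutant empirical
    covariance of the day-paired OLS residuals within that ZIP.
    """

    error_type: str
    theta: pd.DataFrame
    resid_cov: dict[int, pd.DataFrame] = field(default_factory=dict)

    def theta_for(self, zip_id: int, pollutant: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (theta_hat, 2x2 asymptotic covariance) for one fit."""
        row = self.theta[
            (self.theta["zip_id"] == zip_id) & (self.theta["pollutant"] == pollutant)
        ]
        if row.empty:
            raise KeyError((zip_id, pollutant))
        r = row.iloc[0]
        cov = np.array([[r["cov11"], r["cov12"]], [r["cov12"], r["cov22"]]])
        return np.array([r["theta1"], r["theta2"]]), cov

    def resid_cov_for(self, zip_id: int, pol1: str, pol2: str) -> np.ndarray:
        """2x2 residual covariance for a pollutant pair within one ZIP."""
        full = self.resid_cov[zip_id]
        sub = full.loc[[pol1, pol2], [pol1, pol2]].to_numpy()
        eigmin = float(np.linalg.eigvalsh(sub).min())
        if eigmin < -1e-8 * max(1.0, float(np.trace(sub))):
            raise ErrorModelError(
                f"residual covariance for zip {zip_id}, pair ({pol1}, {pol2}) "
                "is not positive semi-definite"
            )
        return sub

    @property
    def zip_ids(self) -> list[int]:
        return sorted(self.resid_cov)

    @property
    def pollutants(self) -> list[str]:
        return list(self.resid_cov[self.zip_ids[0]].columns)

    # -- serialization for audit ---------------------------------------

    def to_csv(self, theta_path, resid_path) -> None:
        t = self.theta.copy()
        t.insert(0, "error_type", self.error_type)
        t.to_csv(theta_path, index=False)
        rows = []
        for z, mat in self.resid_cov.items():
            pols = list(mat.columns)
            for i, p1 in enumerate(pols):
                for p2 in pols[i:]:
                    rows.append(
                        {
                            "error_type": self.error_type,
                            "zip_id": z,
                            "pollutant_1": p1,
                            "pollutant_2": p2,
                            "covariance": mat.loc[p1, p2],
                        }
                    )
        pd.DataFrame(rows).to_csv(resid_path, index=False)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple-regression OLS: theta, asymptotic covariance, residuals."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    dof = max(n - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return theta, cov, resid


def fit_calibrations(
    panel: pd.DataFrame, error_type: str, min_days: int = 10
) -> CalibrationSet:
    """Fit per-(ZIP, pollutant) OLS calibrations for one error type.

    Days with a missing value are dropped listwise per (ZIP, pollutant);
    the cross-pollutant residual covariance pairs residuals by day with
    pairwise-complete observations.  Raises when a ZIP has fewer than
    ``min_days`` usable days or a constant predictor (slope unidentifiable).
    """
    if error_type not in ERROR_TYPES:
        raise ErrorModelError(
            f"unknown error_type {error_type!r}; expected one of {ERROR_TYPES}"
        )
    unref, ref = UNREFINED_METRIC[error_type], REFINED_METRIC[error_type]
    wide = panel.pivot_table(
        index=["zip_id", "day", "pollutant"],
        columns="metric",
        values="value",
        aggfunc="first",
    )
    for metric in (unref, ref):
        if metric not in wide.columns:
            raise ErrorModelError(f"panel lacks metric {metric!r}")

    theta_rows = []
    resid_cov: dict[int, pd.DataFrame] = {}
    for zip_id, zdf in wide.groupby(level="zip_id"):
        zdf = zdf.droplevel("zip_id")
        resid_frames = {}
        for pol, pdf in zdf.groupby(level="pollutant"):
            pdf = pdf.droplevel("pollutant")
            pair = pdf[[unref, ref]].dropna()
            if len(pair) < min_days:
                raise ErrorModelError(
                    f"zip {zip_id}, pollutant {pol!r}: only {len(pair)} "
                    f"complete days (< {min_days})"
                )
            x = pair[unref].to_numpy(dtype=float)
            y = pair[ref].to_numpy(dtype=float)
            if np.ptp(x) < 1e-12:
                raise ErrorModelError(
                    f"zip {zip_id}, pollutant {pol!r}: constant predictor "
                    f"{unref}; slope unidentifiable"
                )
            th, cov, resid = _ols_line(x, y)
            theta_rows.append(
                {
                    "zip_id": zip_id,
                    "pollutant": pol,
                    "theta1": th[0],
                    "theta2": th[1],
                    "cov11": cov[0, 0],
                    "cov12": cov[0, 1],
                    "cov22": cov[1, 1],
                    "resid_var": float(resid @ resid) / len(resid),
                }
            )
            resid_frames[pol] = pd.Series(resid, index=pair.index)
        rmat = pd.DataFrame(resid_frames)
        # population covariance (ddof=0) so the diagonal equals each
        # pollutant's own mean squared residual from its single fit
        resid_cov[zip_id] = rmat.cov(ddof=0)
    return CalibrationSet(
        error_type=error_type,
        theta=pd.DataFrame(theta_rows),
        resid_cov=resid_cov,
    )
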