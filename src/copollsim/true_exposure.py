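"""Simulation of 'true' (error-free) exposures from the unrefined metric.

The measurement-error framework treats the refined metric as the better
estimate of what people actually breathe, so the simulated truth is *more*
variable than the error-prone unrefined metric.  For one Monte Carlo
iteration and a pollutant pair:

1. For each ZIP and each pollutant, one (theta1, theta2) realization is
   drawn from the asymptotic bivariate normal distribution of the OLS
   calibration estimates — bias is spatially heterogeneous across ZIPs but
   constant across days.  Draws for the two pollutants are independent
   (the asymptotic normal is per single-pollutant fit).
2. For each (ZIP, day), one residual pair is drawn from a bivariate normal
   with the ZIP-specific empirical residual covariance of the two
   pollutants, correlating the two errors.
3. ``true = theta1 + theta2 * unrefined + eps``; the IQR of each resulting
   pooled series standardizes the exposure in the health model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .error_models import CalibrationSet, ErrorModelError, UNREFINED_METRIC

__all__ = ["TrueExposurePair", "simulate_true_exposure", "unrefined_matrix", "iqr"]


def iqr(values: np.ndarray) -> float:
    """Interquartile range (75th minus 25th percentile)."""
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


@dataclass
class TrueExposurePair:
    """Simulated true exposures for one iteration, row-aligned to the design.

    ``exp1``/``exp2`` are flat arrays over (zip, day) rows sorted by
    (zip_id, day); ``iqr1``/``iqr2`` are the IQRs of those pooled series;
    ``theta_draws`` records the realized per-ZIP coefficients.
    """

    index: pd.DataFrame
    exp1: np.ndarray
    exp2: np.ndarray
    iqr1: float
    iqr2: float
    theta_draws: pd.DataFrame

    def __post_init__(self):
        if self.iqr1 <= 0 or self.iqr2 <= 0:
            raise ValueError("true-exposure IQRs must be > 0")

    def to_csv(self, path) -> None:
        out = self.index.copy()
        out["true_exp1"] = self.exp1
        out["true_exp2"] = self.exp2
        out.to_csv(path, index=False)


def unrefined_matrix(
    panel: pd.DataFrame, pollutant: str, error_type: str
) -> pd.DataFrame:
    """Unrefined metric for one pollutant as a (zip_id x day) matrix."""
    metric = UNREFINED_METRIC[error_type]
    sub = panel[(panel["pollutant"] == pollutant) & (panel["metric"] == metric)]
    return sub.pivot(index="zip_id", columns="day", values="value").sort_index()


def _psd_root(cov: np.ndarray, what: str) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(1.0, float(np.trace(cov))):
        raise ErrorModelError(f"{what} is not positive semi-definite")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_true_exposure(
    panel: pd.DataFrame,
    calib: CalibrationSet,
    pol1: str,
    pol2: str,
    error_type: str,
    rng: np.random.Generator,
) -> TrueExposurePair:
    """Draw one realization of the true exposure pair.

    ``panel`` supplies the unrefined metric for ``error_type``; ``calib``
    must be the calibration set fitted for the same error type.
    """
    if calib.error_type != error_type:
        raise ValueError(
            f"calibration set is for {calib.error_type!r}, not {error_type!r}"
        )
    w1 = unrefined_matrix(panel, pol1, error_type)
    w2 = unrefined_matrix(panel, pol2, error_type)
    if w1.isna().any().any() or not w1.index.equals(w2.index):
        raise ValueError("panel support differs between the two pollutants")
    zips = list(w1.index)
    n_days = w1.shape[1]

    true1 = np.empty_like(w1.to_numpy(dtype=float))
    true2 = np.empty_like(true1)
    draws = []
    for i, z in enumerate(zips):
        th = {}
        for pol in (pol1, pol2):
            mean, cov = calib.theta_for(z, pol)
            root = _psd_root(cov, f"theta covariance (zip {z}, {pol})")
            th[pol] = mean + root @ rng.standard_normal(2)
        rcov = calib.resid_cov_for(z, pol1, pol2)
        eps = rng.standard_normal((n_days, 2)) @ _psd_root(
            rcov, f"residual covariance (zip {z})"
        ).T
        true1[i] = th[pol1][0] + th[pol1][1] * w1.iloc[i].to_numpy() + eps[:, 0]
        true2[i] = th[pol2][0] + th[pol2][1] * w2.iloc[i].to_numpy() + eps[:, 1]
        for pol in (pol1, pol2):
            draws.append(
                {"zip_id": z, "pollutant": pol,
                 "theta1": th[pol][0], "theta2": th[pol][1]}
            )

    index = pd.DataFrame(
        {
            "zip_id": np.repeat(zips, n_days),
            "day": np.tile(w1.columns.to_numpy(), len(zips)),
        }
    )
    return TrueExposurePair(
        index=index,
        exp1=true1.ravel(),
        exp2=true2.ravel(),
        iqr1=iqr(true1),
        iqr2=iqr(true2),
        theta_draws=pd.DataFrame(draws),
    )
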