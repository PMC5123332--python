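"""Poisson time-series health model: design matrix, count simulation, fitting.

The outcome model for daily ZIP-level emergency-department visit counts
``Y_kt`` is a log-linear Poisson regression

    log E(Y_kt) = a + b1 * poll1_kt + b2 * poll2_kt
                  + ZIP indicators + day-of-week / holiday indicators
                  + hospital-reporting indicators
                  + cubic time spline with monthly knots
                  + max-temperature indicators (one per degree C)
                  + cubic polynomials in dew point and minimum temperature
                  + season indicators

where the two pollutant terms are exposures standardized by their
interquartile ranges, so ``exp(b)`` is a relative risk per IQR increase.

:func:`build_design_matrix` assembles the covariate part (everything except
the two pollutants), :func:`simulate_counts` draws Poisson outcomes with a
known pollutant effect injected, and :func:`fit_copollutant_model` recovers
the two pollutant coefficients by maximum likelihood (IRLS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from patsy import dmatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HealthDesign",
    "FitResult",
    "DesignError",
    "build_design_matrix",
    "poisson_mean",
    "simulate_counts",
    "fit_copollutant_model",
    "fit_poisson",
]

#: Relative R-diagonal threshold below which a design column is aliased.
_RANK_TOL = 1e-9

#: IRLS convergence settings for all Poisson fits.
_IRLS_TOL = 1e-8
_IRLS_MAXITER = 100

#: Linear-predictor clip guarding exp() overflow during IRLS line search.
_ETA_MAX = 30.0


class DesignError(ValueError):
    """Raised when the covariate design cannot be assembled at full rank."""


@dataclass
class HealthDesign:
    """Covariate design matrix with named column blocks.

    Rows are ordered by (zip_id, day); ``index`` carries that ordering.
    ``blocks`` maps block names (``intercept``, ``zip``, ``dow``,
    ``holiday``, ``hospital``, ``time_spline``, ``max_temp``, ``dew_point``,
    ``min_temp``, ``season``) to column positions in ``X``.  Columns found
    to be exactly collinear during assembly are dropped and recorded in
    ``dropped``.
    """

    X: np.ndarray
    columns: list[str]
    blocks: dict[str, list[int]]
    index: pd.DataFrame
    dropped: list[str] = field(default_factory=list)
    _q: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)

    def _orthonormal_basis(self) -> np.ndarray:
        # cached thin-QR basis of the column space, reused to residualize
        # candidate exposure columns across many Monte Carlo iterations
        if self._q is None:
            self._q, _ = np.linalg.qr(self.X)
        return self._q

    def residualize(self, cols: np.ndarray) -> np.ndarray:
        """Project columns onto the orthogonal complement of the design."""
        q = self._orthonormal_basis()
        return cols - q @ (q.T @ cols)


def _month_start_knots(dates: pd.Series) -> np.ndarray:
    """Interior spline knots: time index of each first-of-month strictly
    inside the observation window."""
    d = pd.DatetimeIndex(dates)
    t = np.arange(len(d), dtype=float)
    is_start = (d.day == 1) & (t > 0) & (t < len(d) - 1)
    return t[is_start]


def _dummies(values: pd.Series, prefix: str, drop: object) -> pd.DataFrame:
    dm = pd.get_dummies(values, prefix=prefix, dtype=float)
    drop_col = f"{prefix}_{drop}"
    if drop_col in dm.columns:
        dm = dm.drop(columns=drop_col)
    return dm


def build_design_matrix(covariates: pd.DataFrame) -> HealthDesign:
    """Assemble the covariate design (without the two pollutant columns).

    Reference levels: first ZIP, Monday, the coldest observed integer max
    temperature, and winter.  The time spline is a cubic B-spline basis with
    interior knots at the first day of each calendar month.  Dew point and
    minimum temperature enter as centered cubic polynomials (centering for
    numerical conditioning only; the spanned space is unchanged).

    Raises :class:`DesignError` if the result is rank deficient beyond
    exactly-aliased columns (which are dropped and logged).
    """
    cov = covariates.sort_values(["zip_id", "day"]).reset_index(drop=True)
    n = len(cov)
    index = cov[["zip_id", "day"]].copy()

    pieces: list[tuple[str, pd.DataFrame]] = []
    pieces.append(("intercept", pd.DataFrame({"intercept": np.ones(n)})))

    zips = sorted(cov["zip_id"].unique())
    pieces.append(("zip", _dummies(cov["zip_id"], "zip", zips[0])))

    dow_order = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
    dow = pd.Categorical(cov["day_of_week"], categories=dow_order)
    pieces.append(("dow", _dummies(pd.Series(dow), "dow", "Mon")))
    pieces.append(
        ("holiday", pd.DataFrame({"holiday": cov["holiday"].astype(float).values}))
    )

    hosp_cols = sorted(
        (c for c in cov.columns if c.startswith("hospital_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if hosp_cols:
        pieces.append(("hospital", cov[hosp_cols].astype(float)))

    # one weather/time record per day (shared across ZIPs)
    daily = cov.drop_duplicates("day").sort_values("day")
    knots = _month_start_knots(daily["date"])
    t = cov["day"].to_numpy(dtype=float)
    if len(knots):
        basis = dmatrix(
            "bs(t, knots=k, degree=3, include_intercept=False) - 1",
            {"t": t, "k": knots},
            return_type="dataframe",
        )
        basis.columns = [f"time_spline_{i+1}" for i in range(basis.shape[1])]
        pieces.append(("time_spline", basis.reset_index(drop=True)))

    tmax = cov["max_temperature"].round().astype(int)
    pieces.append(("max_temp", _dummies(tmax, "max_temp", tmax.min())))

    for name, col in (("dew_point", "dew_point"), ("min_temp", "min_temperature")):
        x = cov[col].to_numpy(dtype=float)
        xc = x - x.mean()
        pieces.append(
            (
                name,
                pd.DataFrame(
                    {f"{name}_{p}": xc**p for p in (1, 2, 3)},
                ),
            )
        )

    season_order = ["winter", "spring", "summer", "fall"]
    season = pd.Categorical(cov["season"], categories=season_order)
    pieces.append(("season", _dummies(pd.Series(season), "season", "winter")))

    columns: list[str] = []
    blocks: dict[str, list[int]] = {}
    mats: list[np.ndarray] = []
    pos = 0
    for block, df in pieces:
        cols = list(df.columns)
        blocks.setdefault(block, []).extend(range(pos, pos + len(cols)))
        columns.extend(cols)
        mats.append(df.to_numpy(dtype=float))
        pos += len(cols)
    X = np.hstack(mats)

    # drop exactly-aliased columns by greedy Gram-Schmidt in column order,
    # so earlier blocks (intercept first) win over later aliased ones
    n_rows, n_cols_all = X.shape
    keep_mask = np.ones(n_cols_all, dtype=bool)
    dropped = []
    q = np.empty((n_rows, 0))
    for j in range(n_cols_all):
        v = X[:, j]
        norm_v = np.linalg.norm(v)
        r = v - q @ (q.T @ v)
        r = r - q @ (q.T @ r)  # second pass keeps the basis orthonormal
        norm_r = np.linalg.norm(r)
        if norm_v == 0 or norm_r < np.sqrt(_RANK_TOL) * max(norm_v, 1.0):
            keep_mask[j] = False
            dropped.append(columns[j])
        else:
            q = np.column_stack([q, r / norm_r])
    if q.shape[1] == 0:
        raise DesignError("design matrix is identically zero")
    if dropped:
        logger.warning("dropping %d aliased design column(s): %s", len(dropped), dropped)
        X = X[:, keep_mask]
        old_to_new = np.cumsum(keep_mask) - 1
        columns = [c for c, k in zip(columns, keep_mask) if k]
        blocks = {
            b: [int(old_to_new[j]) for j in idx if keep_mask[j]]
            for b, idx in blocks.items()
        }
        blocks = {b: idx for b, idx in blocks.items() if idx}

    return HealthDesign(X=X, columns=columns, blocks=blocks, index=index, dropped=dropped)


def poisson_mean(
    design: HealthDesign,
    B: np.ndarray | pd.Series,
    true_pair,
    rr1: float,
    rr2: float,
) -> np.ndarray:
    """Poisson mean per (zip, day) row with the pollutant effects injected:
    ``mu = exp(X B + log(rr1) * true_exp1/IQR1 + log(rr2) * true_exp2/IQR2)``.
    """
    if rr1 <= 0 or rr2 <= 0:
        raise ValueError("relative risks must be > 0")
    B = np.asarray(B, dtype=float)
    if B.shape != (design.n_cols,):
        raise ValueError(
            f"coefficient vector length {B.shape} does not match design "
            f"columns ({design.n_cols})"
        )
    eta = design.X @ B
    eta = eta + np.log(rr1) * (true_pair.exp1 / true_pair.iqr1)
    eta = eta + np.log(rr2) * (true_pair.exp2 / true_pair.iqr2)
    mu = np.exp(eta)
    if not np.all(np.isfinite(mu)):
        bad = int(np.flatnonzero(~np.isfinite(mu))[0])
        zip_id, day = design.index.iloc[bad]
        raise ValueError(f"non-finite Poisson mean at zip {zip_id}, day {day}")
    return mu


def simulate_counts(
    design: HealthDesign,
    B: np.ndarray | pd.Series,
    true_pair,
    rr1: float,
    rr2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent Poisson draws with mean :func:`poisson_mean` per row.

    ``true_pair`` supplies the simulated true exposures and their IQRs,
    row-aligned with the design.
    """
    return rng.poisson(poisson_mean(design, B, true_pair, rr1, rr2))


@dataclass(frozen=True)
class FitResult:
    """Pollutant coefficients from one copollutant Poisson fit.

    ``beta1``/``beta2`` are log relative risks per IQR; ``se1``/``se2``
    their asymptotic standard errors.  ``converged`` is False for IRLS
    non-convergence or a degenerate exposure block, with the reason in
    ``message``.
    """

    beta1: float
    beta2: float
    se1: float
    se2: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class PoissonFit:
    """Result of one Poisson IRLS fit."""

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    n_iter: int

    @property
    def fit_history(self) -> dict:
        return {"iterations": self.n_iter, "llf": self.llf}


def fit_poisson(
    X: np.ndarray,
    counts: np.ndarray,
    start_params: np.ndarray | None = None,
    tol: float = _IRLS_TOL,
    maxiter: int = _IRLS_MAXITER,
) -> PoissonFit:
    """Poisson maximum-likelihood fit by iteratively reweighted least squares.

    Each step solves the weighted normal equations by Cholesky
    factorization; convergence is a relative log-likelihood change below
    ``tol``.  The asymptotic covariance is the inverse Fisher information
    at the final iterate.  Raises ``numpy.linalg.LinAlgError`` for a
    singular information matrix (rank-deficient design).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(counts, dtype=float)
    n, p = X.shape
    if start_params is not None:
        beta = np.asarray(start_params, dtype=float).copy()
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
    else:
        # standard GLM starting values: mu0 = y + 0.5
        eta = np.log(y + 0.5)
    mu = np.exp(eta)
    llf_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, maxiter + 1):
        z = eta + (y - mu) / mu
        xw = X * mu[:, None]
        info = xw.T @ X
        beta = scipy.linalg.solve(info, xw.T @ z, assume_a="pos")
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        llf = float(y @ eta - mu.sum())
        if abs(llf - llf_old) < tol * (abs(llf) + tol):
            converged = True
            break
        llf_old = llf
    info = (X * mu[:, None]).T @ X
    cov = scipy.linalg.inv(info)
    return PoissonFit(
        params=beta,
        bse=np.sqrt(np.diag(cov)),
        cov_params=cov,
        llf=float(y @ eta - mu.sum()),
        converged=converged,
        n_iter=n_iter,
    )


def fit_copollutant_model(
    design: HealthDesign,
    counts: np.ndarray,
    exp1_std: np.ndarray,
    exp2_std: np.ndarray,
    start_params: np.ndarray | None = None,
) -> FitResult:
    """Fit the two-pollutant Poisson model and extract the pollutant terms.

    ``exp1_std`` and ``exp2_std`` must already be standardized by their
    IQRs and row-aligned with the design.  Degenerate exposure blocks
    (constant column, or the two exposures collinear with each other or the
    covariates) are flagged, not raised, as are non-converged fits.
    ``start_params`` (length ``n_cols``, covariates only) warm-starts IRLS.
    """
    counts = np.asarray(counts)
    e = np.column_stack([np.asarray(exp1_std, float), np.asarray(exp2_std, float)])
    if e.shape[0] != design.n_rows:
        raise ValueError("exposure length does not match design rows")

    resid = design.residualize(e)
    sv = np.linalg.svd(resid, compute_uv=False)
    scale = max(np.linalg.norm(e), 1.0)
    if sv[-1] < 1e-8 * scale:
        return FitResult(
            np.nan, np.nan, np.nan, np.nan, False,
            "exposure columns rank deficient given the covariate design",
        )

    X = np.hstack([design.X, e])
    sp = None
    if start_params is not None:
        sp = np.concatenate([np.asarray(start_params, float), [0.0, 0.0]])
    try:
        res = fit_poisson(X, counts, start_params=sp)
        if not res.converged and sp is not None:
            res = fit_poisson(X, counts)
    except np.linalg.LinAlgError as exc:
        return FitResult(
            np.nan, np.nan, np.nan, np.nan, False,
            f"singular information matrix: {exc}",
        )
    converged = res.converged
    b = res.params[-2:]
    se = res.bse[-2:]
    msg = "" if converged else "IRLS did not converge"
    if converged and not np.all(np.isfinite(se)):
        converged, msg = False, "non-finite standard errors"
    return FitResult(
        float(b[0]), float(b[1]), float(se[0]), float(se[1]), converged, msg
    )
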