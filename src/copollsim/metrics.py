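"""Summary statistics over Monte Carlo iteration results.

For a stream of estimated log relative risks ``b_n`` (n = 1..N) and their
standard errors ``s_n`` from one scenario:

* mean RR            ``exp(sum(b_n)/N)``
* percent attenuation ``100 * (RR_assumed - meanRR_noisy) / (RR_assumed - 1)``
* RMSE               ``sqrt(sum((b_n - log RR_assumed)^2)/N)`` and the
  RMSE ratio ``RMSE_noisy / RMSE_true`` (bias plus precision loss)
* power / type I error: the fraction of iterations whose standardized
  coefficient passes the 1.96 threshold, with binomial standard error
  ``sqrt(p(1-p)/N)``.  The default is two-sided (|z| > 1.96), which gives
  the nominal 0.05 null rate; the one-sided rule (z > 1.96) is available
  by flag.
* 95% CI coverage: fraction of iterations with the assumed log RR inside
  ``b_n +/- 1.96 s_n``.
* Welch two-sided t-test between two copollutant estimate streams.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .engine import ScenarioResult

__all__ = [
    "Z_CRIT",
    "mean_rr",
    "percent_attenuation",
    "rmse",
    "rmse_ratio",
    "power_type1",
    "ci_coverage",
    "compare_copollutants",
    "summarize_scenario",
]

#: Critical value of the standard normal for two-sided alpha = 0.05.
Z_CRIT = 1.96


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def mean_rr(betas) -> float:
    """Mean relative risk: exp of the arithmetic mean of the log RRs."""
    return float(np.exp(_as_array(betas, "betas").mean()))


def percent_attenuation(rr_assumed: float, rr_mean_noisy: float) -> float:
    """Attenuation of the estimated RR toward the null, in percent.

    Undefined for a null pollutant (``rr_assumed = 1``); may be negative
    (bias away from the null) or exceed 100.
    """
    if rr_assumed == 1:
        raise ValueError("attenuation is undefined when the assumed RR is 1")
    return 100.0 * (rr_assumed - rr_mean_noisy) / (rr_assumed - 1.0)


def rmse(betas, rr_assumed: float) -> float:
    """Root mean squared deviation of the log RRs from log(rr_assumed)."""
    b = _as_array(betas, "betas")
    return float(np.sqrt(np.mean((b - np.log(rr_assumed)) ** 2)))


def rmse_ratio(rmse_noisy: float, rmse_true: float) -> float:
    if rmse_true <= 0:
        raise ValueError("rmse_true must be > 0 for the ratio")
    return rmse_noisy / rmse_true


def power_type1(betas, ses, two_sided: bool = True) -> tuple[float, float]:
    """Rejection proportion at the 1.96 threshold and its binomial SE.

    Reads as statistical power when the pollutant has a real effect and as
    the type I error rate when it is null.
    """
    b = _as_array(betas, "betas")
    s = _as_array(ses, "ses")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    z = b / s
    hits = np.abs(z) > Z_CRIT if two_sided else z > Z_CRIT
    p = float(hits.mean())
    se = float(np.sqrt(p * (1.0 - p) / b.size))
    return p, se


def ci_coverage(betas, ses, true_log_rr: float) -> float:
    """Fraction of nominal 95% intervals containing the assumed log RR."""
    b = _as_array(betas, "betas")
    s = _as_array(ses, "ses")
    if b.shape != s.shape:
        raise ValueError("betas and ses must have equal length")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be > 0")
    lo, hi = b - Z_CRIT * s, b + Z_CRIT * s
    return float(np.mean((true_log_rr >= lo) & (true_log_rr <= hi)))


def compare_copollutants(betas_a, betas_b) -> tuple[float, float]:
    """Welch two-sided t-test between two log-RR streams for the same main
    pollutant paired with different copollutants."""
    a = _as_array(betas_a, "betas_a")
    b = _as_array(betas_b, "betas_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each stream needs at least 2 estimates")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def summarize_scenario(result: ScenarioResult, two_sided: bool = True) -> dict:
    """One row of the per-scenario metrics table.

    Emits, per pollutant and per fit (true / noisy): mean RR with the SE of
    the mean log RR (and the across-iteration SD), RMSE, rejection
    proportion with SE, and 95% CI coverage; plus percent attenuation of
    the main pollutant under the noisy fit and the two RMSE ratios.
    Attenuation and RMSE ratios are NaN when the noisy fit was skipped.
    """
    df = result.to_dataframe()
    n = len(df)
    if n == 0:
        raise ValueError("scenario has no converged iterations")
    out = {
        "pol1": result.pol1, "pol2": result.pol2,
        "error_type": result.error_type,
        "rr1": result.rr1, "rr2": result.rr2,
        "n_iterations": n, "n_failed": result.n_failed,
    }
    has_noisy = df["beta1_noisy"].notna().all()
    log_rr = {"1": np.log(result.rr1), "2": np.log(result.rr2)}
    for fit in ("true", "noisy"):
        if fit == "noisy" and not has_noisy:
            for pol in ("1", "2"):
                for k in ("mean_rr", "sd_log_rr", "se_log_rr", "rmse",
                          "reject", "reject_se", "coverage95",
                          "rr_pct_lo", "rr_pct_hi", "rr_norm_lo", "rr_norm_hi"):
                    out[f"{k}_{pol}_{fit}"] = np.nan
            continue
        for pol in ("1", "2"):
            b = df[f"beta{pol}_{fit}"].to_numpy()
            s = df[f"se{pol}_{fit}"].to_numpy()
            rr = result.rr1 if pol == "1" else result.rr2
            p, p_se = power_type1(b, s, two_sided=two_sided)
            out[f"mean_rr_{pol}_{fit}"] = mean_rr(b)
            out[f"sd_log_rr_{pol}_{fit}"] = float(b.std(ddof=1)) if n > 1 else np.nan
            out[f"se_log_rr_{pol}_{fit}"] = (
                float(b.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            )
            out[f"rmse_{pol}_{fit}"] = rmse(b, rr)
            out[f"reject_{pol}_{fit}"] = p
            out[f"reject_se_{pol}_{fit}"] = p_se
            out[f"coverage95_{pol}_{fit}"] = ci_coverage(b, s, log_rr[pol])
            # across-iteration bands for the RR point estimate: empirical
            # percentiles and the normal-theory counterpart, both emitted
            lo, hi = np.percentile(b, [2.5, 97.5])
            out[f"rr_pct_lo_{pol}_{fit}"] = float(np.exp(lo))
            out[f"rr_pct_hi_{pol}_{fit}"] = float(np.exp(hi))
            sd = b.std(ddof=1) if n > 1 else 0.0
            out[f"rr_norm_lo_{pol}_{fit}"] = float(np.exp(b.mean() - Z_CRIT * sd))
            out[f"rr_norm_hi_{pol}_{fit}"] = float(np.exp(b.mean() + Z_CRIT * sd))
    if has_noisy:
        if result.rr1 != 1:
            out["pct_attenuation_1_noisy"] = percent_attenuation(
                result.rr1, out["mean_rr_1_noisy"]
            )
        else:
            out["pct_attenuation_1_noisy"] = np.nan
        for pol in ("1", "2"):
            out[f"rmse_ratio_{pol}"] = rmse_ratio(
                out[f"rmse_{pol}_noisy"], out[f"rmse_{pol}_true"]
            )
    else:
        out["pct_attenuation_1_noisy"] = np.nan
        out["rmse_ratio_1"] = np.nan
        out["rmse_ratio_2"] = np.nan
    return out
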