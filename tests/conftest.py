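"""Shared fixtures: small two-pollutant scenarios used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from copollsim.config import (
    CalibrationDistribution,
    ConcentrationProcess,
    Pollutant,
    ScenarioConfig,
)


def make_pair_config(
    resid_sd_a: float = 0.8,
    resid_sd_b: float = 0.5,
    error_corr: float = 0.0,
    conc_corr: float = 0.0,
    theta1_sd: float = 0.0,
    theta2_sd: float = 0.0,
    theta2_mean: float = 1.0,
    n_zips: int = 2,
    n_days: int = 120,
    ar1: float = 0.0,
    seasonal_amplitude: float = 0.0,
    baseline_rate: float = 5.0,
    n_iterations: int = 4,
    seed: int = 9,
    **overrides,
) -> ScenarioConfig:
    """A minimal two-pollutant scenario (A local, B regional).

    Defaults are deliberately plain — white-noise concentrations, no bias
    heterogeneity — so tests can switch on exactly one feature at a time.
    """
    pollutants = [Pollutant("A", "local"), Pollutant("B", "regional")]
    conc = {
        "A": ConcentrationProcess(10.0, seasonal_amplitude, 2.0, ar1),
        "B": ConcentrationProcess(8.0, seasonal_amplitude, 1.5, ar1),
    }
    corr = np.array([[1.0, conc_corr], [conc_corr, 1.0]])
    ecorr = np.array([[1.0, error_corr], [error_corr, 1.0]])
    calib = {
        "A": {
            "spatial": CalibrationDistribution(
                0.0, theta1_sd, theta2_mean, theta2_sd, resid_sd_a
            ),
            "population": CalibrationDistribution(
                0.0, theta1_sd, theta2_mean, theta2_sd, 0.5 * resid_sd_a
            ),
        },
        "B": {
            "spatial": CalibrationDistribution(
                0.0, theta1_sd, theta2_mean, theta2_sd, resid_sd_b
            ),
            "population": CalibrationDistribution(
                0.0, theta1_sd, theta2_mean, theta2_sd, 0.5 * resid_sd_b
            ),
        },
    }
    return ScenarioConfig(
        n_zips=n_zips,
        n_days=n_days,
        pollutants=pollutants,
        n_hospitals=2,
        concentration_params=conc,
        concentration_correlation=corr,
        calibration_params=calib,
        error_correlation=ecorr,
        baseline_rate=baseline_rate,
        rr_main=1.05,
        rr_co=1.0,
        n_iterations=n_iterations,
        seed=seed,
        **overrides,
    )


def zero_error_config(**kw) -> ScenarioConfig:
    """All calibrations degenerate at the identity: CS = AQ = PE."""
    kw.setdefault("resid_sd_a", 0.0)
    kw.setdefault("resid_sd_b", 0.0)
    return make_pair_config(**kw)


def pin_identity_calibration(calib):
    """Overwrite a CalibrationSet with exact theta = (0, 1), zero theta
    covariance and zero residual covariance (degenerate-draw setting)."""
    calib.theta.loc[:, ["theta1", "theta2"]] = [0.0, 1.0]
    calib.theta.loc[:, ["cov11", "cov12", "cov22", "resid_var"]] = 0.0
    for z in calib.resid_cov:
        calib.resid_cov[z].loc[:, :] = 0.0
    return calib


@pytest.fixture(scope="session")
def tiny_config() -> ScenarioConfig:
    return make_pair_config()


@pytest.fixture(scope="session")
def tiny_inputs(tiny_config):
    from copollsim.engine import prepare_inputs

    return prepare_inputs(tiny_config)
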