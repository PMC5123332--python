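import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copollsim.error_models import (
    ErrorModelError,
    compute_error_panel,
    fit_calibrations,
)
from copollsim.synthetic_data import generate_exposure_panel

from conftest import make_pair_config, zero_error_config


def _cell_panel(cs, aq, pe):
    rows = []
    for metric, value in (("CS", cs), ("AQ", aq), ("PE", pe)):
        rows.append(
            {"zip_id": 0, "day": 0, "pollutant": "X", "metric": metric,
             "value": value}
        )
    return pd.DataFrame(rows)


class TestErrorPanel:
    def test_single_cell_arithmetic(self):
        err = compute_error_panel(_cell_panel(3.0, 5.0, 4.0)).set_index("error_type")
        assert err.loc["spatial", "delta"] == 2.0
        assert err.loc["population", "delta"] == -1.0
        assert err.loc["total", "delta"] == 1.0

    def test_spatial_error_zero_when_aq_equals_cs(self):
        panel = generate_exposure_panel(zero_error_config())
        err = compute_error_panel(panel)
        assert np.allclose(err[err.error_type == "spatial"]["delta"], 0.0)

    def test_additivity_identity_on_generated_panel(self):
        panel = generate_exposure_panel(
            make_pair_config(resid_sd_a=1.2, theta1_sd=0.2, theta2_sd=0.1)
        )
        err = compute_error_panel(panel)
        wide = err.pivot_table(
            index=["zip_id", "day", "pollutant"], columns="error_type",
            values="delta",
        )
        gap = (wide["spatial"] + wide["population"] - wide["total"]).abs()
        assert gap.max() < 1e-9

    @given(
        cs=st.floats(-50, 50), d1=st.floats(-20, 20), d2=st.floats(-20, 20)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_additivity_identity_property(self, cs, d1, d2):
        err = compute_error_panel(_cell_panel(cs, cs + d1, cs + d1 + d2))
        wide = err.set_index("error_type")["delta"]
        assert wide["spatial"] + wide["population"] == pytest.approx(
            wide["total"], abs=1e-9
        )

    def test_missing_metric_named_in_error(self):
        panel = _cell_panel(1.0, 2.0, 3.0)
        panel = panel[panel.metric != "PE"]
        with pytest.raises(ErrorModelError, match="PE"):
            compute_error_panel(panel)


class TestFitCalibrations:
    def test_noiseless_line_recovered_exactly(self):
        # AQ = 1 + 2 * CS with no residual: theta = (1, 2), covariances ~ 0
        cfg = make_pair_config(resid_sd_a=0.0, resid_sd_b=0.0)
        panel = generate_exposure_panel(cfg)
        aq = panel.metric == "AQ"
        cs_vals = panel[panel.metric == "CS"].sort_values(
            ["zip_id", "day", "pollutant"]
        )["value"].to_numpy()
        panel.loc[aq, "value"] = 1.0 + 2.0 * cs_vals
        pe = panel.metric == "PE"
        panel.loc[pe, "value"] = 1.0 + 2.0 * cs_vals
        calib = fit_calibrations(panel, "spatial")
        for zip_id in calib.zip_ids:
            for pol in ("A", "B"):
                theta, cov = calib.theta_for(zip_id, pol)
                assert theta == pytest.approx([1.0, 2.0], abs=1e-8)
                assert np.abs(cov).max() < 1e-12
            assert np.abs(calib.resid_cov[zip_id].to_numpy()).max() < 1e-12

    def test_identity_panel_gives_unit_calibration(self):
        panel = generate_exposure_panel(zero_error_config())
        calib = fit_calibrations(panel, "total")
        for zip_id in calib.zip_ids:
            for pol in ("A", "B"):
                theta, _ = calib.theta_for(zip_id, pol)
                assert theta == pytest.approx([0.0, 1.0], abs=1e-8)

    def test_parameter_recovery_against_generator(self):
        # 5000 days: theta-hat within 3 asymptotic SEs of the generator's
        # realized theta; residual covariance within 10% of configured
        cfg = make_pair_config(
            resid_sd_a=1.0, resid_sd_b=0.6, error_corr=0.5, n_days=5000,
            theta1_sd=0.3, theta2_sd=0.1,
        )
        panel, truth = generate_exposure_panel(cfg, return_truth=True)
        calib = fit_calibrations(panel, "spatial")
        target = np.array([[1.0, 0.5 * 0.6], [0.5 * 0.6, 0.36]])
        for zip_id in calib.zip_ids:
            for pol in ("A", "B"):
                row = truth[
                    (truth.zip_id == zip_id) & (truth.pollutant == pol)
                    & (truth.stage == "spatial")
                ].iloc[0]
                theta, cov = calib.theta_for(zip_id, pol)
                se = np.sqrt(np.diag(cov))
                assert np.all(
                    np.abs(theta - [row.theta1, row.theta2]) < 3 * se
                )
            emp = calib.resid_cov[zip_id].loc[["A", "B"], ["A", "B"]].to_numpy()
            assert np.allclose(emp, target, rtol=0.10)

    def test_uncorrelated_errors_give_near_zero_cross_covariance(self):
        cfg = make_pair_config(
            resid_sd_a=1.0, resid_sd_b=0.8, error_corr=0.0, n_days=5000
        )
        panel = generate_exposure_panel(cfg)
        calib = fit_calibrations(panel, "spatial")
        for zip_id in calib.zip_ids:
            mat = calib.resid_cov[zip_id]
            bound = 0.05 * np.sqrt(mat.loc["A", "A"] * mat.loc["B", "B"])
            assert abs(mat.loc["A", "B"]) < bound

    def test_diagonal_matches_single_fit_residual_variance(self):
        panel = generate_exposure_panel(make_pair_config(resid_sd_a=1.0))
        calib = fit_calibrations(panel, "spatial")
        for zip_id in calib.zip_ids:
            for pol in ("A", "B"):
                row = calib.theta[
                    (calib.theta.zip_id == zip_id) & (calib.theta.pollutant == pol)
                ].iloc[0]
                assert calib.resid_cov[zip_id].loc[pol, pol] == pytest.approx(
                    row["resid_var"], rel=1e-10
                )

    def test_residual_means_are_zero_per_zip(self):
        # OLS with intercept: reconstruction from theta reproduces the
        # refined metric up to residuals with zero mean within each ZIP
        panel = generate_exposure_panel(make_pair_config(resid_sd_a=1.3))
        calib = fit_calibrations(panel, "spatial")
        wide = panel.pivot_table(
            index=["zip_id", "day", "pollutant"], columns="metric", values="value"
        ).reset_index()
        for zip_id in calib.zip_ids:
            for pol in ("A", "B"):
                sub = wide[(wide.zip_id == zip_id) & (wide.pollutant == pol)]
                theta, _ = calib.theta_for(zip_id, pol)
                resid = sub["AQ"] - (theta[0] + theta[1] * sub["CS"])
                assert resid.mean() == pytest.approx(0.0, abs=1e-10)

    def test_constant_predictor_rejected(self):
        panel = generate_exposure_panel(make_pair_config(n_days=60))
        panel.loc[panel.metric == "CS", "value"] = 7.0
        with pytest.raises(ErrorModelError, match="constant predictor"):
            fit_calibrations(panel, "spatial")

    def test_population_error_uses_aq_as_predictor(self):
        # make PE an exact line in AQ but not in CS; the population fit
        # must be noiseless while the total fit is not
        cfg = make_pair_config(resid_sd_a=1.0, resid_sd_b=1.0)
        panel = generate_exposure_panel(cfg)
        aq_vals = panel[panel.metric == "AQ"].sort_values(
            ["zip_id", "day", "pollutant"]
        )["value"].to_numpy()
        panel.loc[panel.metric == "PE", "value"] = 0.5 + 1.5 * aq_vals
        pop = fit_calibrations(panel, "population")
        tot = fit_calibrations(panel, "total")
        theta, _ = pop.theta_for(0, "A")
        assert theta == pytest.approx([0.5, 1.5], abs=1e-8)
        assert pop.resid_cov[0].loc["A", "A"] < 1e-12
        assert tot.resid_cov[0].loc["A", "A"] > 0.1

    def test_csv_audit_dump(self, tmp_path):
        panel = generate_exposure_panel(make_pair_config(n_days=60))
        calib = fit_calibrations(panel, "spatial")
        tpath, rpath = tmp_path / "theta.csv", tmp_path / "residcov.csv"
        calib.to_csv(tpath, rpath)
        theta = pd.read_csv(tpath)
        rc = pd.read_csv(rpath)
        assert len(theta) == 2 * 2  # zips x pollutants
        assert len(rc) == 2 * 3  # zips x upper-triangle pairs
        assert set(theta["error_type"]) == {"spatial"}
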