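import numpy as np
import pandas as pd
import pytest

from copollsim.config import default_config
from copollsim.engine import prepare_inputs
from copollsim.error_models import compute_error_panel
from copollsim.health_model import build_design_matrix, fit_poisson
from copollsim.synthetic_data import (
    covariates_from_csv,
    covariates_to_csv,
    fit_baseline_coefficients,
    generate_covariates,
    generate_exposure_panel,
    make_baseline_coefficients,
    panel_from_csv,
    panel_to_csv,
    simulate_baseline_counts,
)

from conftest import make_pair_config, zero_error_config


def _metric_wide(panel, metric):
    sub = panel[panel["metric"] == metric]
    return sub.pivot_table(
        index=["zip_id", "day"], columns="pollutant", values="value"
    )


class TestExposurePanel:
    def test_zero_noise_calibration_is_exact_line(self):
        # residual sd 0, theta fixed at (0, 2): AQ = 2 * CS exactly
        cfg = make_pair_config(resid_sd_a=0.0, resid_sd_b=0.0, theta2_mean=2.0)
        panel, truth = generate_exposure_panel(cfg, return_truth=True)
        cs = _metric_wide(panel, "CS")
        aq = _metric_wide(panel, "AQ")
        assert np.allclose(aq.to_numpy(), 2.0 * cs.to_numpy(), atol=1e-12)

    def test_identity_calibration_makes_all_metrics_equal(self):
        panel = generate_exposure_panel(zero_error_config())
        cs, aq, pe = (_metric_wide(panel, m) for m in ("CS", "AQ", "PE"))
        assert np.allclose(cs, aq, atol=1e-12)
        assert np.allclose(aq, pe, atol=1e-12)

    def test_cs_identical_across_zips(self):
        panel = generate_exposure_panel(make_pair_config(resid_sd_a=1.0))
        cs = _metric_wide(panel, "CS").reset_index()
        per_day = cs.groupby("day")[["A", "B"]].nunique()
        assert (per_day == 1).all().all()

    def test_one_value_per_cell(self):
        cfg = make_pair_config(n_days=60)
        panel = generate_exposure_panel(cfg)
        assert len(panel) == cfg.n_zips * cfg.n_days * 2 * 3
        assert not panel.duplicated(["zip_id", "day", "pollutant", "metric"]).any()

    def test_reproducible_and_seed_sensitive(self):
        cfg = make_pair_config()
        a = generate_exposure_panel(cfg, seed=5)
        b = generate_exposure_panel(cfg, seed=5)
        c = generate_exposure_panel(cfg, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a["value"].equals(c["value"])

    def test_error_correlation_recovered_at_large_n(self):
        # rho = 0.6, residual sd 1 on both pollutants, 5000 days: the sample
        # correlation of the generated calibration residuals is close to rho
        cfg = make_pair_config(
            resid_sd_a=1.0, resid_sd_b=1.0, error_corr=0.6, n_days=5000
        )
        panel, truth = generate_exposure_panel(cfg, return_truth=True)
        cs, aq = _metric_wide(panel, "CS"), _metric_wide(panel, "AQ")
        for zip_id in range(cfg.n_zips):
            resid = {}
            for pol in ("A", "B"):
                row = truth[
                    (truth.zip_id == zip_id)
                    & (truth.pollutant == pol)
                    & (truth.stage == "spatial")
                ].iloc[0]
                x = cs.xs(zip_id, level="zip_id")[pol]
                y = aq.xs(zip_id, level="zip_id")[pol]
                resid[pol] = y - (row.theta1 + row.theta2 * x)
            rho = np.corrcoef(resid["A"], resid["B"])[0, 1]
            assert rho == pytest.approx(0.6, abs=0.05)

    def test_error_covariance_converges_to_configured(self):
        cfg = make_pair_config(resid_sd_a=1.5, resid_sd_b=0.7, error_corr=0.4,
                               n_days=5000)
        panel, truth = generate_exposure_panel(cfg, return_truth=True)
        cs, aq = _metric_wide(panel, "CS"), _metric_wide(panel, "AQ")
        target = np.array([[1.5**2, 0.4 * 1.5 * 0.7], [0.4 * 1.5 * 0.7, 0.7**2]])
        resid = []
        for pol in ("A", "B"):
            row = truth[
                (truth.zip_id == 0) & (truth.pollutant == pol)
                & (truth.stage == "spatial")
            ].iloc[0]
            x = cs.xs(0, level="zip_id")[pol]
            y = aq.xs(0, level="zip_id")[pol]
            resid.append(y - (row.theta1 + row.theta2 * x))
        emp = np.cov(np.array(resid))
        assert np.allclose(emp, target, rtol=0.10)

    def test_local_pollutants_noisier_than_regional_by_default(self):
        # premise of the study design: local species carry more spatial
        # error relative to their day-to-day variability than regional ones
        cfg = default_config()
        panel = generate_exposure_panel(cfg)
        err = compute_error_panel(panel)
        spat = err[err.error_type == "spatial"]
        ratios = {}
        for pol in cfg.pollutant_names:
            dvar = spat[spat.pollutant == pol]["delta"].var()
            csvar = panel[
                (panel.pollutant == pol) & (panel.metric == "CS")
            ]["value"].var()
            ratios[pol] = dvar / csvar
        local = [ratios[p.name] for p in cfg.pollutants if p.spatial_class == "local"]
        regional = [
            ratios[p.name] for p in cfg.pollutants if p.spatial_class == "regional"
        ]
        assert min(local) > max(regional)

    def test_cs_autocorrelation_and_cross_correlation(self):
        cfg = make_pair_config(ar1=0.6, conc_corr=0.5, n_days=5000)
        panel = generate_exposure_panel(cfg)
        cs = _metric_wide(panel, "CS").xs(0, level="zip_id")
        a = cs["A"].to_numpy()
        lag1 = np.corrcoef(a[:-1], a[1:])[0, 1]
        assert lag1 == pytest.approx(0.6, abs=0.06)
        cross = np.corrcoef(cs["A"], cs["B"])[0, 1]
        assert cross == pytest.approx(0.5, abs=0.06)


class TestCovariates:
    def test_day_of_week_cycles_from_monday(self):
        cfg = make_pair_config(n_days=70)
        cov = generate_covariates(cfg, start_date="1999-01-04")  # a Monday
        one_zip = cov[cov.zip_id == 0].sort_values("day")
        expected = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"] * 10
        assert list(one_zip["day_of_week"]) == expected

    def test_one_row_per_zip_day_and_temperature_order(self):
        cfg = make_pair_config()
        cov = generate_covariates(cfg)
        assert len(cov) == cfg.n_zips * cfg.n_days
        assert not cov.duplicated(["zip_id", "day"]).any()
        assert (cov["max_temperature"] >= cov["min_temperature"]).all()
        assert np.isfinite(cov[["min_temperature", "dew_point"]]).all().all()

    def test_hospital_windows_contiguous_and_cover_half(self):
        cfg = make_pair_config(n_days=365)
        cov = generate_covariates(cfg)
        daily = cov[cov.zip_id == 0].sort_values("day")
        for h in range(1, cfg.n_hospitals + 1):
            active = daily[f"hospital_{h}"].to_numpy()
            assert active.sum() >= 0.5 * cfg.n_days
            on = np.flatnonzero(active)
            assert np.array_equal(on, np.arange(on[0], on[-1] + 1))

    def test_reproducibility_contract(self):
        cfg = make_pair_config()
        a = generate_covariates(cfg, seed=3)
        b = generate_covariates(cfg, seed=3)
        c = generate_covariates(cfg, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


class TestBaselineCoefficients:
    def test_recovery_at_large_baseline_rate(self):
        cfg = make_pair_config(baseline_rate=100.0, n_days=180, n_zips=3)
        cov = generate_covariates(cfg)
        design = build_design_matrix(cov)
        rng = np.random.default_rng(42)
        b_star = make_baseline_coefficients(design, cfg.baseline_rate, rng)
        counts = simulate_baseline_counts(design, b_star, rng)
        b_hat = fit_baseline_coefficients(cov, counts, design=design)
        res = fit_poisson(design.X, counts)
        z = (b_hat.to_numpy() - b_star.to_numpy()) / res.bse
        assert np.all(np.abs(z) < 3.0)

    def test_intercept_only_closed_form(self):
        counts = np.array([4, 4, 4, 4, 4, 4])
        res = fit_poisson(np.ones((6, 1)), counts)
        assert res.params[0] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_all_zero_counts_degenerate(self, tiny_config):
        cov = generate_covariates(tiny_config)
        n = len(cov)
        with pytest.raises(ValueError, match="zero"):
            fit_baseline_coefficients(cov, np.zeros(n, dtype=int))

    def test_mean_rate_matches_baseline(self, tiny_config):
        cov = generate_covariates(tiny_config)
        design = build_design_matrix(cov)
        rng = np.random.default_rng(0)
        b_star = make_baseline_coefficients(design, 7.0, rng)
        mu = np.exp(design.X @ b_star.to_numpy())
        assert mu.mean() == pytest.approx(7.0, rel=1e-6)


class TestCsvRoundTrip:
    def test_panel_round_trip(self, tmp_path):
        panel = generate_exposure_panel(make_pair_config(n_days=60))
        path = tmp_path / "panel.csv"
        panel_to_csv(panel, path)
        header = path.read_text().splitlines()[0]
        assert header == "zip_id,date,pollutant,metric,value"
        back = panel_from_csv(path)
        pd.testing.assert_frame_equal(back, panel)

    def test_covariates_round_trip(self, tmp_path):
        cov = generate_covariates(make_pair_config(n_days=60))
        path = tmp_path / "cov.csv"
        covariates_to_csv(cov, path)
        back = covariates_from_csv(path)
        assert back.shape == cov.shape
        assert back["day_of_week"].equals(cov["day_of_week"])
        np.testing.assert_allclose(back["dew_point"], cov["dew_point"])
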