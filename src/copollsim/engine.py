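"""Monte Carlo orchestration for copollutant measurement-error scenarios.

A *scenario* is one (main pollutant, copollutant, error type) cell.  Each
iteration simulates a true exposure pair, draws Poisson counts with the
assumed relative risks injected, then fits the health model twice on the
same counts: once with the simulated true exposures and once with the
unrefined (error-prone) exposures, each standardized by its own IQR.  The
noisy-exposure IQRs are those of the unrefined series, fixed across
iterations.

Reproducibility: iteration n of scenario (i, j, e) draws from the substream
``SeedSequence(master_seed, spawn_key=(5, i, j, e, n))`` where i, j index
the pollutant roster and e the error type — independent streams that make
single scenarios and interrupted grids resumable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ERROR_TYPES, ScenarioConfig
from .error_models import CalibrationSet, fit_calibrations
from .health_model import (
    HealthDesign,
    build_design_matrix,
    fit_copollutant_model,
    simulate_counts,
)
from .synthetic_data import (
    fit_baseline_coefficients,
    generate_covariates,
    generate_exposure_panel,
    make_baseline_coefficients,
    simulate_baseline_counts,
)
from .true_exposure import iqr, simulate_true_exposure, unrefined_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "IterationResult",
    "ScenarioResult",
    "PreparedInputs",
    "ScenarioInvalidError",
    "prepare_inputs",
    "run_scenario",
    "run_grid",
    "scenario_filename",
]

#: Fraction of iterations allowed to fail before a run is invalid.
FAILURE_CAP = 0.01


class ScenarioInvalidError(RuntimeError):
    """Raised when too many iterations of a scenario fail to converge."""


@dataclass(frozen=True)
class IterationResult:
    """Pollutant estimates from one Monte Carlo iteration (both fits)."""

    iteration: int
    beta1_true: float
    beta2_true: float
    se1_true: float
    se2_true: float
    beta1_noisy: float
    beta2_noisy: float
    se1_noisy: float
    se2_noisy: float
    converged_true: bool
    converged_noisy: bool


_RESULT_COLUMNS = [
    "iteration",
    "beta1_true", "beta2_true", "se1_true", "se2_true",
    "beta1_noisy", "beta2_noisy", "se1_noisy", "se2_noisy",
    "converged_true", "converged_noisy",
]


@dataclass
class ScenarioResult:
    """All iteration results for one scenario cell."""

    pol1: str
    pol2: str
    error_type: str
    rr1: float
    rr2: float
    master_seed: int
    iterations: list[IterationResult] = field(default_factory=list)
    n_failed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(it) for it in self.iterations], columns=_RESULT_COLUMNS)
        for col, val in (
            ("pol1", self.pol1), ("pol2", self.pol2),
            ("error_type", self.error_type),
            ("rr1", self.rr1), ("rr2", self.rr2),
            ("master_seed", self.master_seed), ("n_failed", self.n_failed),
        ):
            df[col] = val
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScenarioResult":
        df = pd.read_csv(path)
        required = set(_RESULT_COLUMNS) | {
            "pol1", "pol2", "error_type", "rr1", "rr2", "master_seed", "n_failed"
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(
                f"malformed scenario result file {path}: missing columns "
                f"{sorted(missing)}"
            )
        if df.empty:
            raise ValueError(f"malformed scenario result file {path}: no rows")
        head = df.iloc[0]
        its = [
            IterationResult(**{k: row[k] for k in _RESULT_COLUMNS})
            for _, row in df[_RESULT_COLUMNS].iterrows()
        ]
        return cls(
            pol1=str(head["pol1"]), pol2=str(head["pol2"]),
            error_type=str(head["error_type"]),
            rr1=float(head["rr1"]), rr2=float(head["rr2"]),
            master_seed=int(head["master_seed"]),
            iterations=its, n_failed=int(head["n_failed"]),
        )


@dataclass
class PreparedInputs:
    """Scenario-independent inputs shared across a grid run."""

    config: ScenarioConfig
    panel: pd.DataFrame
    covariates: pd.DataFrame
    design: HealthDesign
    B: np.ndarray
    calibrations: dict[str, CalibrationSet]


def prepare_inputs(
    config: ScenarioConfig,
    error_types: tuple[str, ...] = ERROR_TYPES,
) -> PreparedInputs:
    """Generate data and fit the scenario-independent structure once.

    Generates the exposure panel and covariates, builds the covariate
    design, simulates baseline counts from a known coefficient vector and
    re-fits it to obtain B (mirroring estimation of the baseline model from
    observed data), and fits the per-error-type calibration sets.
    """
    seed = config.seed
    panel = generate_exposure_panel(config, seed)
    covariates = generate_covariates(config, seed)
    design = build_design_matrix(covariates)

    rng_b = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    b_star = make_baseline_coefficients(design, config.baseline_rate, rng_b)
    rng_c = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    counts = simulate_baseline_counts(design, b_star, rng_c)
    B = fit_baseline_coefficients(covariates, counts, design=design).to_numpy()

    calibrations = {et: fit_calibrations(panel, et) for et in error_types}
    return PreparedInputs(
        config=config, panel=panel, covariates=covariates,
        design=design, B=B, calibrations=calibrations,
    )


def _scenario_key(config: ScenarioConfig, pol1: str, pol2: str, error_type: str):
    names = config.pollutant_names
    return (5, names.index(pol1), names.index(pol2), ERROR_TYPES.index(error_type))


def run_scenario(
    config: ScenarioConfig,
    panel: pd.DataFrame,
    calib: CalibrationSet,
    B: np.ndarray,
    design: HealthDesign,
    pol1: str,
    pol2: str,
    error_type: str,
    master_seed: int | None = None,
    n_iterations: int | None = None,
    include_noisy: bool = True,
) -> ScenarioResult:
    """Run the Monte Carlo experiment for one scenario cell.

    ``include_noisy=False`` skips the unrefined-exposure refit (the
    noisy-side columns are NaN), halving the cost when only the
    no-measurement-error behaviour is of interest.
    """
    master_seed = config.seed if master_seed is None else master_seed
    n_iter = config.n_iterations if n_iterations is None else n_iterations
    key = _scenario_key(config, pol1, pol2, error_type)

    # unrefined (noisy) exposures are fixed across iterations
    w1 = unrefined_matrix(panel, pol1, error_type)
    w2 = unrefined_matrix(panel, pol2, error_type)
    w1_flat, w2_flat = w1.to_numpy().ravel(), w2.to_numpy().ravel()
    noisy1 = w1_flat / iqr(w1_flat)
    noisy2 = w2_flat / iqr(w2_flat)

    result = ScenarioResult(
        pol1=pol1, pol2=pol2, error_type=error_type,
        rr1=config.rr_main, rr2=config.rr_co, master_seed=master_seed,
    )
    failures: list[str] = []
    for n in range(n_iter):
        rng = np.random.default_rng(
            np.random.SeedSequence(master_seed, spawn_key=key + (n,))
        )
        pair = simulate_true_exposure(panel, calib, pol1, pol2, error_type, rng)
        counts = simulate_counts(
            design, B, pair, config.rr_main, config.rr_co, rng
        )
        fit_true = fit_copollutant_model(
            design, counts, pair.exp1 / pair.iqr1, pair.exp2 / pair.iqr2,
            start_params=B,
        )
        if include_noisy:
            fit_noisy = fit_copollutant_model(
                design, counts, noisy1, noisy2, start_params=B
            )
        else:
            from .health_model import FitResult

            fit_noisy = FitResult(np.nan, np.nan, np.nan, np.nan, True, "skipped")
        if fit_true.converged and fit_noisy.converged:
            result.iterations.append(
                IterationResult(
                    iteration=n,
                    beta1_true=fit_true.beta1, beta2_true=fit_true.beta2,
                    se1_true=fit_true.se1, se2_true=fit_true.se2,
                    beta1_noisy=fit_noisy.beta1, beta2_noisy=fit_noisy.beta2,
                    se1_noisy=fit_noisy.se1, se2_noisy=fit_noisy.se2,
                    converged_true=True, converged_noisy=fit_noisy.converged,
                )
            )
        else:
            result.n_failed += 1
            failures.append(
                f"iteration {n}: true[{fit_true.message or 'ok'}] "
                f"noisy[{fit_noisy.message or 'ok'}]"
            )
            logger.warning(
                "scenario (%s, %s, %s): dropped %s", pol1, pol2, error_type,
                failures[-1],
            )
    if result.n_failed > FAILURE_CAP * n_iter:
        raise ScenarioInvalidError(
            f"scenario ({pol1}, {pol2}, {error_type}): {result.n_failed}/"
            f"{n_iter} iterations failed (cap {FAILURE_CAP:.0%}); "
            + "; ".join(failures[:5])
        )
    return result


def scenario_filename(pol1: str, pol2: str, error_type: str) -> str:
    safe = lambda s: s.replace("/", "-").replace(".", "")
    return f"scenario_{safe(pol1)}_{safe(pol2)}_{error_type}.csv"


def run_grid(
    config: ScenarioConfig,
    inputs: PreparedInputs | None = None,
    out_dir: str | Path | None = None,
    error_types: tuple[str, ...] = ERROR_TYPES,
    pairs: list[tuple[str, str]] | None = None,
    n_iterations: int | None = None,
) -> list[ScenarioResult]:
    """Run every (main, copollutant, error type) scenario cell.

    With ``out_dir`` set, each completed scenario is written to CSV and any
    cell whose file already exists is loaded instead of re-run, making an
    interrupted grid resumable.  Scenario failures are logged and skipped
    without aborting the remaining cells.
    """
    if inputs is None:
        inputs = prepare_inputs(config, error_types=error_types)
    if pairs is None:
        names = config.pollutant_names
        pairs = [(a, b) for a in names for b in names if a != b]
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    results = []
    total = len(pairs) * len(error_types)
    done = 0
    for error_type in error_types:
        for pol1, pol2 in pairs:
            done += 1
            fname = out_path / scenario_filename(pol1, pol2, error_type) if out_path else None
            if fname is not None and fname.exists():
                logger.info("[%d/%d] loading existing %s", done, total, fname.name)
                results.append(ScenarioResult.from_csv(fname))
                continue
            logger.info(
                "[%d/%d] running scenario main=%s co=%s error=%s",
                done, total, pol1, pol2, error_type,
            )
            try:
                res = run_scenario(
                    config, inputs.panel, inputs.calibrations[error_type],
                    inputs.B, inputs.design, pol1, pol2, error_type,
                    n_iterations=n_iterations,
                )
            except ScenarioInvalidError as exc:
                logger.error("scenario failed: %s", exc)
                continue
            if fname is not None:
                res.to_csv(fname)
            results.append(res)
    return results
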