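"""Scenario configuration for the copollutant measurement-error simulation.

A :class:`ScenarioConfig` fully describes one synthetic study: the panel
dimensions (ZIP areas x days), the six-pollutant roster with its local /
regional split, the daily concentration processes, the ZIP-level linear
calibrations linking the three exposure metrics (central-site CS, air-quality
model AQ, population exposure PE), the between-pollutant error correlation,
and the health-simulation settings (baseline emergency-department visit rate,
assumed relative risks per IQR, Monte Carlo iteration count, master seed).

Configurations round-trip to YAML; unknown keys are rejected at every level
so a typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "Pollutant",
    "ConcentrationProcess",
    "CalibrationDistribution",
    "ScenarioConfig",
    "default_config",
    "load_config",
    "save_config",
    "ERROR_TYPES",
    "CALIBRATION_STAGES",
    "METRICS",
    "START_DATE",
]

#: The three measurement-error decompositions handled downstream.
ERROR_TYPES = ("spatial", "population", "total")

#: The two generative calibration stages (CS -> AQ, AQ -> PE).
CALIBRATION_STAGES = ("spatial", "population")

#: Exposure metrics, from least to most refined.
METRICS = ("CS", "AQ", "PE")

#: Calendar origin of every synthetic panel (day 0).
START_DATE = "1999-01-01"


class ConfigError(ValueError):
    """Raised when a scenario configuration violates an invariant."""


def _check_correlation_matrix(mat: np.ndarray, name: str, n: int) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (n, n):
        raise ConfigError(f"{name} must be {n}x{n}, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigError(f"{name} is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ConfigError(f"{name} does not have a unit diagonal")
    if np.any(np.abs(mat) > 1 + 1e-10):
        raise ConfigError(f"{name} has entries outside [-1, 1]")
    eigmin = float(np.linalg.eigvalsh(mat).min())
    if eigmin < -1e-8:
        raise ConfigError(
            f"{name} is not positive semi-definite (min eigenvalue {eigmin:.3g})"
        )
    return mat


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    missing = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING
    } - set(data)
    if missing:
        raise ConfigError(f"{context}: missing keys {sorted(missing)}")
    return cls(**data)


@dataclass(frozen=True)
class Pollutant:
    """A pollutant label with its spatial-source class.

    ``local`` species (CO, NOx, EC) are dominated by nearby sources and carry
    larger, more correlated exposure error than ``regional`` species
    (PM2.5, SO4, O3) transported over long distances.
    """

    name: str
    spatial_class: str

    def __post_init__(self):
        if self.spatial_class not in ("local", "regional"):
            raise ConfigError(
                f"pollutant {self.name!r}: spatial_class must be 'local' or "
                f"'regional', got {self.spatial_class!r}"
            )


@dataclass(frozen=True)
class ConcentrationProcess:
    """Daily central-site concentration process for one pollutant.

    The CS series is a seasonal sinusoid plus a stationary AR(1) deviation:
    ``CS_t = level + amplitude * cos(2*pi*(doy - peak_day)/365.25) + z_t``
    with ``z_t = ar1 * z_{t-1} + innovation`` scaled so the stationary
    standard deviation of ``z`` equals ``daily_sd``.  Units are the
    pollutant's native concentration units.
    """

    level: float
    seasonal_amplitude: float
    daily_sd: float
    ar1: float
    peak_day: int = 15

    def __post_init__(self):
        if self.daily_sd < 0:
            raise ConfigError("daily_sd must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ConfigError(f"ar1 must be in [0, 1), got {self.ar1}")


@dataclass(frozen=True)
class CalibrationDistribution:
    """Across-ZIP distribution of the linear calibration for one stage.

    Each ZIP k receives one draw ``theta1 ~ N(theta1_mean, theta1_sd^2)``
    (additive bias, concentration units) and ``theta2 ~ N(theta2_mean,
    theta2_sd^2)`` (multiplicative bias, unitless), held constant across
    days.  ``resid_sd`` is the day-level residual standard deviation of the
    refined metric around the calibration line.
    """

    theta1_mean: float
    theta1_sd: float
    theta2_mean: float
    theta2_sd: float
    resid_sd: float

    def __post_init__(self):
        if self.theta1_sd < 0 or self.theta2_sd < 0 or self.resid_sd < 0:
            raise ConfigError("calibration standard deviations must be >= 0")


@dataclass
class ScenarioConfig:
    """Complete description of one simulation scenario family."""

    n_zips: int
    n_days: int
    pollutants: list[Pollutant]
    n_hospitals: int
    concentration_params: dict[str, ConcentrationProcess]
    concentration_correlation: np.ndarray
    calibration_params: dict[str, dict[str, CalibrationDistribution]]
    error_correlation: np.ndarray
    baseline_rate: float
    rr_main: float
    rr_co: float
    n_iterations: int
    seed: int

    def __post_init__(self):
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        if self.n_zips < 2:
            raise ConfigError(f"n_zips must be >= 2, got {self.n_zips}")
        if self.n_days < 60:
            raise ConfigError(
                f"n_days must be >= 60 (monthly-knot spline needs >= 2 "
                f"months), got {self.n_days}"
            )
        if self.n_hospitals < 1:
            raise ConfigError("n_hospitals must be >= 1")
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        if self.rr_main <= 0 or self.rr_co <= 0:
            raise ConfigError("rr_main and rr_co must be > 0")
        if self.baseline_rate <= 0:
            raise ConfigError("baseline_rate must be > 0")
        names = [p.name for p in self.pollutants]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate pollutant names in {names}")
        if len(names) < 2:
            raise ConfigError("need at least two pollutants")
        if set(self.concentration_params) != set(names):
            raise ConfigError(
                "concentration_params must cover exactly the configured "
                f"pollutants {names}"
            )
        if set(self.calibration_params) != set(names):
            raise ConfigError(
                f"calibration_params must cover exactly the pollutants {names}"
            )
        for pol, stages in self.calibration_params.items():
            if set(stages) != set(CALIBRATION_STAGES):
                raise ConfigError(
                    f"calibration_params[{pol!r}] must have stages "
                    f"{CALIBRATION_STAGES}, got {sorted(stages)}"
                )
        n = len(names)
        self.concentration_correlation = _check_correlation_matrix(
            self.concentration_correlation, "concentration_correlation", n
        )
        self.error_correlation = _check_correlation_matrix(
            self.error_correlation, "error_correlation", n
        )

    # -- convenience ----------------------------------------------------

    @property
    def pollutant_names(self) -> list[str]:
        return [p.name for p in self.pollutants]

    def spatial_class(self, name: str) -> str:
        for p in self.pollutants:
            if p.name == name:
                return p.spatial_class
        raise KeyError(name)

    def replace(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with the given top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_zips": self.n_zips,
            "n_days": self.n_days,
            "pollutants": [
                {"name": p.name, "spatial_class": p.spatial_class}
                for p in self.pollutants
            ],
            "n_hospitals": self.n_hospitals,
            "concentration_params": {
                k: dataclasses.asdict(v) for k, v in self.concentration_params.items()
            },
            "concentration_correlation": self.concentration_correlation.tolist(),
            "calibration_params": {
                pol: {st: dataclasses.asdict(d) for st, d in stages.items()}
                for pol, stages in self.calibration_params.items()
            },
            "error_correlation": self.error_correlation.tolist(),
            "baseline_rate": self.baseline_rate,
            "rr_main": self.rr_main,
            "rr_co": self.rr_co,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys {sorted(unknown)}")
        missing = known - set(data)
        if missing:
            raise ConfigError(f"missing configuration keys {sorted(missing)}")
        pollutants = [
            _from_mapping(Pollutant, p, f"pollutants[{i}]")
            for i, p in enumerate(data["pollutants"])
        ]
        conc = {
            k: _from_mapping(ConcentrationProcess, v, f"concentration_params[{k!r}]")
            for k, v in data["concentration_params"].items()
        }
        calib = {}
        for pol, stages in data["calibration_params"].items():
            if not isinstance(stages, dict):
                raise ConfigError(f"calibration_params[{pol!r}] must be a mapping")
            calib[pol] = {
                st: _from_mapping(
                    CalibrationDistribution,
                    d,
                    f"calibration_params[{pol!r}][{st!r}]",
                )
                for st, d in stages.items()
            }
        return cls(
            n_zips=int(data["n_zips"]),
            n_days=int(data["n_days"]),
            pollutants=pollutants,
            n_hospitals=int(data["n_hospitals"]),
            concentration_params=conc,
            concentration_correlation=np.asarray(
                data["concentration_correlation"], dtype=float
            ),
            calibration_params=calib,
            error_correlation=np.asarray(data["error_correlation"], dtype=float),
            baseline_rate=float(data["baseline_rate"]),
            rr_main=float(data["rr_main"]),
            rr_co=float(data["rr_co"]),
            n_iterations=int(data["n_iterations"]),
            seed=int(data["seed"]),
        )


def load_config(path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path) -> None:
    """Write a scenario configuration to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Shipped default scenario
# ---------------------------------------------------------------------------

_DEFAULT_POLLUTANTS = [
    ("CO", "local"),
    ("NOx", "local"),
    ("EC", "local"),
    ("PM2.5", "regional"),
    ("SO4", "regional"),
    ("O3", "regional"),
]

# Daily concentration processes, order-of-magnitude plausible for a large
# southeastern US metro area: CO in ppm, NOx and O3 in ppb, EC / PM2.5 / SO4
# in ug/m3.  Combustion species peak in winter (stagnation), secondary
# species peak in summer (photochemistry).
_DEFAULT_CONCENTRATION = {
    "CO": ConcentrationProcess(0.6, 0.10, 0.28, 0.40, peak_day=15),
    "NOx": ConcentrationProcess(45.0, 8.0, 22.0, 0.40, peak_day=15),
    "EC": ConcentrationProcess(1.6, 0.30, 0.70, 0.40, peak_day=15),
    "PM2.5": ConcentrationProcess(16.0, 4.0, 6.0, 0.50, peak_day=196),
    "SO4": ConcentrationProcess(4.5, 1.4, 1.8, 0.50, peak_day=196),
    "O3": ConcentrationProcess(45.0, 14.0, 13.0, 0.45, peak_day=196),
}

_DEFAULT_CONCENTRATION_CORR = [
    # CO    NOx   EC    PM2.5 SO4   O3
    [1.00, 0.70, 0.65, 0.35, 0.25, -0.15],
    [0.70, 1.00, 0.65, 0.35, 0.25, -0.20],
    [0.65, 0.65, 1.00, 0.45, 0.30, -0.05],
    [0.35, 0.35, 0.45, 1.00, 0.60, 0.30],
    [0.25, 0.25, 0.30, 0.60, 1.00, 0.35],
    [-0.15, -0.20, -0.05, 0.30, 0.35, 1.00],
]

_DEFAULT_ERROR_CORR = [
    # CO    NOx   EC    PM2.5 SO4   O3
    [1.00, 0.60, 0.55, 0.25, 0.20, 0.15],
    [0.60, 1.00, 0.55, 0.25, 0.20, 0.15],
    [0.55, 0.55, 1.00, 0.30, 0.25, 0.15],
    [0.25, 0.25, 0.30, 1.00, 0.35, 0.30],
    [0.20, 0.20, 0.25, 0.35, 1.00, 0.30],
    [0.15, 0.15, 0.15, 0.30, 0.30, 1.00],
]


def _default_calibrations() -> dict[str, dict[str, CalibrationDistribution]]:
    # Residual SDs are set relative to each pollutant's day-to-day SD:
    # local species carry substantially more spatial error than regional
    # ones; the population stage adds moderate error to everything, with an
    # infiltration-style multiplicative shrinkage (theta2 < 1).
    spatial_rel = {"local": 0.50, "regional": 0.15}
    population_rel = {"local": 0.40, "regional": 0.25}
    theta2_sd = {"local": 0.15, "regional": 0.05}
    out: dict[str, dict[str, CalibrationDistribution]] = {}
    for name, klass in _DEFAULT_POLLUTANTS:
        proc = _DEFAULT_CONCENTRATION[name]
        out[name] = {
            "spatial": CalibrationDistribution(
                theta1_mean=0.0,
                theta1_sd=0.05 * proc.level,
                theta2_mean=1.0,
                theta2_sd=theta2_sd[klass],
                resid_sd=spatial_rel[klass] * proc.daily_sd,
            ),
            "population": CalibrationDistribution(
                theta1_mean=0.02 * proc.level,
                theta1_sd=0.05 * proc.level,
                theta2_mean=0.85,
                theta2_sd=theta2_sd[klass],
                resid_sd=population_rel[klass] * proc.daily_sd,
            ),
        }
    return out


def default_config(**overrides) -> ScenarioConfig:
    """The shipped desk-scale scenario.

    15 ZIP areas x 730 days x 6 hospitals, baseline 2 expected ED visits per
    ZIP-day, main-pollutant relative risk 1.05 per IQR, null copollutant,
    200 Monte Carlo iterations.
    """
    cfg = ScenarioConfig(
        n_zips=15,
        n_days=730,
        pollutants=[Pollutant(n, c) for n, c in _DEFAULT_POLLUTANTS],
        n_hospitals=6,
        concentration_params=dict(_DEFAULT_CONCENTRATION),
        concentration_correlation=np.asarray(_DEFAULT_CONCENTRATION_CORR),
        calibration_params=_default_calibrations(),
        error_correlation=np.asarray(_DEFAULT_ERROR_CORR),
        baseline_rate=2.0,
        rr_main=1.05,
        rr_co=1.0,
        n_iterations=200,
        seed=20161125,
    )
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg
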