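"""Result tables and figures for a directory of scenario result files.

:func:`report` is a pure function of the per-scenario CSV files: it rebuilds
the per-scenario metrics table and renders

* an attenuation table — percent attenuation of the main-pollutant RR under
  the noisy fit, one row per main pollutant, one column per error type,
  cells showing the min–max range across copollutants;
* an RMSE-ratio table — one row per (main pollutant, copollutant) pair,
  main and copollutant ratios per error type;
* an RR point-estimate figure with across-iteration 2.5th–97.5th percentile
  bars (normal-theory bands are in the metrics CSV, labeled);
* a copollutant type-I-error figure with a reference line at 0.05.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .config import ERROR_TYPES, ScenarioConfig
from .engine import ScenarioResult
from .metrics import summarize_scenario

__all__ = [
    "load_results",
    "metrics_table",
    "attenuation_table",
    "rmse_ratio_table",
    "report",
    "write_manifest",
]


def load_results(results_dir) -> list[ScenarioResult]:
    """Load every ``scenario_*.csv`` in a directory."""
    paths = sorted(Path(results_dir).glob("scenario_*.csv"))
    if not paths:
        raise FileNotFoundError(
            f"no scenario result files (scenario_*.csv) in {results_dir}"
        )
    return [ScenarioResult.from_csv(p) for p in paths]


def metrics_table(
    results: list[ScenarioResult], two_sided: bool = True
) -> pd.DataFrame:
    """Per-scenario summary metrics, one row per scenario."""
    rows = [summarize_scenario(r, two_sided=two_sided) for r in results]
    return pd.DataFrame(rows).sort_values(
        ["error_type", "pol1", "pol2"], ignore_index=True
    )


def _fmt_range(values: pd.Series) -> str:
    lo, hi = values.min(), values.max()
    if np.isnan(lo):
        return "-"
    if round(lo) == round(hi):
        return f"{lo:.0f}%"
    return f"{lo:.0f}-{hi:.0f}%"


def attenuation_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Main-pollutant attenuation ranges across copollutants.

    Rows: main pollutant; columns: error type; cell: min-max percent
    attenuation of the noisy-fit RR across all copollutant models.
    """
    present = [e for e in ERROR_TYPES if e in set(metrics["error_type"])]
    tab = metrics.pivot_table(
        index="pol1",
        columns="error_type",
        values="pct_attenuation_1_noisy",
        aggfunc=_fmt_range,
    )
    return tab.reindex(columns=present)


def rmse_ratio_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """RMSE ratios (noisy/true) per pollutant pair and error type."""
    long = metrics[
        ["pol1", "pol2", "error_type", "rmse_ratio_1", "rmse_ratio_2"]
    ].rename(columns={"rmse_ratio_1": "main", "rmse_ratio_2": "co"})
    tab = long.pivot_table(
        index=["pol1", "pol2"], columns="error_type", values=["main", "co"]
    )
    tab = tab.swaplevel(axis=1).sort_index(axis=1)
    present = [e for e in ERROR_TYPES if e in set(metrics["error_type"])]
    return tab.reindex(columns=pd.MultiIndex.from_product([present, ["main", "co"]]))


def _scenario_labels(metrics: pd.DataFrame) -> list[str]:
    return [f"{r.pol1}\n{r.pol2}" for r in metrics.itertuples()]


def _fig_rr(metrics: pd.DataFrame, path: Path) -> None:
    errs = [e for e in ERROR_TYPES if e in set(metrics["error_type"])]
    fig, axes = plt.subplots(
        len(errs), 1, figsize=(max(6, 0.6 * len(metrics)), 3.2 * len(errs)),
        squeeze=False,
    )
    for ax, err in zip(axes[:, 0], errs):
        sub = metrics[metrics["error_type"] == err].reset_index(drop=True)
        x = np.arange(len(sub), dtype=float)
        for off, fit, color in ((-0.15, "true", "C0"), (0.15, "noisy", "C3")):
            mid = sub[f"mean_rr_1_{fit}"].to_numpy()
            lo = mid - sub[f"rr_pct_lo_1_{fit}"].to_numpy()
            hi = sub[f"rr_pct_hi_1_{fit}"].to_numpy() - mid
            ax.errorbar(
                x + off, mid, yerr=[lo, hi], fmt="o", ms=4, color=color,
                label=f"{fit} fit", capsize=2, lw=1,
            )
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.axhline(sub["rr1"].iloc[0], color="grey", lw=0.8, ls="--")
        ax.set_xticks(x, _scenario_labels(sub), fontsize=7)
        ax.set_ylabel("RR per IQR (main)")
        ax.set_title(f"{err} measurement error")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fig_type1(metrics: pd.DataFrame, path: Path) -> None:
    errs = [e for e in ERROR_TYPES if e in set(metrics["error_type"])]
    fig, axes = plt.subplots(
        len(errs), 1, figsize=(max(6, 0.6 * len(metrics)), 3.0 * len(errs)),
        squeeze=False,
    )
    for ax, err in zip(axes[:, 0], errs):
        sub = metrics[metrics["error_type"] == err].reset_index(drop=True)
        x = np.arange(len(sub), dtype=float)
        for off, fit, color in ((-0.15, "true", "C0"), (0.15, "noisy", "C3")):
            y = sub[f"reject_2_{fit}"].to_numpy()
            ax.errorbar(
                x + off, y, yerr=2 * sub[f"reject_se_2_{fit}"].to_numpy(),
                fmt="o", ms=4,
                color=color, label=f"{fit} fit", capsize=2, lw=1,
            )
        ax.axhline(0.05, color="red", lw=1.0)
        ax.set_xticks(x, _scenario_labels(sub), fontsize=7)
        ax.set_ylabel("copollutant type I error")
        ax.set_title(f"{err} measurement error")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(results_dir, out_dir, two_sided: bool = True) -> dict[str, Path]:
    """Render the full report bundle from a directory of scenario files.

    Returns a mapping of artifact name to written path.  Deterministic:
    re-running on the same inputs reproduces identical tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = load_results(results_dir)
    metrics = metrics_table(results, two_sided=two_sided)

    paths = {
        "metrics": out / "metrics.csv",
        "attenuation": out / "attenuation_table.txt",
        "rmse_ratios": out / "rmse_ratio_table.txt",
        "fig_rr": out / "rr_estimates.png",
        "fig_type1": out / "type1_error.png",
    }
    metrics.to_csv(paths["metrics"], index=False)
    att = attenuation_table(metrics)
    paths["attenuation"].write_text(
        "Percent attenuation of the main-pollutant RR (noisy fit)\n"
        "rows: main pollutant; cells: range across copollutant models\n\n"
        + att.to_string() + "\n"
    )
    rr = rmse_ratio_table(metrics)
    paths["rmse_ratios"].write_text(
        "RMSE ratio (noisy/true) by pollutant pair and error type\n\n"
        + rr.round(2).to_string() + "\n"
    )
    _fig_rr(metrics, paths["fig_rr"])
    _fig_type1(metrics, paths["fig_type1"])
    return paths


def write_manifest(
    out_dir,
    config: ScenarioConfig,
    master_seed: int,
    scenario_paths: list[Path],
) -> Path:
    """Write a run manifest (config hash, seed, version, outputs, time)."""
    out = Path(out_dir)
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "config_sha256": cfg_hash,
        "master_seed": master_seed,
        "version": __version__,
        "scenario_files": [str(p) for p in scenario_paths],
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for p in scenario_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest references missing file {p}")
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
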