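"""End-to-end pipeline: data -> regularize/QC -> metrics -> home range ->
model fit/selection -> recovery times, with a manifest for reproducibility.

Every stage writes its interface CSV into the output directory; identical
configuration and seed reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .homerange import home_range_area
from .metrics import centre_of_gravity, distance_series, movement_records
from .recovery import recovery_interval
from .smoothfit import (
    ModelSpec,
    aicc,
    evaluate_smooth,
    fit_candidates,
    fit_model,
    fixed_coefficient,
    select_model,
)
from .synthetic import simulate_dataset, write_dataset
from .trajectory import qc_individual, read_captures, read_fixes, regularize

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6f"
VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


def _load_inputs(config: RunConfig, out: Path):
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        fixes, captures, truth = simulate_dataset(sim)
        write_dataset(fixes, captures, truth, out)
        return fixes, captures, truth
    fixes = read_fixes(config.fixes_path)
    captures = read_captures(config.captures_path, strict_season=config.strict_season)
    return fixes, captures, None


def _preprocess(config: RunConfig, fixes: pd.DataFrame, captures: pd.DataFrame):
    """Regularize and QC each individual; build movement records."""
    qc_rows = []
    record_frames = []
    hr_rows = []
    n_input = len(fixes)
    n_retained_fixes = 0
    grouped = dict(tuple(fixes.groupby("animal_id"))) if n_input else {}
    for _, capture in captures.iterrows():
        animal = capture["animal_id"]
        animal_fixes = grouped.get(animal)
        if animal_fixes is None:
            animal_fixes = fixes.iloc[0:0]
        reg = regularize(
            animal_fixes, capture, bin_hours=config.bin_hours, max_gap_hours=config.max_gap_hours
        )
        decision = qc_individual(
            reg,
            capture,
            min_monitoring_days=config.min_monitoring_days,
            max_first_fix_days=config.max_first_fix_days,
        )
        if not decision.keep:
            qc_rows.append(
                {
                    "animal_id": animal,
                    "stage": "trajectory_qc",
                    "reasons": ";".join(decision.reasons),
                    "first_fix_days": decision.first_fix_days,
                    "span_days": decision.span_days,
                }
            )
            logger.info("excluded %s: %s", animal, ";".join(decision.reasons))
            continue
        cog = centre_of_gravity(reg)
        series = distance_series(reg, cog, capture)
        hr = home_range_area(
            series,
            animal,
            min_locations=config.hr_min_locations,
            window=config.hr_window_days,
        )
        hr_rows.append(
            {
                "animal_id": animal,
                "n_locs": hr.n_locs,
                "bandwidth_m": hr.bandwidth_m,
                "area_m2": hr.area_m2,
                "excluded_flag": hr.excluded,
            }
        )
        if hr.excluded:
            qc_rows.append(
                {
                    "animal_id": animal,
                    "stage": "home_range",
                    "reasons": "TOO_FEW_HR_LOCATIONS",
                    "first_fix_days": decision.first_fix_days,
                    "span_days": decision.span_days,
                }
            )
            logger.info("excluded %s: <%d locations in home-range window", animal, config.hr_min_locations)
            continue
        n_retained_fixes += len(reg)
        record_frames.append(movement_records(series, capture, float(np.log(hr.area_m2))))
    records = (
        pd.concat(record_frames, ignore_index=True)
        if record_frames
        else pd.DataFrame(
            columns=[
                "animal_id",
                "site_id",
                "t_days",
                "x_m",
                "y_m",
                "d_cog_m",
                "step_m",
                "log_d_cog",
                "log_step",
                "method",
                "sex",
                "age_class",
                "log_hr",
            ]
        )
    )
    qc_log = pd.DataFrame(qc_rows, columns=["animal_id", "stage", "reasons", "first_fix_days", "span_days"])
    homeranges = pd.DataFrame(
        hr_rows, columns=["animal_id", "n_locs", "bandwidth_m", "area_m2", "excluded_flag"]
    )
    counts = {
        "input_fixes": int(n_input),
        "retained_fixes": int(n_retained_fixes),
        "capture_events": int(len(captures)),
        "retained_animals": int(records["animal_id"].nunique()) if len(records) else 0,
        "excluded_animals": int(qc_log["animal_id"].nunique()) if len(qc_log) else 0,
    }
    return records, qc_log, homeranges, counts


def _metric_records(records: pd.DataFrame, metric: str, dcog_horizon: float) -> pd.DataFrame:
    """Rows entering the model for one metric.

    Both metrics are modelled over the full monitoring window; the step
    metric drops the step-less first fix of each animal.  (The 60-day rule
    for distance-to-COG bounds the crossing search, not the data.)
    """
    if metric == "d_cog":
        return records
    return records.dropna(subset=["log_step"])


def _fit_metric(
    config: RunConfig, records: pd.DataFrame, metric: str, select: bool = True
):
    response = "log_d_cog" if metric == "d_cog" else "log_step"
    data = _metric_records(records, metric, config.dcog_horizon_days)
    if select:
        specs, models = fit_candidates(data, response=response, k=config.basis_dim)
    else:
        specs = [ModelSpec(response=response, k=config.basis_dim)]
        models = [fit_model(data, s) for s in specs]
    best, weights = select_model(models)
    scores = np.array([aicc(m) for m in models])
    table = pd.DataFrame(
        {
            "metric": metric,
            "fixed_terms": [s.label for s in specs],
            "k_params": [m.k_params for m in models],
            "logLik": [m.loglik for m in models],
            "AICc": scores,
            "delta_AICc": scores - scores.min(),
            "weight": weights,
        }
    ).sort_values("AICc", kind="mergesort")
    return best, table, data


def _recover_metric(config: RunConfig, model, data: pd.DataFrame, metric: str):
    curves = []
    estimates = []
    for method in model.methods:
        t_max = float(data.loc[data["method"] == method, "t_days"].max())
        horizon = min(t_max, config.dcog_horizon_days) if metric == "d_cog" else t_max
        grid = np.arange(0.0, horizon + 1e-9, config.recovery_grid_step_days)
        f, se = evaluate_smooth(model, method, grid)
        curves.append(
            pd.DataFrame({"metric": metric, "method": method, "t": grid, "f": f, "se": se})
        )
        estimates.append(recovery_interval(grid, f, se, metric=metric, method=method))
    curve_table = pd.concat(curves, ignore_index=True)
    est_table = pd.DataFrame(
        [
            {
                "metric": e.metric,
                "method": e.method,
                "tau_days": e.tau_days,
                "ci_low_days": e.ci_low_days,
                "ci_high_days": e.ci_high_days,
                "censored": e.censored,
                "horizon_days": e.horizon_days,
            }
            for e in estimates
        ]
    )
    return curve_table, est_table


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _plot_curves(curves: pd.DataFrame, estimates: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, sub in curves.groupby("metric"):
        methods = sub["method"].unique()
        fig, axes = plt.subplots(1, len(methods), figsize=(3.2 * len(methods), 3), sharey=True)
        axes = np.atleast_1d(axes)
        for ax, method in zip(axes, methods):
            s = sub[sub["method"] == method]
            ax.plot(s["t"], s["f"], color="tab:red")
            ax.fill_between(s["t"], s["f"] - s["se"], s["f"] + s["se"], alpha=0.3, color="tab:red")
            ax.axhline(0.0, color="tab:blue", lw=1)
            row = estimates[(estimates["metric"] == metric) & (estimates["method"] == method)]
            if len(row) and not row["censored"].iloc[0]:
                ax.axvline(row["tau_days"].iloc[0], color="darkred", lw=2)
            ax.set_title(method, fontsize=9)
            ax.set_xlabel("days since capture")
        axes[0].set_ylabel(f"centred log {metric}")
        fig.tight_layout()
        fig.savefig(out / f"smooths_{metric}.png", dpi=120)
        plt.close(fig)


def build_records(config: RunConfig, out_dir: Path | None = None):
    """Load (or simulate) inputs and run regularization, QC, metrics and the
    home-range covariate; returns (records, qc_log, homeranges, counts, truth).

    ``truth`` is the simulation ground truth, or None for CSV inputs.
    """
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixes, captures, truth = _load_inputs(config, out)
    records, qc_log, homeranges, counts = _preprocess(config, fixes, captures)
    return records, qc_log, homeranges, counts, truth


def run(config: RunConfig, select_models: bool = True) -> dict:
    """Execute all stages and write the report bundle.

    Returns a manifest dict (also written as ``run_manifest.json``): config
    echo, seed, stage row counts, and package version.  With
    ``select_models=False`` only the base structure (by-method smooth +
    log home-range size) is fitted, skipping AICc candidate search.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": VERSION,
        "seed": config.seed,
        "config": config.to_manifest_dict(),
        "flags": [],
    }

    try:
        fixes, captures, truth = _load_inputs(config, out)
    except Exception as exc:  # noqa: BLE001 - stage context added
        raise PipelineError(f"input stage failed: {exc}") from exc

    records, qc_log, homeranges, counts = _preprocess(config, fixes, captures)
    manifest["counts"] = counts
    _write(qc_log, out / "qc_log.csv")
    _write(homeranges, out / "homeranges.csv")
    _write(records, out / "records.csv")

    if counts["retained_animals"] < 2:
        manifest["flags"].append("NO_DATA")
        logger.warning("model stage skipped: %d retained individuals", counts["retained_animals"])
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest

    selection_tables = []
    curve_tables = []
    estimate_tables = []
    slopes = {}
    for metric in ("d_cog", "step"):
        try:
            best, table, data = _fit_metric(config, records, metric, select=select_models)
        except Exception as exc:
            raise PipelineError(f"model stage failed for metric {metric!r}: {exc}") from exc
        selection_tables.append(table)
        slope, slope_se = fixed_coefficient(best, "log_hr")
        slopes[metric] = {"log_hr_slope": slope, "log_hr_slope_se": slope_se}
        curves, estimates = _recover_metric(config, best, data, metric)
        curve_tables.append(curves)
        estimate_tables.append(estimates)

    selection = pd.concat(selection_tables, ignore_index=True)
    curves = pd.concat(curve_tables, ignore_index=True)
    estimates = pd.concat(estimate_tables, ignore_index=True)
    _write(selection, out / "model_selection.csv")
    _write(curves, out / "smooth_curves.csv")
    _write(estimates, out / "recovery_estimates.csv")
    manifest["covariate_slopes"] = slopes
    manifest["counts"]["model_rows"] = {
        "d_cog": int(len(records)),
        "step": int(records["log_step"].notna().sum()),
    }

    if config.make_plots:
        _plot_curves(curves, estimates, out)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
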