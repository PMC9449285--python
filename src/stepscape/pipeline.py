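"""End-to-end orchestration of the trajectory -> exposure -> model pipeline.

Stages run in the fixed order ingest -> interpolate -> residence ->
exposure -> fit -> predict -> map, each producing a table that the next
stage consumes.  ``run_pipeline`` executes them with in-memory handoff and
(optionally) persists every stage table plus a machine-readable record-count
log; the CLI can also run any stage standalone from the prior stage's
artifact, failing with a dependency error that names the missing stage.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import exposure as exposure_mod
from . import ingest as ingest_mod
from . import mapping as mapping_mod
from . import residence as residence_mod
from . import stepmodel
from . import trajectory as trajectory_mod

logger = logging.getLogger(__name__)


class DependencyError(FileNotFoundError):
    """An upstream stage artifact is missing."""


@dataclass
class PipelineConfig:
    """All pipeline knobs, loadable from one YAML file."""

    logs: str | None = None
    landuse: str | None = None
    outdir: str = "out"
    max_accuracy_m: float = 200.0
    min_logs_per_day: int = 24
    min_valid_days: int = 11
    adjacency_mode: str = "queen"
    buffer_radius_m: float = 100.0
    holidays: tuple = mapping_mod.DEFAULT_HOLIDAYS
    weekend_pairs: tuple = mapping_mod.DEFAULT_WEEKEND_PAIRS
    region: object = None
    basis_dim: int = 10
    min_users_per_grid: int = 5
    seed: int = 0
    write_geojson: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "holidays" in raw:
            raw["holidays"] = tuple(_to_date(d) for d in raw["holidays"])
        if "weekend_pairs" in raw:
            raw["weekend_pairs"] = tuple(
                tuple(_to_date(d) for d in pair) for pair in raw["weekend_pairs"]
            )
        return cls(**raw)


def _to_date(v) -> dt.date:
    return v if isinstance(v, dt.date) else pd.Timestamp(v).date()


def _require(path, stage: str, needed_by: str):
    if path is None or not os.path.exists(str(path)):
        raise DependencyError(
            f"stage '{needed_by}' needs the output of stage '{stage}' "
            f"({path!r}), which does not exist — run '{stage}' first"
        )
    return path


def run_pipeline(
    config: PipelineConfig,
    logs: pd.DataFrame | None = None,
    landuse: pd.DataFrame | None = None,
    persist: bool = True,
) -> dict:
    """Run every stage; returns a dict of stage outputs plus the count log.

    ``logs`` and ``landuse`` may be given in memory; otherwise they are
    read from ``config.logs`` / ``config.landuse``.  With ``persist`` the
    stage tables land in ``config.outdir``.
    """
    counts: dict[str, int] = {}
    out: dict[str, object] = {"counts": counts}

    if logs is None:
        logs = ingest_mod.read_logs(_require(config.logs, "simulate", "ingest"))
    if landuse is None:
        landuse = pd.read_csv(_require(config.landuse, "simulate", "exposure"))

    # ingest
    counts["raw_logs"] = len(logs)
    flogs = ingest_mod.filter_accuracy(logs, config.max_accuracy_m)
    counts["accuracy_filtered_logs"] = len(flogs)
    index = ingest_mod.index_valid_days(flogs, config.min_logs_per_day, config.min_valid_days)
    active = ingest_mod.select_active(flogs, index)
    counts["active_users"] = active["uuid"].nunique()
    counts["active_user_logs"] = len(active)
    points = ingest_mod.dedupe_minute(active)
    counts["representative_points"] = len(points)
    out["points"] = points
    logger.info("ingest: %d logs -> %d representative points of %d active users",
                counts["raw_logs"], counts["representative_points"], counts["active_users"])

    # interpolate
    traj = trajectory_mod.interpolate_user(points, index)
    counts["trajectory_points"] = len(traj)
    out["trajectory"] = traj
    logger.info("interpolate: %d trajectory points", len(traj))

    # residence
    residences = residence_mod.estimate_residences(traj, adjacency=config.adjacency_mode)
    counts["residence_valid_users"] = int((residences["status"] == "valid").sum())
    counts["residence_undefinable_users"] = int((residences["status"] == "undefinable").sum())
    residences_in = residence_mod.restrict_region(residences, config.region)
    counts["residence_in_region_users"] = int((residences_in["status"] == "valid").sum())
    filtered = residence_mod.filter_residential_all(traj, residences_in)
    counts["residence_filtered_points"] = len(filtered)
    out["residences"] = residences_in
    out["filtered_points"] = filtered
    logger.info("residence: %d valid users, %d undefinable; %d points survive",
                counts["residence_valid_users"], counts["residence_undefinable_users"],
                len(filtered))

    # exposure
    grid = exposure_mod.LandUseGrid(landuse)
    records = exposure_mod.count_exposure(filtered, grid, radius_m=config.buffer_radius_m)
    records = exposure_mod.attach_attributes(records, flogs)
    with_steps, without_steps = exposure_mod.split_model_data(records)
    counts["exposure_records"] = len(records)
    counts["model_records"] = len(with_steps)
    counts["model_users"] = with_steps["uuid"].nunique()
    counts["prediction_records"] = len(without_steps)
    out["exposure"] = records
    out["with_steps"] = with_steps
    out["without_steps"] = without_steps
    logger.info("exposure: %d records (%d model, %d prediction)",
                len(records), len(with_steps), len(without_steps))

    # fit + predict
    fit = None
    predictions = pd.DataFrame(columns=["uuid", "date", "predicted_steps"])
    if len(with_steps) and with_steps["uuid"].nunique() >= 2:
        fit = stepmodel.fit(with_steps, stepmodel.ModelConfig(basis_dim=config.basis_dim))
        logger.info("fit: deviance explained %.3f, sigma_L1 %.0f, sigma_L2 %.0f",
                    fit.deviance_explained, fit.sigma2_l1 ** 0.5, fit.sigma2_l2 ** 0.5)
        if len(without_steps):
            predictions = without_steps[["uuid", "date"]].copy()
            predictions["predicted_steps"] = fit.predict_fixed(without_steps)
    out["fit"] = fit
    out["predictions"] = predictions
    counts["predictions"] = len(predictions)

    # map
    summaries = pd.DataFrame(columns=mapping_mod.SUMMARY_COLUMNS)
    if len(predictions):
        means = mapping_mod.user_means(predictions, config.holidays, config.weekend_pairs)
        summaries = mapping_mod.grid_summaries(
            means, out["residences"], min_users=config.min_users_per_grid
        )
        out["user_means"] = means
    out["grid_summary"] = summaries
    counts["summary_grids"] = summaries["grid"].nunique() if len(summaries) else 0

    if persist:
        os.makedirs(config.outdir, exist_ok=True)
        points.to_csv(f"{config.outdir}/representative_points.csv", index=False)
        traj.to_csv(f"{config.outdir}/trajectory.csv", index=False)
        residences_in.to_csv(f"{config.outdir}/residences.csv", index=False)
        records.to_csv(f"{config.outdir}/exposure.csv", index=False)
        predictions.to_csv(f"{config.outdir}/predictions.csv", index=False)
        summaries.to_csv(f"{config.outdir}/grid_summary.csv", index=False)
        if fit is not None:
            stepmodel.save_fit(fit, f"{config.outdir}/model.json")
        if config.write_geojson and len(summaries):
            mapping_mod.summaries_to_geojson(summaries, f"{config.outdir}/grid_summary.geojson")
        with open(f"{config.outdir}/counts.json", "w") as fh:
            json.dump(counts, fh, indent=2)
    return out
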