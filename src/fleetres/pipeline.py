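"""End-to-end orchestration: ingest -> classify -> map -> ETP -> assess.

``run_pipeline`` executes the full analysis from a :class:`RunConfig`.
Inputs that are not provided as files are generated synthetically, so the
default configuration is a self-contained demonstration run. All outputs
are deterministic under the configured seed (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import ais, classify, etp, gridding, synthetic
from .amsy import FleetResilienceModel, PriorConfig
from .config import RunConfig, validate_config
from .series import EffortSeries

logger = logging.getLogger(__name__)

DEMO_BBOX = (12.5, 42.0, 16.5, 45.8)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s", name)
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("ingest")
def _ingest(config: RunConfig):
    if config.pings_path:
        pings = ais.read_pings(config.pings_path)
        registry = (
            classify.read_registry(config.registry_path) if config.registry_path else None
        )
    else:
        vessels = synthetic.default_fleet(config.n_per_gear)
        pings = synthetic.simulate_ais_tracks(vessels, n_days=config.n_days, seed=config.seed)
        registry = synthetic.registry_from_vessels(vessels)
    return pings, registry


@_stage("classify-gear")
def _classify(config: RunConfig, pings, registry):
    preds = classify.classify_vessels(
        pings,
        bands=config.bands(),
        k=config.k_clusters,
        seed=config.seed,
        max_gap_hours=config.max_gap_hours,
    )
    validation = (
        classify.validate_against_registry(preds, registry) if registry is not None else None
    )
    return preds, validation


@_stage("map-effort")
def _map_effort(config: RunConfig, pings, preds):
    gear_map = dict(zip(preds["vessel_id"], preds["predicted_gear"]))
    flagged = ais.flag_fleet(
        pings,
        gear_map,
        bands=config.bands(),
        max_gap_hours=config.max_gap_hours,
        port_buffer_km=config.port_buffer_km,
    )
    intervals = gridding.fishing_intervals(flagged, config.max_interval_hours)
    total = gridding.grid_effort(intervals, config.resolution, gear="ALL")
    total = gridding.classify_cells_lognormal(total)
    gears = sorted(g for g in intervals["gear"].unique()) if len(intervals) else []
    per_gear = {
        g: gridding.grid_effort(intervals, config.resolution, gear=g) for g in gears
    }
    barys = [gridding.monthly_barycentre(gr) for gr in per_gear.values() if gr.total_hours > 0]
    return flagged, total, per_gear, barys


@_stage("etp-impact")
def _etp(config: RunConfig, effort_grid):
    if config.ranges_path:
        ranges = etp.load_ranges_geojson(config.ranges_path)
        cells = effort_grid.cells
        bbox = (
            float(cells["lon_min"].min()),
            float(cells["lat_min"].min()),
            float(cells["lon_min"].max()) + config.resolution,
            float(cells["lat_min"].max()) + config.resolution,
        )
        sgrid = etp.species_richness_grid(ranges, bbox, config.resolution)
    else:
        sgrid = synthetic.simulate_etp_grid(DEMO_BBOX, resolution=config.resolution, seed=config.seed)
    sgrid = etp.classify_richness(sgrid)
    impact = etp.classify_impact(effort_grid, sgrid)
    return sgrid, impact


@_stage("assess-fleet")
def _assess(config: RunConfig):
    prior = PriorConfig(
        r_range=config.r_range, n_samples=config.n_samples, seed=config.seed
    )
    results = {}
    if config.series_path:
        df = pd.read_csv(config.series_path)
        fleets = sorted(df["fleet"].unique()) if "fleet" in df.columns else [None]
        for f in fleets:
            series = EffortSeries.from_dataframe(df, fleet=f)
            results[series.fleet] = FleetResilienceModel(series, prior=prior).fit()
    else:
        for gear, params in synthetic.ADRIATIC_FLEETS.items():
            series = synthetic.simulate_effort_series(
                params, n_months=config.n_months, seed=config.seed
            )
            results[gear] = FleetResilienceModel(series, prior=prior).fit()
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; write artifacts to config.out_dir; return the report."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pings, registry = _ingest(config)
    preds, validation = _classify(config, pings, registry)
    flagged, total_grid, per_gear, barys = _map_effort(config, pings, preds)
    sgrid, impact = _etp(config, total_grid)
    fits = _assess(config)

    # artifacts
    flagged.to_csv(out / "flagged_pings.csv", index=False)
    preds.to_csv(out / "gear_predictions.csv", index=False)
    total_grid.to_csv(out / "effort_grid.csv")
    total_grid.to_geojson(out / "effort_grid.geojson")
    sgrid.to_csv(out / "species_grid.csv")
    impact.to_csv(out / "impact_cells.csv", index=False)
    if barys:
        gridding.barycentres_to_geojson(barys, out / "barycentres.geojson")
    for gear, res in fits.items():
        res.stress.to_csv(out / f"stress_{gear}.csv", index=False)
        res.viable.to_csv(out / f"viable_pairs_{gear}.csv", index=False)

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pings": int(len(pings)),
        "kappa": (validation["kappa"] if validation else None),
        "total_fishing_hours": total_grid.total_hours,
        "n_active_cells": total_grid.n_active,
        "n_impact_cells": int(impact["impact"].sum()),
        "fleets": {g: r.to_report() for g, r in sorted(fits.items())},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
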