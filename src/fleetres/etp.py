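"""Overlap of fishing effort with endangered, threatened and protected species.

Species range polygons are rasterized onto the effort lattice as a richness
grid (number of distinct species whose range intersects each cell; any
overlap counts, including a shared corner). Richness cells are classified
LOW/MEDIUM/HIGH with the same log-normal classifier used for effort, and a
cell is flagged as a potential-impact hotspot iff it is HIGH in both effort
and richness. The monthly effort summed over those cells tracks how much
fishing pressure falls on the locations at higher risk of impact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box, mapping, shape

from .gridding import EffortGrid, classify_values_lognormal, snap_to_cell


def lattice_cells(bbox: tuple[float, float, float, float], resolution: float) -> list[tuple[float, float]]:
    """Lower-left corners of all lattice cells covering the bbox."""
    lon_min, lat_min, lon_max, lat_max = bbox
    lon0 = snap_to_cell(lon_min, resolution)
    lat0 = snap_to_cell(lat_min, resolution)
    lons = np.round(np.arange(lon0, lon_max, resolution), 9)
    lats = np.round(np.arange(lat0, lat_max, resolution), 9)
    return [(float(lo), float(la)) for lo in lons for la in lats]


@dataclass
class SpeciesGrid:
    """ETP species counts per lattice cell, with optional range geometries."""

    resolution: float
    cells: pd.DataFrame  # lon_min, lat_min, species_count [, richness_class]
    geometries: dict | None = None

    @property
    def total_species_cells(self) -> int:
        return int((self.cells["species_count"] > 0).sum())

    def keyed(self) -> pd.DataFrame:
        return self.cells.set_index(["lon_min", "lat_min"])

    def to_csv(self, path) -> None:
        out = self.cells.copy()
        out.insert(2, "resolution_deg", self.resolution)
        out.to_csv(path, index=False)

    def ranges_to_geojson(self, path) -> None:
        if not self.geometries:
            raise ValueError("grid carries no range geometries")
        feats = [
            {"type": "Feature", "properties": {"species_id": sid}, "geometry": mapping(geom)}
            for sid, geom in self.geometries.items()
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def load_ranges_geojson(path) -> dict:
    """Read a FeatureCollection of species ranges into {species_id: geometry}.

    Invalid polygons are repaired with a zero-width buffer; multiple features
    sharing a species_id are unioned.
    """
    with open(path) as fh:
        fc = json.load(fh)
    ranges: dict = {}
    for i, feat in enumerate(fc.get("features", [])):
        sid = str(feat.get("properties", {}).get("species_id", f"feature{i}"))
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = geom.buffer(0)
        ranges[sid] = geom if sid not in ranges else ranges[sid].union(geom)
    return ranges


def species_richness_grid(
    ranges: dict, bbox: tuple[float, float, float, float], resolution: float
) -> SpeciesGrid:
    """Count, per lattice cell, the distinct species whose range intersects it.

    Presence/absence only (no area weighting); touching a cell edge or
    corner counts as presence. An empty range set yields an all-zero grid
    with a warning.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    cells = lattice_cells(bbox, resolution)
    counts = np.zeros(len(cells), dtype=int)
    if not ranges:
        warnings.warn("empty species range set: all cell counts are zero")
    else:
        cell_geoms = [box(lo, la, lo + resolution, la + resolution) for lo, la in cells]
        tree = STRtree(cell_geoms)
        for geom in ranges.values():
            idx = tree.query(geom, predicate="intersects")
            counts[np.unique(idx)] += 1
    df = pd.DataFrame(
        {"lon_min": [c[0] for c in cells], "lat_min": [c[1] for c in cells], "species_count": counts}
    )
    return SpeciesGrid(resolution, df, geometries=dict(ranges) if ranges else None)


def classify_richness(
    grid: SpeciesGrid, method: str = "sigma", n_sigma: float = 1.0
) -> SpeciesGrid:
    """LOW/MEDIUM/HIGH richness classes over cells with >= 1 species.

    Reuses the effort log-normal classifier on the counts; zero-count cells
    stay unclassified.
    """
    classes = classify_values_lognormal(grid.cells["species_count"].astype(float), method=method, n_sigma=n_sigma)
    cells = grid.cells.copy()
    cells["richness_class"] = classes.to_numpy()
    return SpeciesGrid(grid.resolution, cells, geometries=grid.geometries)


def classify_impact(effort: EffortGrid, richness: SpeciesGrid) -> pd.DataFrame:
    """Join classified effort and richness grids into per-cell impact records.

    One record per cell active in either grid, with the effort class, the
    richness class and an impact flag that is true iff both are HIGH.
    """
    if effort.resolution != richness.resolution:
        raise ValueError("effort and richness grids must share the lattice")
    if "effort_class" not in effort.cells.columns:
        raise ValueError("effort grid must be classified first")
    if "richness_class" not in richness.cells.columns:
        raise ValueError("richness grid must be classified first")
    e = effort.keyed()[["hours", "effort_class"]]
    r = richness.keyed()[["species_count", "richness_class"]]
    j = e.join(r, how="outer")
    active = (j["hours"].fillna(0) > 0) | (j["species_count"].fillna(0) > 0)
    j = j[active].reset_index()
    j["impact"] = (j["effort_class"] == "HIGH") & (j["richness_class"] == "HIGH")
    return j


def impact_summary(impact: pd.DataFrame) -> pd.DataFrame:
    """Cell counts by (effort class x richness class)."""
    return (
        impact.fillna({"effort_class": "NONE", "richness_class": "NONE"})
        .groupby(["effort_class", "richness_class"])
        .size()
        .rename("n_cells")
        .reset_index()
    )


def effort_at_risk_series(monthly_grids: list[EffortGrid], impact_cells: set) -> pd.DataFrame:
    """Monthly fishing hours falling on the impact cells, per gear.

    ``impact_cells`` is a set of (lon_min, lat_min) keys on the grids'
    lattice; each grid contributes one row (gear, period, hours).
    """
    rows = []
    for g in monthly_grids:
        keys = list(zip(g.cells["lon_min"], g.cells["lat_min"]))
        mask = np.array([k in impact_cells for k in keys], dtype=bool)
        rows.append(
            {"gear": g.gear, "period": g.period, "hours": float(g.cells.loc[mask, "hours"].sum())}
        )
    return pd.DataFrame(rows)
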