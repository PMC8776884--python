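"""Gridded fishing effort: binning, log-normal cell classes, barycentres.

Fishing hours are accumulated on a regular lat-lon lattice anchored at
integer degrees, with half-open cells [lon_min, lon_min+res) x
[lat_min, lat_min+res). Positive cells are classified LOW / MEDIUM / HIGH
assuming a log-normal distribution of hours over cells: with mu and sigma
the mean and sample SD of log10(hours), HIGH means log10 h >= mu + sigma and
LOW means log10 h < mu - sigma. The monthly barycentre of a fleet is the
hours-weighted mean of its active cell centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EDGE_EPS = 1e-9  # snap points this close (in cells) to the upper edge into the next cell
CLASS_NAMES = ("LOW", "MEDIUM", "HIGH")


def snap_to_cell(values, resolution: float) -> np.ndarray:
    """Lower edge of the lattice cell containing each coordinate."""
    v = np.asarray(values, dtype=float)
    idx = np.floor(v / resolution + EDGE_EPS)
    return np.round(idx * resolution, 9)


@dataclass
class EffortGrid:
    """Fishing hours per lattice cell for one period and gear.

    ``cells`` has columns lon_min, lat_min, hours and, once classified,
    effort_class.
    """

    resolution: float
    cells: pd.DataFrame
    period: str = "ALL"
    gear: str = "ALL"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        need = {"lon_min", "lat_min", "hours"}
        if not need.issubset(self.cells.columns):
            raise ValueError(f"cells must have columns {sorted(need)}")
        if (self.cells["hours"] < 0).any():
            raise ValueError("cell hours must be non-negative")

    @property
    def total_hours(self) -> float:
        return float(self.cells["hours"].sum())

    @property
    def n_active(self) -> int:
        return int((self.cells["hours"] > 0).sum())

    def cell_centres(self) -> pd.DataFrame:
        c = self.cells.copy()
        c["lon_c"] = c["lon_min"] + self.resolution / 2
        c["lat_c"] = c["lat_min"] + self.resolution / 2
        return c

    def keyed(self) -> pd.DataFrame:
        return self.cells.set_index(["lon_min", "lat_min"])

    def to_csv(self, path) -> None:
        out = self.cells.copy()
        out.insert(2, "resolution_deg", self.resolution)
        out.to_csv(path, index=False)

    def to_geojson(self, path) -> None:
        feats = []
        for _, row in self.cells.iterrows():
            lo, la = row["lon_min"], row["lat_min"]
            props = {k: (row[k] if isinstance(row[k], str) else float(row[k]))
                     for k in self.cells.columns if k not in ("lon_min", "lat_min")}
            props.update(lon_min=float(lo), lat_min=float(la), resolution_deg=self.resolution)
            feats.append(
                {
                    "type": "Feature",
                    "properties": props,
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[
                            [lo, la], [lo + self.resolution, la],
                            [lo + self.resolution, la + self.resolution],
                            [lo, la + self.resolution], [lo, la],
                        ]],
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def fishing_intervals(flagged: pd.DataFrame, max_interval_hours: float = 1.0) -> pd.DataFrame:
    """Per-interval fishing hours from a flagged ping table.

    An interval is a consecutive ping pair within one trip where both pings
    are flagged fishing and the gap does not exceed ``max_interval_hours``.
    Hours are attributed to the first ping's position (and its gear, if a
    gear column is present). Requires columns vessel_id, trip_id, timestamp,
    lat, lon, fishing.
    """
    need = {"vessel_id", "trip_id", "timestamp", "lat", "lon", "fishing"}
    missing = need - set(flagged.columns)
    if missing:
        raise ValueError(f"flagged ping table is missing columns: {sorted(missing)}")
    df = flagged.sort_values(["vessel_id", "trip_id", "timestamp"], kind="mergesort")
    grp = df.groupby(["vessel_id", "trip_id"], sort=False)
    dt_h = grp["timestamp"].diff().shift(-1).dt.total_seconds() / 3600.0
    both = df["fishing"] & df.groupby(["vessel_id", "trip_id"], sort=False)["fishing"].shift(-1, fill_value=False)
    ok = both & (dt_h <= max_interval_hours) & (dt_h > 0)
    out = df.loc[ok, ["vessel_id", "trip_id", "timestamp", "lat", "lon"]].copy()
    if "gear" in df.columns:
        out["gear"] = df.loc[ok, "gear"]
    out["hours"] = dt_h[ok].to_numpy()
    return out.reset_index(drop=True)


def grid_effort(
    flagged: pd.DataFrame,
    resolution: float = 0.1,
    period: str = "ALL",
    gear: str = "ALL",
    max_interval_hours: float = 1.0,
) -> EffortGrid:
    """Accumulate fishing hours from flagged pings onto a lattice grid.

    Conservative by construction: the grid total equals the summed fishing
    hours of the contributing intervals (each interval is assigned entirely
    to the cell of its first ping). ``gear`` other than "ALL" restricts to
    intervals of that gear (requires a gear column).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    iv = flagged if "hours" in flagged.columns else fishing_intervals(flagged, max_interval_hours)
    if gear != "ALL":
        if "gear" not in iv.columns:
            raise ValueError("per-gear gridding needs a gear column")
        iv = iv[iv["gear"] == gear]
    cells = pd.DataFrame(
        {
            "lon_min": snap_to_cell(iv["lon"], resolution),
            "lat_min": snap_to_cell(iv["lat"], resolution),
            "hours": iv["hours"].to_numpy(),
        }
    )
    agg = cells.groupby(["lon_min", "lat_min"], as_index=False)["hours"].sum()
    return EffortGrid(resolution, agg, period=period, gear=gear)


def classify_values_lognormal(
    values: pd.Series,
    reference: pd.Series | None = None,
    method: str = "sigma",
    n_sigma: float = 1.0,
) -> pd.Series:
    """LOW/MEDIUM/HIGH classes for positive cell values under a log-normal fit.

    The thresholds are fitted on ``reference`` (default: the values
    themselves) restricted to positive entries: mean mu and sample SD sigma
    of log10(value); HIGH iff log10 v >= mu + n_sigma*sigma, LOW iff
    log10 v < mu - n_sigma*sigma. With sigma == 0 everything is MEDIUM.
    ``method="quantile"`` uses tertiles of the reference instead.
    """
    pos = values[values > 0]
    if len(pos) == 0:
        raise ValueError("no positive cells to classify")
    ref = reference if reference is not None else values
    ref = ref[ref > 0]
    if len(ref) == 0:
        raise ValueError("reference grid has no positive cells")
    out = pd.Series("MEDIUM", index=values.index, dtype=object)
    if method == "sigma":
        logs = np.log10(ref.to_numpy(dtype=float))
        mu = logs.mean()
        sigma = logs.std(ddof=1) if len(logs) > 1 else 0.0
        if sigma > 0:
            lv = np.log10(pos.to_numpy(dtype=float))
            out.loc[pos.index[lv >= mu + n_sigma * sigma]] = "HIGH"
            out.loc[pos.index[lv < mu - n_sigma * sigma]] = "LOW"
    elif method == "quantile":
        lo, hi = np.quantile(ref.to_numpy(dtype=float), [1 / 3, 2 / 3])
        if hi > lo:
            v = pos.to_numpy(dtype=float)
            out.loc[pos.index[v >= hi]] = "HIGH"
            out.loc[pos.index[v < lo]] = "LOW"
    else:
        raise ValueError(f"unknown method {method!r}")
    out[values <= 0] = None
    return out


def classify_cells_lognormal(
    grid: EffortGrid,
    reference: EffortGrid | None = None,
    method: str = "sigma",
    n_sigma: float = 1.0,
) -> EffortGrid:
    """Classified copy of the grid (adds an effort_class column).

    Passing a ``reference`` grid (e.g. the first year of the study) applies
    that period's thresholds to every later period for comparability.
    """
    ref = reference.cells["hours"] if reference is not None else None
    classes = classify_values_lognormal(grid.cells["hours"], reference=ref, method=method, n_sigma=n_sigma)
    cells = grid.cells.copy()
    cells["effort_class"] = classes.to_numpy()
    return EffortGrid(grid.resolution, cells, period=grid.period, gear=grid.gear)


def compare_periods(grid_a: EffortGrid, grid_b: EffortGrid) -> dict:
    """Summary of effort change between two same-lattice grids.

    Returns totals, absolute and percent hour change, active-cell counts and
    their change, per-cell differences, and the overlap of HIGH cells when
    both grids are classified.
    """
    if grid_a.resolution != grid_b.resolution:
        raise ValueError("grids must share resolution and lattice")
    a, b = grid_a.keyed(), grid_b.keyed()
    joined = a[["hours"]].join(b[["hours"]], how="outer", lsuffix="_a", rsuffix="_b").fillna(0.0)
    joined["diff"] = joined["hours_b"] - joined["hours_a"]
    ta, tb = grid_a.total_hours, grid_b.total_hours
    summary = {
        "hours_a": ta,
        "hours_b": tb,
        "hours_diff": tb - ta,
        "pct_change": (tb - ta) / ta * 100.0 if ta > 0 else (np.nan if tb == 0 else np.inf),
        "cells_a": grid_a.n_active,
        "cells_b": grid_b.n_active,
        "cells_diff": grid_b.n_active - grid_a.n_active,
        "per_cell": joined,
    }
    if "effort_class" in grid_a.cells.columns and "effort_class" in grid_b.cells.columns:
        high_a = set(map(tuple, grid_a.cells.loc[grid_a.cells["effort_class"] == "HIGH", ["lon_min", "lat_min"]].to_numpy()))
        high_b = set(map(tuple, grid_b.cells.loc[grid_b.cells["effort_class"] == "HIGH", ["lon_min", "lat_min"]].to_numpy()))
        summary["high_overlap"] = len(high_a & high_b)
        summary["high_a"], summary["high_b"] = len(high_a), len(high_b)
    return summary


@dataclass(frozen=True)
class BarycentrePoint:
    """Hours-weighted mean position of a fleet's fishing activity in a period."""

    gear: str
    period: str
    lon: float
    lat: float
    total_hours: float


def monthly_barycentre(grid: EffortGrid) -> BarycentrePoint:
    """Effort-weighted barycentre of the grid's active cell centres."""
    c = grid.cell_centres()
    w = c["hours"].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("cannot compute a barycentre of an all-zero grid")
    return BarycentrePoint(
        gear=grid.gear,
        period=grid.period,
        lon=float(np.average(c["lon_c"], weights=w)),
        lat=float(np.average(c["lat_c"], weights=w)),
        total_hours=float(w.sum()),
    )


def barycentre_extent(points: list[BarycentrePoint]) -> dict:
    """Bounding box and latitudinal range of a barycentre series."""
    if not points:
        raise ValueError("empty barycentre series")
    lons = [p.lon for p in points]
    lats = [p.lat for p in points]
    return {
        "lon_min": min(lons),
        "lon_max": max(lons),
        "lat_min": min(lats),
        "lat_max": max(lats),
        "lat_range": max(lats) - min(lats),
    }


def barycentres_to_geojson(points: list[BarycentrePoint], path) -> None:
    """One LineString per gear through its chronological barycentres, plus bbox."""
    feats = []
    by_gear: dict[str, list[BarycentrePoint]] = {}
    for p in points:
        by_gear.setdefault(p.gear, []).append(p)
    for gear, pts in sorted(by_gear.items()):
        coords = [[p.lon, p.lat] for p in pts]
        feats.append(
            {
                "type": "Feature",
                "properties": {"gear": gear, "kind": "barycentre_track",
                               "periods": [p.period for p in pts]},
                "geometry": {"type": "LineString", "coordinates": coords}
                if len(coords) > 1
                else {"type": "Point", "coordinates": coords[0]},
            }
        )
        ext = barycentre_extent(pts)
        feats.append(
            {
                "type": "Feature",
                "properties": {"gear": gear, "kind": "extent", "lat_range": ext["lat_range"]},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[
                        [ext["lon_min"], ext["lat_min"]], [ext["lon_max"], ext["lat_min"]],
                        [ext["lon_max"], ext["lat_max"]], [ext["lon_min"], ext["lat_max"]],
                        [ext["lon_min"], ext["lat_min"]],
                    ]],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
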