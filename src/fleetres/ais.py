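"""AIS preprocessing: read ping tables, cut trips, flag fishing, count hours.

Every map and effort series downstream starts here. Pings are tabular AIS
records (vessel, UTC timestamp, position, speed over ground, course). Trips
are maximal runs of a vessel's pings with no gap above a threshold (default
4 h — a silent spell at berth). A ping is flagged as fishing when its speed
over ground falls in the gear's fishing band; purse-seine pings must
additionally be away from the trip endpoints, so that drifting in port is
not mistaken for setting the net. Fishing hours are summed over consecutive
flagged ping pairs, capping individual gaps (default 1 h) so transmission
dropouts do not inflate the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gears import DEFAULT_BANDS, GEAR_LABELS, GearSpeedBands
from .geo import haversine_km

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("vessel_id", "timestamp", "lat", "lon", "sog_knots", "cog_degrees")
DEFAULT_MAX_GAP_HOURS = 4.0
DEFAULT_MAX_INTERVAL_HOURS = 1.0
DEFAULT_PORT_BUFFER_KM = 1.0


def read_pings(path) -> pd.DataFrame:
    """Read and validate a ping CSV.

    Hard error on a missing column; rows with unparseable timestamps or
    out-of-range coordinates/speeds are dropped with a logged warning (the
    dropped count is kept in ``df.attrs["n_dropped"]``). Output is sorted by
    (vessel_id, timestamp).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ping table is missing required column(s): {missing}")
    n_raw = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    for col in ("lat", "lon", "sog_knots", "cog_degrees"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["timestamp"].notna()
        & df["lat"].between(-90, 90)
        & (df["lon"] >= -180)
        & (df["lon"] < 180)
        & (df["sog_knots"] >= 0)
    )
    dropped = int(n_raw - ok.sum())
    if dropped:
        logger.warning("dropped %d invalid ping row(s) of %d", dropped, n_raw)
    out = df[ok].sort_values(["vessel_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_dropped"] = dropped
    return out


@dataclass
class Trip:
    """One vessel voyage: a time-ordered run of pings with no large gap."""

    vessel_id: str
    trip_id: str
    pings: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.pings) == 0:
            raise ValueError("a trip must contain at least one ping")
        ts = self.pings["timestamp"]
        if not ts.is_monotonic_increasing:
            raise ValueError("trip pings must be time-ordered")

    def __len__(self) -> int:
        return len(self.pings)

    @property
    def start(self) -> pd.Timestamp:
        return self.pings["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.pings["timestamp"].iloc[-1]

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


def add_trip_ids(pings: pd.DataFrame, max_gap_hours: float = DEFAULT_MAX_GAP_HOURS) -> pd.DataFrame:
    """Return a copy of the ping table with a trip_id column.

    A new trip starts whenever the gap to the previous ping of the same
    vessel exceeds ``max_gap_hours``.
    """
    df = pings.sort_values(["vessel_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    gap_h = df.groupby("vessel_id", sort=False)["timestamp"].diff().dt.total_seconds() / 3600.0
    new_trip = gap_h.isna() | (gap_h > max_gap_hours)
    seq = new_trip.groupby(df["vessel_id"], sort=False).cumsum().astype(int)
    df["trip_id"] = df["vessel_id"].astype(str) + "-" + seq.astype(str).str.zfill(3)
    return df


def segment_trips(pings: pd.DataFrame, max_gap_hours: float = DEFAULT_MAX_GAP_HOURS) -> list[Trip]:
    """Cut each vessel's ping sequence into trips at gaps > max_gap_hours.

    Trips partition the pings of each vessel; inside a trip every
    consecutive gap is <= the threshold. Single pings form trips of length 1.
    """
    df = add_trip_ids(pings, max_gap_hours=max_gap_hours)
    return [
        Trip(vessel_id=str(g["vessel_id"].iloc[0]), trip_id=tid, pings=g.reset_index(drop=True))
        for tid, g in df.groupby("trip_id", sort=True)
    ]


def detect_fishing_points(
    trip: Trip,
    gear: str,
    bands: GearSpeedBands = DEFAULT_BANDS,
    port_buffer_km: float = DEFAULT_PORT_BUFFER_KM,
) -> Trip:
    """Flag each ping of a trip as fishing or not, by gear speed band.

    A ping is fishing iff its sog lies in the gear's band; for PS the ping
    must also be farther than ``port_buffer_km`` from both trip endpoints
    (purse seiners set at near-zero speed, indistinguishable from port dwell
    by speed alone).
    """
    if gear not in GEAR_LABELS:
        raise ValueError(f"unknown gear label {gear!r}")
    p = trip.pings.copy()
    flag = np.asarray(bands.contains(gear, p["sog_knots"].to_numpy()))
    if gear == "PS":
        lat0, lon0 = p["lat"].iloc[0], p["lon"].iloc[0]
        lat1, lon1 = p["lat"].iloc[-1], p["lon"].iloc[-1]
        d0 = haversine_km(p["lat"], p["lon"], lat0, lon0)
        d1 = haversine_km(p["lat"], p["lon"], lat1, lon1)
        flag &= (np.asarray(d0) > port_buffer_km) & (np.asarray(d1) > port_buffer_km)
    p["fishing"] = flag
    p["gear"] = gear
    return Trip(trip.vessel_id, trip.trip_id, p)


def fishing_hours(trip: Trip, max_interval_hours: float = DEFAULT_MAX_INTERVAL_HOURS) -> float:
    """Fishing hours of a flagged trip.

    Sum of gaps between consecutive ping pairs where both pings are flagged
    and the gap does not exceed ``max_interval_hours``.
    """
    p = trip.pings
    if "fishing" not in p.columns:
        raise ValueError("trip is not flagged; run detect_fishing_points first")
    dt_h = p["timestamp"].diff().dt.total_seconds().to_numpy() / 3600.0
    both = p["fishing"].to_numpy() & np.roll(p["fishing"].to_numpy(), 1)
    both[0] = False
    ok = both & (dt_h <= max_interval_hours)
    return float(np.nansum(dt_h[ok]))


def displacement_speed_knots(trip: Trip) -> np.ndarray:
    """Speed implied by consecutive positions, in knots (validation utility).

    First element is NaN. The pipeline itself always uses the reported sog.
    """
    p = trip.pings
    d_km = haversine_km(p["lat"].shift(), p["lon"].shift(), p["lat"], p["lon"])
    dt_h = p["timestamp"].diff().dt.total_seconds() / 3600.0
    return (np.asarray(d_km) / 1.852) / np.asarray(dt_h)


def flag_fleet(
    pings: pd.DataFrame,
    gear_map: dict,
    bands: GearSpeedBands = DEFAULT_BANDS,
    max_gap_hours: float = DEFAULT_MAX_GAP_HOURS,
    port_buffer_km: float = DEFAULT_PORT_BUFFER_KM,
) -> pd.DataFrame:
    """Segment and flag a whole fleet's pings in one pass.

    ``gear_map`` maps vessel_id -> gear label; vessels missing from the map
    are treated as OTHER. Returns the ping table with trip_id, gear and
    fishing columns.
    """
    trips = segment_trips(pings, max_gap_hours=max_gap_hours)
    flagged = [
        detect_fishing_points(
            t, gear_map.get(t.vessel_id, "OTHER"), bands=bands, port_buffer_km=port_buffer_km
        ).pings
        for t in trips
    ]
    return pd.concat(flagged, ignore_index=True)
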