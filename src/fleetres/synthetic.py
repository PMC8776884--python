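"""Synthetic inputs for the whole pipeline: effort series, AIS tracks, ETP grids.

The real analysis runs on proprietary AIS censuses, aggregated fishing-effort
products, fleet registers and species range maps. This module generates
structurally equivalent stand-ins so every downstream stage is testable:

* monthly fleet effort series that follow Schaefer surplus-production
  dynamics under a seasonal stress schedule with optional lockdown shocks;
* vessel ping tables with gear-specific speed regimes (trawl tows, beam-trawl
  tows, paired pelagic trawling within 300 m, purse-seine setting at near
  zero speed) on a 5-minute reporting cadence;
* clustered species-richness grids with an explicit hotspot.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from . import etp
from .amsy import simulate_schaefer
from .geo import displace
from .gears import GEAR_LABELS
from .series import EffortSeries

# ---------------------------------------------------------------------------
# Monthly effort series with Schaefer structure
# ---------------------------------------------------------------------------


@dataclass
class FleetParams:
    """Simulation truths for one fleet's effort dynamics.

    r_true is the monthly intrinsic growth rate, kq_true the maximum
    sustainable monthly fishing hours. The stress schedule removes a
    fraction of the current effort each month: a baseline ``base_stress``
    (default r_true/2, which holds the fleet at the sustainably-stressed
    equilibrium A* = kq/2) modulated by a seasonal sinusoid of relative
    amplitude ``seasonal_amplitude`` whose minimum falls in August, plus an
    extra removal of ``shock_magnitude`` * A_t in each shock month.
    """

    gear: str
    r_true: float
    kq_true: float
    a0: float
    seasonal_amplitude: float = 0.15
    shock_months: tuple[tuple[int, int], ...] = ()
    shock_magnitude: float = 0.37
    noise_cv: float = 0.05
    base_stress: float | None = None

    def __post_init__(self) -> None:
        if self.r_true < 0 or self.kq_true <= 0:
            raise ValueError("r_true must be >= 0 and kq_true positive")
        if not (0 < self.a0 <= self.kq_true):
            raise ValueError("a0 must satisfy 0 < a0 <= kq_true")
        if not (0 <= self.seasonal_amplitude < 1):
            raise ValueError("seasonal_amplitude must be in [0, 1)")
        if not (0 <= self.shock_magnitude <= 1):
            raise ValueError("shock_magnitude must be in [0, 1]")
        if not (0 <= self.noise_cv < 1):
            raise ValueError("noise_cv must be in [0, 1)")

    @property
    def stress_base(self) -> float:
        return self.r_true / 2.0 if self.base_stress is None else self.base_stress


#: Default study conditions: the four main Adriatic fleets with their
#: estimated traits as simulation truths, March-May 2020 lockdown shock,
#: 71 months starting January 2015.
LOCKDOWN_MONTHS: tuple[tuple[int, int], ...] = ((2020, 3), (2020, 4), (2020, 5))
DEFAULT_START: tuple[int, int] = (2015, 1)
DEFAULT_N_MONTHS = 71

ADRIATIC_FLEETS: dict[str, FleetParams] = {
    "PS": FleetParams("PS", 1.04, 20818.0, 20818.0 / 2, shock_months=LOCKDOWN_MONTHS),
    "PTM": FleetParams("PTM", 0.96, 4526.0, 4526.0 / 2, shock_months=LOCKDOWN_MONTHS),
    "TBB": FleetParams("TBB", 0.57, 18150.0, 18150.0 / 2, shock_months=LOCKDOWN_MONTHS),
    "OTB": FleetParams("OTB", 0.56, 117033.0, 117033.0 / 2, shock_months=LOCKDOWN_MONTHS),
}


def stress_fraction(params: FleetParams, year: int, month: int) -> float:
    """Fraction of current effort removed by stress in a calendar month."""
    seasonal = 1.0 - params.seasonal_amplitude * np.cos(2.0 * np.pi * (month - 8) / 12.0)
    f = params.stress_base * seasonal
    if (year, month) in params.shock_months:
        f += params.shock_magnitude
    return float(f)


def simulate_effort_series(
    params: FleetParams,
    n_months: int = DEFAULT_N_MONTHS,
    start: tuple[int, int] = DEFAULT_START,
    seed: int = 0,
    full_output: bool = False,
):
    """Simulate a monthly effort series under Schaefer dynamics.

    The latent recurrence is A_{t+1} = A_t + r A_t (1 - A_t/kq) - Cq_t with
    Cq_t = f(month_{t+1}) * A_t from the stress schedule. Multiplicative
    lognormal observation noise (median 1, CV ``noise_cv``) is applied last,
    so with noise_cv = 0 the returned series satisfies the recurrence
    exactly for the generated Cq_t.

    Returns an :class:`EffortSeries`; with ``full_output=True`` returns
    (series, catch) where catch is the generated Cq_t (length n_months-1).
    """
    if n_months < 2:
        raise ValueError("n_months must be >= 2")
    months = pd.period_range(start=pd.Period(year=start[0], month=start[1], freq="M"), periods=n_months)
    latent = np.empty(n_months)
    catch = np.empty(n_months - 1)
    latent[0] = params.a0
    for t in range(n_months - 1):
        target = months[t + 1]
        catch[t] = stress_fraction(params, target.year, target.month) * latent[t]
        latent[t + 1] = simulate_schaefer(latent[t], params.r_true, params.kq_true, [catch[t]])[-1]
        if latent[t + 1] <= 0:
            raise ValueError(f"effort collapse under stress schedule at {target}")
    hours = latent
    if params.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + params.noise_cv**2))
        hours = latent * np.exp(sigma * rng.standard_normal(n_months))
    series = EffortSeries(params.gear, months, hours)
    return (series, catch) if full_output else series


# ---------------------------------------------------------------------------
# AIS ping tables
# ---------------------------------------------------------------------------


@dataclass
class VesselSpec:
    """Behavioural parameters of one simulated vessel."""

    vessel_id: str
    gear: str
    home_port: tuple[float, float]  # (lon, lat)
    fishing_speed_mode: float
    steaming_speed: float
    pair_partner: str | None = None

    def __post_init__(self) -> None:
        if self.gear not in GEAR_LABELS:
            raise ValueError(f"unknown gear {self.gear!r}")
        if not self.fishing_speed_mode < self.steaming_speed:
            raise ValueError("fishing_speed_mode must be below steaming_speed")
        if self.gear == "PTM" and self.pair_partner is None:
            raise ValueError("PTM vessels need a pair_partner")
        if self.gear != "PTM" and self.pair_partner is not None:
            raise ValueError("only PTM vessels have a pair_partner")


#: (fishing speed mode, steaming speed) in knots per gear.
GEAR_BEHAVIOUR: dict[str, tuple[float, float]] = {
    "OTB": (3.2, 9.0),
    "PTM": (3.5, 9.5),
    "TBB": (5.5, 10.0),
    "PS": (0.8, 8.0),
    "OTHER": (8.0, 11.0),
}

PAIR_OFFSET_NM = 0.08  # ~150 m between pair-trawl partners
PING_COLUMNS = ("vessel_id", "timestamp", "lat", "lon", "sog_knots", "cog_degrees")


def default_fleet(n_per_gear: int = 4) -> list[VesselSpec]:
    """A mixed synthetic fleet: n_per_gear vessels of each of the five gears.

    PTM vessels come in pairs, so n_per_gear must be even. Home ports are
    laid out on an abstract Adriatic-like lattice so that unrelated vessels
    do not start within pairing distance of each other.
    """
    if n_per_gear % 2:
        raise ValueError("n_per_gear must be even (PTM vessels are paired)")
    vessels: list[VesselSpec] = []
    i = 0

    def port(idx: int) -> tuple[float, float]:
        return (12.7 + 0.35 * (idx % 8), 42.4 + 0.8 * (idx // 8))

    for gear in ("OTB", "TBB", "PS", "OTHER"):
        fish, steam = GEAR_BEHAVIOUR[gear]
        for j in range(n_per_gear):
            vessels.append(VesselSpec(f"{gear}{j:02d}", gear, port(i), fish, steam))
            i += 1
    fish, steam = GEAR_BEHAVIOUR["PTM"]
    for j in range(n_per_gear // 2):
        a, b = f"PTM{2 * j:02d}", f"PTM{2 * j + 1:02d}"
        p = port(i)
        vessels.append(VesselSpec(a, "PTM", p, fish, steam, pair_partner=b))
        vessels.append(VesselSpec(b, "PTM", p, fish, steam, pair_partner=a))
        i += 1
    return vessels


def registry_from_vessels(vessels: list[VesselSpec]) -> pd.DataFrame:
    """Licence-registry table (vessel_id, licensed_gear) for a synthetic fleet."""
    return pd.DataFrame(
        {"vessel_id": [v.vessel_id for v in vessels], "licensed_gear": [v.gear for v in vessels]}
    )


def _vessel_legs(spec: VesselSpec, total_hours: float, rng: np.random.Generator):
    """Yield (phase, duration_h, speed_kn) legs covering total_hours.

    Phases: 'port' (no pings), 'steam', 'fish'. Purse seiners alternate
    near-zero-speed setting phases with ~1 kn hauling; other gears tow at
    speeds jittered around their fishing mode.
    """
    legs = []
    t = 0.0
    while t < total_hours:
        dwell = 5.0 + rng.exponential(8.0)  # > 4 h, so port stays split trips
        legs.append(("port", dwell, 0.0))
        t += dwell
        steam_out = rng.uniform(1.0, 3.0)
        legs.append(("steam", steam_out, spec.steaming_speed))
        t += steam_out
        if spec.gear == "PS":
            for _ in range(rng.integers(4, 7)):
                legs.append(("fish", rng.uniform(1.0, 2.0), 0.2))  # setting / soaking
                legs.append(("fish", rng.uniform(0.75, 1.25), 1.0))  # hauling
                t += legs[-2][1] + legs[-1][1]
        else:
            for _ in range(rng.integers(2, 5)):
                dur = rng.uniform(2.0, 6.0)
                legs.append(("fish", dur, spec.fishing_speed_mode))
                t += dur
        steam_back = rng.uniform(1.0, 3.0)
        legs.append(("steam", steam_back, spec.steaming_speed))
        t += steam_back
    return legs


def _simulate_single(spec: VesselSpec, n_days: int, interval_min: float, rng: np.random.Generator):
    """Simulate one vessel's pings. Returns dict of column arrays."""
    dt_h = interval_min / 60.0
    total_hours = n_days * 24.0
    lon, lat = spec.home_port
    heading = rng.uniform(0.0, 360.0)
    t_h = 0.0
    rows: list[tuple] = []
    for phase, dur, speed in _vessel_legs(spec, total_hours, rng):
        if phase == "port":
            t_h += dur
            continue
        if phase == "steam":
            # head out on a fresh bearing, or roughly back toward port
            bearing_home = np.degrees(np.arctan2(spec.home_port[0] - lon, spec.home_port[1] - lat)) % 360
            heading = rng.uniform(0, 360) if rng.random() < 0.5 else bearing_home
        n_steps = max(1, int(round(dur / dt_h)))
        for _ in range(n_steps):
            if t_h >= total_hours:
                break
            if phase == "fish" and spec.gear != "PS":
                sog = float(np.clip(rng.normal(speed, 0.15), 0.1, None))
                heading = (heading + rng.uniform(-15, 15)) % 360
            elif phase == "fish":  # PS setting/hauling: slow, tight turning
                sog = float(np.clip(rng.normal(speed, 0.05), 0.05, None))
                heading = (heading + rng.uniform(-40, 40)) % 360
            else:
                sog = float(np.clip(rng.normal(speed, 0.2), 0.5, None))
            lat, lon = displace(lat, lon, heading, sog * dt_h)
            t_h += dt_h
            rows.append((t_h, lat, lon, sog, heading))
    return rows


def simulate_ais_tracks(
    vessels: list[VesselSpec],
    n_days: int = 3,
    ping_interval_minutes: float = 5.0,
    seed: int = 0,
    start: str = "2020-01-01T00:00:00Z",
) -> pd.DataFrame:
    """Simulate a ping table for a fleet of vessels.

    Each vessel alternates silent port dwell, steaming legs and fishing legs
    at gear-specific speeds; pair-trawl partners move as a rigid pair ~150 m
    apart. Reported speed over ground is the speed used to integrate the
    position, so displacement-derived speeds agree with it.

    Returns a DataFrame with columns vessel_id, timestamp (UTC), lat, lon,
    sog_knots, cog_degrees, sorted by (vessel_id, timestamp).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if ping_interval_minutes <= 0:
        raise ValueError("ping_interval_minutes must be positive")
    ids = [v.vessel_id for v in vessels]
    if len(set(ids)) != len(ids):
        raise ValueError("vessel ids must be unique")
    by_id = {v.vessel_id: v for v in vessels}
    for v in vessels:
        if v.gear == "PTM" and v.pair_partner not in by_id:
            raise ValueError(f"PTM vessel {v.vessel_id} has no partner {v.pair_partner!r} in the list")

    t0 = pd.Timestamp(start)
    frames = []
    for idx, spec in enumerate(vessels):
        if spec.gear == "PTM" and spec.pair_partner < spec.vessel_id:
            continue  # partner track is generated with the pair leader
        rng = np.random.default_rng([seed, idx])
        rows = _simulate_single(spec, n_days, ping_interval_minutes, rng)
        if not rows:
            continue
        t_h, lat, lon, sog, cog = map(np.asarray, zip(*rows))
        ts = t0 + pd.to_timedelta(np.round(t_h * 3600).astype(int), unit="s")
        frames.append(
            pd.DataFrame(
                {"vessel_id": spec.vessel_id, "timestamp": ts, "lat": lat, "lon": lon,
                 "sog_knots": sog, "cog_degrees": cog}
            )
        )
        if spec.gear == "PTM":
            # partner = rigid translate of the leader track: same speeds, ~150 m off
            bearing = rng.uniform(0.0, 360.0)
            plat, plon = displace(lat, lon, bearing, PAIR_OFFSET_NM)
            frames.append(
                pd.DataFrame(
                    {"vessel_id": spec.pair_partner, "timestamp": ts, "lat": plat, "lon": plon,
                     "sog_knots": sog, "cog_degrees": cog}
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["vessel_id", "timestamp"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Species-richness grids
# ---------------------------------------------------------------------------


def simulate_etp_grid(
    bbox: tuple[float, float, float, float],
    resolution: float = 0.1,
    n_species: int = 10,
    hotspot: tuple[float, float, float] = None,
    seed: int = 0,
    p_background: float = 0.15,
) -> "etp.SpeciesGrid":
    """Simulate an ETP species-richness grid with a hotspot.

    Every species' range covers the hotspot disc (lon, lat, radius in
    degrees); outside it, each species occupies each cell independently with
    probability ``p_background``. Counts are derived from the generated
    range polygons with the same intersection rule used for real range
    maps, so re-deriving the grid from ``grid.geometries`` is an identity.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lon_min, lat_min, lon_max, lat_max = bbox
    if hotspot is None:
        hotspot = ((lon_min + lon_max) / 2, (lat_min + lat_max) / 2, (lon_max - lon_min) / 4)
    hx, hy, radius = hotspot
    if not (lon_min <= hx <= lon_max and lat_min <= hy <= lat_max):
        raise ValueError("hotspot centre must lie inside the bbox")
    disc = Point(hx, hy).buffer(radius, quad_segs=32)
    cells = etp.lattice_cells(bbox, resolution)
    rng = np.random.default_rng(seed)
    shrink = resolution * 1e-6  # keep background cells off shared edges
    geometries: dict[str, object] = {}
    for s in range(n_species):
        occupied = rng.random(len(cells)) < p_background
        squares = [
            box(lo + shrink, la + shrink, lo + resolution - shrink, la + resolution - shrink)
            for (lo, la), occ in zip(cells, occupied)
            if occ
        ]
        geom = disc
        for sq in squares:
            geom = geom.union(sq)
        geometries[f"sp{s:03d}"] = geom
    grid = etp.species_richness_grid(geometries, bbox, resolution)
    # realized-grid sanity check: the hotspot must be richer than the outside
    centres_in = np.array(
        [(lo + resolution / 2 - hx) ** 2 + (la + resolution / 2 - hy) ** 2 <= radius**2 for lo, la in cells]
    )
    counts = grid.cells["species_count"].to_numpy()
    if centres_in.any() and (~centres_in).any():
        if counts[centres_in].mean() <= counts[~centres_in].mean():
            raise RuntimeError("degenerate draw: hotspot not richer than background")
    return grid
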