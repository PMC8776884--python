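"""Gear classification from vessel movement: speed profiles, clustering, rules.

A vessel's gear is inferred from how it moves. Each trip is summarised as a
feature vector — a normalized speed histogram (0-15 kn in 0.5-kn bins), a
loitering fraction (near-zero speed away from the trip endpoints) and a
paired fraction (time spent within 300 m of another vessel at trawling
speed). Trips are optionally smoothed by k-means clustering (k = 5,
mirroring the five gear classes) before a rule cascade assigns a gear:
pairing marks pelagic pair trawlers, the dominant towing-speed mode
separates beam from otter trawlers (beam trawls tow faster, so the faster
band is checked first), sustained loitering with a near-zero speed mode
marks purse seiners, and anything else is OTHER. Vessel labels are the
majority over the vessel's trips and are validated against licence
registries with Cohen's kappa.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import cohen_kappa_score

from .ais import Trip, segment_trips
from .gears import DEFAULT_BANDS, GearSpeedBands, normalize_gear
from .geo import haversine_km

SPEED_BIN_EDGES = np.arange(0.0, 15.5, 0.5)  # 30 half-knot bins over [0, 15]
PAIRING_DISTANCE_KM = 0.3
PAIRING_WINDOW_MIN = 2.5
PAIRING_SPEED_RANGE = (2.0, 5.0)
LOITER_SPEED_KN = 0.5
LOITER_BUFFER_KM = 1.0
PAIRED_THRESHOLD = 0.3
LOITER_THRESHOLD = 0.3
NEAR_ZERO_MODE_KN = 1.5
#: bins below this speed are ignored when finding the towing-speed mode
MODE_MIN_SPEED_KN = 1.0


@dataclass
class FeatureVector:
    """Speed-profile summary of one trip."""

    histogram: np.ndarray  # 30 values, sums to 1
    loitering_fraction: float
    paired_fraction: float

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.histogram, [self.loitering_fraction, self.paired_fraction]])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "FeatureVector":
        return cls(np.asarray(arr[:30], dtype=float), float(arr[30]), float(arr[31]))

    @property
    def mode_speed(self) -> float:
        """Centre of the dominant towing-speed bin (bins below 1 kn excluded)."""
        start = int(MODE_MIN_SPEED_KN / 0.5)
        return float(SPEED_BIN_EDGES[start + int(np.argmax(self.histogram[start:]))] + 0.25)

    @property
    def full_mode_speed(self) -> float:
        """Centre of the dominant bin over the whole histogram."""
        return float(SPEED_BIN_EDGES[int(np.argmax(self.histogram))] + 0.25)


def paired_time_fraction(
    trip: Trip,
    fleet_pings: pd.DataFrame,
    distance_km: float = PAIRING_DISTANCE_KM,
    window_min: float = PAIRING_WINDOW_MIN,
    speed_range: tuple[float, float] = PAIRING_SPEED_RANGE,
) -> float:
    """Fraction of a trip's pings at towing speed with a neighbour within 300 m.

    Synchronous positions are matched by rounding timestamps to a
    2*window_min grid (so any other-vessel ping within +-window_min shares a
    slot).
    """
    p = trip.pings
    at_speed = p["sog_knots"].between(*speed_range)
    if not at_speed.any() or fleet_pings is None:
        return 0.0
    others = fleet_pings[fleet_pings["vessel_id"] != trip.vessel_id]
    if len(others) == 0:
        return 0.0
    slot = pd.Timedelta(minutes=2 * window_min)
    mine = p.loc[at_speed, ["timestamp", "lat", "lon"]].copy()
    mine["slot"] = mine["timestamp"].dt.round(slot)
    theirs = others[["timestamp", "lat", "lon"]].copy()
    theirs["slot"] = theirs["timestamp"].dt.round(slot)
    merged = mine.reset_index().merge(theirs, on="slot", suffixes=("", "_o"))
    if len(merged) == 0:
        return 0.0
    d = haversine_km(merged["lat"], merged["lon"], merged["lat_o"], merged["lon_o"])
    paired_idx = merged.loc[np.asarray(d) < distance_km, "index"].unique()
    return float(len(paired_idx) / len(p))


def speed_profile_features(
    trip: Trip,
    fleet_pings: pd.DataFrame | None = None,
    loiter_buffer_km: float = LOITER_BUFFER_KM,
) -> FeatureVector:
    """Feature vector of one trip (histogram, loitering and paired fractions)."""
    if len(trip) == 0:
        raise ValueError("cannot featurize an empty trip")
    p = trip.pings
    speeds = np.clip(p["sog_knots"].to_numpy(dtype=float), 0.0, 15.0 - 1e-9)
    hist, _ = np.histogram(speeds, bins=SPEED_BIN_EDGES)
    hist = hist / hist.sum()
    d0 = haversine_km(p["lat"], p["lon"], p["lat"].iloc[0], p["lon"].iloc[0])
    d1 = haversine_km(p["lat"], p["lon"], p["lat"].iloc[-1], p["lon"].iloc[-1])
    away = (np.asarray(d0) > loiter_buffer_km) & (np.asarray(d1) > loiter_buffer_km)
    loiter = float(np.mean((p["sog_knots"].to_numpy() < LOITER_SPEED_KN) & away))
    paired = paired_time_fraction(trip, fleet_pings) if fleet_pings is not None else 0.0
    return FeatureVector(hist, loiter, paired)


def cluster_trips(features: list[FeatureVector], k: int = 5, seed: int = 0) -> np.ndarray:
    """k-means labels over trip feature vectors (deterministic under seed)."""
    if len(features) < k:
        raise ValueError(f"need at least k={k} feature vectors, got {len(features)}")
    X = np.vstack([f.as_array() for f in features])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(X)


def smooth_features(features: list[FeatureVector], labels: np.ndarray) -> list[FeatureVector]:
    """Replace each trip's features by its cluster centroid (rule smoothing)."""
    X = np.vstack([f.as_array() for f in features])
    out = []
    for lab in labels:
        out.append(FeatureVector.from_array(X[labels == lab].mean(axis=0)))
    return out


def _gear_rule(f: FeatureVector, bands: GearSpeedBands) -> str:
    """Rule cascade mapping one trip's features to a gear label."""
    if f.paired_fraction > PAIRED_THRESHOLD:
        return "PTM"
    mode = f.mode_speed
    lo, hi = bands["TBB"]
    if lo <= mode < hi:
        return "TBB"
    lo, hi = bands["OTB"]
    if lo <= mode < hi:
        return "OTB"
    if f.loitering_fraction > LOITER_THRESHOLD and f.full_mode_speed < NEAR_ZERO_MODE_KN:
        return "PS"
    return "OTHER"


def assign_gear(trip_features: list[FeatureVector], bands: GearSpeedBands = DEFAULT_BANDS) -> str:
    """Vessel gear = majority of per-trip rule labels; ties go to OTHER."""
    if not trip_features:
        raise ValueError("vessel has no trips")
    votes = Counter(_gear_rule(f, bands) for f in trip_features)
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return "OTHER"
    return top[0][0]


def classify_vessels(
    pings: pd.DataFrame,
    bands: GearSpeedBands = DEFAULT_BANDS,
    k: int = 5,
    seed: int = 0,
    smooth: bool = True,
    max_gap_hours: float = 4.0,
    min_trip_pings: int = 5,
) -> pd.DataFrame:
    """End-to-end gear classification of every vessel in a ping table.

    Segments trips, featurizes them (pairing computed against the whole
    fleet), smooths features through k-means when enough trips exist, and
    assigns per-vessel labels. Returns vessel_id, predicted_gear, n_trips.
    """
    trips = [t for t in segment_trips(pings, max_gap_hours=max_gap_hours) if len(t) >= min_trip_pings]
    if not trips:
        raise ValueError("no usable trips in the ping table")
    feats = [speed_profile_features(t, fleet_pings=pings) for t in trips]
    if smooth and len(feats) >= k:
        labels = cluster_trips(feats, k=k, seed=seed)
        feats = smooth_features(feats, labels)
    by_vessel: dict[str, list[FeatureVector]] = {}
    for t, f in zip(trips, feats):
        by_vessel.setdefault(t.vessel_id, []).append(f)
    rows = [
        {"vessel_id": vid, "predicted_gear": assign_gear(fs, bands), "n_trips": len(fs)}
        for vid, fs in sorted(by_vessel.items())
    ]
    return pd.DataFrame(rows)


def cohen_kappa(predicted, reference) -> float:
    """Cohen's kappa between two label sequences over the five gear classes.

    1 for perfect agreement, ~0 under independence; symmetric. When both
    sides are constant and identical (expected agreement 1) kappa is 1 by
    convention.
    """
    predicted = list(predicted)
    reference = list(reference)
    if len(predicted) != len(reference):
        raise ValueError("label lists must have equal length")
    if len(predicted) == 0:
        raise ValueError("label lists must be non-empty")
    if set(predicted) == set(reference) and len(set(predicted)) == 1:
        return 1.0
    return float(cohen_kappa_score(reference, predicted))


def confusion_matrix(predicted, reference) -> pd.DataFrame:
    """Reference (rows) x predicted (columns) contingency table."""
    return pd.crosstab(
        pd.Series(reference, name="reference"), pd.Series(predicted, name="predicted")
    )


def read_registry(path) -> pd.DataFrame:
    """Read a licence registry CSV (vessel_id, licensed_gear with FAO codes)."""
    df = pd.read_csv(path)
    missing = [c for c in ("vessel_id", "licensed_gear") if c not in df.columns]
    if missing:
        raise ValueError(f"registry is missing column(s): {missing}")
    df["licensed_gear"] = df["licensed_gear"].map(normalize_gear)
    return df


def validate_against_registry(predictions: pd.DataFrame, registry: pd.DataFrame) -> dict:
    """Join predictions with the registry and score agreement.

    Returns kappa, the confusion matrix and the joined table (vessels in
    both sources only).
    """
    j = predictions.merge(registry, on="vessel_id", how="inner")
    if len(j) == 0:
        raise ValueError("no vessels shared between predictions and registry")
    kappa = cohen_kappa(j["predicted_gear"], j["licensed_gear"])
    return {
        "kappa": kappa,
        "n_vessels": int(len(j)),
        "confusion": confusion_matrix(j["predicted_gear"], j["licensed_gear"]),
        "table": j,
    }
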