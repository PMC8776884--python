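"""Run configuration: every tunable threshold of the pipeline in one place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .gears import GearSpeedBands


@dataclass
class RunConfig:
    """Flat, human-editable configuration for an end-to-end run.

    Paths left as None trigger synthetic generation (demo mode). All
    thresholds carry their documented defaults.
    """

    # input paths (None -> synthetic)
    pings_path: str | None = None
    registry_path: str | None = None
    ranges_path: str | None = None
    series_path: str | None = None
    out_dir: str = "fleetres-out"
    seed: int = 1

    # gridding
    resolution: float = 0.1
    reference_period: str | None = None

    # trip segmentation / fishing hours
    max_gap_hours: float = 4.0
    max_interval_hours: float = 1.0
    port_buffer_km: float = 1.0

    # gear speed bands (lo, hi) knots
    speed_bands: dict = field(
        default_factory=lambda: dict(GearSpeedBands().bands)
    )

    # classifier
    k_clusters: int = 5
    paired_threshold: float = 0.3
    pairing_distance_km: float = 0.3
    pairing_window_min: float = 2.5
    loiter_threshold: float = 0.3

    # assessment prior
    r_range: tuple[float, float] = (0.05, 2.0)
    kq_upper_factor: float = 4.0
    n_samples: int = 100_000

    # synthetic sizes (demo mode)
    n_per_gear: int = 4
    n_days: int = 3
    n_months: int = 71

    def bands(self) -> GearSpeedBands:
        return GearSpeedBands(bands={g: tuple(b) for g, b in self.speed_bands.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        for key in ("pings_path", "registry_path", "ranges_path", "series_path", "out_dir"):
            d.pop(key, None)
        canon = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "r_range" in data:
            data["r_range"] = tuple(data["r_range"])
        return cls(**data)


def validate_config(config: RunConfig) -> list[str]:
    """Every violated invariant, as 'field: problem' strings (empty = ok)."""
    v: list[str] = []
    if config.resolution <= 0:
        v.append("resolution: must be positive")
    if config.max_gap_hours <= 0:
        v.append("max_gap_hours: must be positive")
    if config.max_interval_hours <= 0:
        v.append("max_interval_hours: must be positive")
    if config.port_buffer_km < 0:
        v.append("port_buffer_km: must be non-negative")
    lo, hi = config.r_range
    if not (0 < lo < hi):
        v.append("r_range: must satisfy 0 < low < high")
    if config.kq_upper_factor <= 1:
        v.append("kq_upper_factor: must exceed 1")
    if config.n_samples < 1:
        v.append("n_samples: must be >= 1")
    if config.k_clusters < 1:
        v.append("k_clusters: must be >= 1")
    for frac in ("paired_threshold", "loiter_threshold"):
        if not (0 <= getattr(config, frac) <= 1):
            v.append(f"{frac}: must be in [0, 1]")
    for gear, band in config.speed_bands.items():
        blo, bhi = band
        if not (0 <= blo < bhi):
            v.append(f"speed_bands[{gear}]: must satisfy 0 <= low < high")
    if config.n_months < 2:
        v.append("n_months: must be >= 2")
    if config.n_days < 1:
        v.append("n_days: must be >= 1")
    if config.n_per_gear < 2 or config.n_per_gear % 2:
        v.append("n_per_gear: must be an even number >= 2")
    return v
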