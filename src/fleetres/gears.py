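"""Gear vocabulary shared across the package.

Five gear classes are used throughout: bottom otter trawl (OTB), pelagic
pair trawl (PTM), beam trawl (TBB), purse seine (PS) and a catch-all OTHER.
Each gear has a characteristic fishing-speed band in knots; the bands are
configurable defaults, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GEAR_LABELS: tuple[str, ...] = ("OTB", "PTM", "TBB", "PS", "OTHER")

#: Map from FAO gear codes (as found in fleet registers) to the five classes.
#: Codes not listed map to OTHER.
FAO_TO_GEAR: dict[str, str] = {
    "OTB": "OTB",
    "OTT": "OTB",
    "TBB": "TBB",
    "PTM": "PTM",
    "PTB": "PTM",
    "PS": "PS",
    "PS1": "PS",
    "PS2": "PS",
}


def normalize_gear(code: str) -> str:
    """Map a raw gear code to one of the five gear labels."""
    return FAO_TO_GEAR.get(str(code).strip().upper(), "OTHER")


@dataclass(frozen=True)
class GearSpeedBands:
    """Per-gear fishing-speed intervals [lo, hi) in knots.

    Defaults reflect typical towing/setting speeds: bottom otter trawls tow
    at 2-4.5 kn, beam trawls faster (4-7 kn), pair trawls 2-5 kn, purse
    seiners set and haul almost at rest (< 1.5 kn). OTHER is an open band.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "OTB": (2.0, 4.5),
            "TBB": (4.0, 7.0),
            "PTM": (2.0, 5.0),
            "PS": (0.0, 1.5),
            "OTHER": (0.0, 15.0),
        }
    )

    def __post_init__(self) -> None:
        for gear, (lo, hi) in self.bands.items():
            if gear not in GEAR_LABELS:
                raise ValueError(f"unknown gear label {gear!r}")
            if not (0 <= lo < hi):
                raise ValueError(f"invalid speed band for {gear}: ({lo}, {hi})")

    def __getitem__(self, gear: str) -> tuple[float, float]:
        try:
            return self.bands[gear]
        except KeyError:
            raise KeyError(f"unknown gear label {gear!r}") from None

    def contains(self, gear: str, speed) -> bool | "object":
        """True where ``speed`` (scalar or array) is in gear's band [lo, hi)."""
        lo, hi = self[gear]
        return (speed >= lo) & (speed < hi)

    def widened(self, gear: str, lo: float, hi: float) -> "GearSpeedBands":
        new = dict(self.bands)
        new[gear] = (lo, hi)
        return GearSpeedBands(bands=new)


DEFAULT_BANDS = GearSpeedBands()
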