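"""Monthly fleet effort series: the abundance index of the fleet-as-stock model.

A fleet here is the set of vessels that use the same gear; its total fishing
hours in month t, A_t, play the role of the abundance of a stock exposed to
stress factors (seasonal bans, decommissioning, market shocks) that remove
fishing hours the way fishing pressure removes biomass.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CSV_COLUMNS = ("fleet", "year", "month", "hours")


class EffortSeries:
    """Ordered, strictly positive monthly fishing-hour totals for one fleet.

    Parameters
    ----------
    fleet : str
        Gear label of the fleet (e.g. "PS").
    months : sequence of (year, month) tuples or pandas PeriodIndex
        Consecutive calendar months.
    hours : array-like of float
        Total fishing hours per month; strictly positive.
    """

    def __init__(self, fleet: str, months, hours) -> None:
        if isinstance(months, pd.PeriodIndex):
            idx = months
        else:
            idx = pd.PeriodIndex([pd.Period(year=y, month=m, freq="M") for y, m in months], freq="M")
        hours = np.asarray(hours, dtype=float)
        if len(idx) != len(hours):
            raise ValueError("months and hours must have equal length")
        if len(idx) == 0:
            raise ValueError("effort series must be non-empty")
        diffs = np.diff(idx.asi8)
        if len(diffs) and not np.all(diffs == 1):
            raise ValueError("months must be consecutive")
        if not np.all(hours > 0):
            raise ValueError("effort hours must be strictly positive")
        self.fleet = str(fleet)
        self.months = idx
        self.hours = hours

    def __len__(self) -> int:
        return len(self.hours)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EffortSeries(fleet={self.fleet!r}, {len(self)} months "
            f"{self.months[0]}..{self.months[-1]})"
        )

    @property
    def year_month(self) -> list[tuple[int, int]]:
        return [(p.year, p.month) for p in self.months]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fleet": self.fleet,
                "year": self.months.year,
                "month": self.months.month,
                "hours": self.hours,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fleet: str | None = None) -> "EffortSeries":
        missing = [c for c in ("year", "month", "hours") if c not in df.columns]
        if missing:
            raise ValueError(f"effort series table is missing columns: {missing}")
        if fleet is not None and "fleet" in df.columns:
            df = df[df["fleet"] == fleet]
        elif fleet is None:
            fleets = df["fleet"].unique() if "fleet" in df.columns else ["ALL"]
            if len(fleets) > 1:
                raise ValueError(f"multiple fleets present ({list(fleets)}); pass fleet=")
            fleet = fleets[0]
        df = df.sort_values(["year", "month"])
        months = list(zip(df["year"].astype(int), df["month"].astype(int)))
        return cls(fleet, months, df["hours"].to_numpy(dtype=float))

    @classmethod
    def read_csv(cls, path, fleet: str | None = None) -> "EffortSeries":
        return cls.from_dataframe(pd.read_csv(path), fleet=fleet)


def read_all_fleets(path) -> dict[str, EffortSeries]:
    """Read a multi-fleet effort CSV into one EffortSeries per fleet."""
    df = pd.read_csv(path)
    if "fleet" not in df.columns:
        return {"ALL": EffortSeries.from_dataframe(df)}
    return {f: EffortSeries.from_dataframe(df, fleet=f) for f in sorted(df["fleet"].unique())}
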