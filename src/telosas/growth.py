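"""Population doublings and percent replicative potential from daily OD600.

The culturing protocol dilutes every clone to a fixed OD600 each morning and
reads the density again after 24 h.  Doublings per day follow from the log2
OD ratio; the replicative potential of a clone on a given day is its OD600
after growth expressed as a percentage of the *reference* clone's first
reading (the empty-vector-transformed, or complemented, sister culture).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GrowthSeries

__all__ = ["PotentialSeries", "population_doublings", "replicative_potential"]


@dataclass
class PotentialSeries:
    """Per-clone daily (day, pd_cumulative, potential_pct) records."""

    clone_id: str
    condition: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"day", "pd_cumulative", "potential_pct"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"potential frame missing columns: {sorted(missing)}")

    @property
    def days(self) -> np.ndarray:
        return self.frame["day"].to_numpy()

    @property
    def pd_cumulative(self) -> np.ndarray:
        return self.frame["pd_cumulative"].to_numpy(dtype=float)

    @property
    def potential_pct(self) -> np.ndarray:
        return self.frame["potential_pct"].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "condition", self.condition)
        out.insert(0, "clone_id", self.clone_id)
        return out


def population_doublings(od_end: float, od_start: float) -> float:
    """Doublings between two OD600 readings, ``log2(od_end / od_start)``.

    Negative values are allowed (a culture that shrank); non-positive ODs
    are not.  Additive over consecutive intervals.
    """
    od_end = np.asarray(od_end, dtype=float)
    od_start = np.asarray(od_start, dtype=float)
    if np.any(od_end <= 0) or np.any(od_start <= 0):
        raise ValueError("OD600 readings must be positive")
    out = np.log2(od_end / od_start)
    return float(out) if out.ndim == 0 else out


def _check_daily(days: np.ndarray, label: str) -> None:
    if np.any(np.diff(days) != 1):
        raise ValueError(
            f"{label} has missing or duplicated days; the protocol is strictly "
            "daily and gaps are not interpolated"
        )


def replicative_potential(
    series: GrowthSeries,
    reference: GrowthSeries,
    day_matched: bool = False,
) -> PotentialSeries:
    """Percent replicative potential of ``series`` against ``reference``.

    By default every ``od_end`` of ``series`` is divided by the *first*
    (day-0) ``od_end`` of the reference clone and scaled to percent, so the
    reference's own day 0 maps to exactly 100.  With ``day_matched=True``
    each day is instead divided by the reference reading of the same day
    (a variant normalization, not the default convention).

    Both series must cover consecutive days and, for the day-matched
    variant, the same days.
    """
    s = series.frame.sort_values("day").reset_index(drop=True)
    r = reference.frame.sort_values("day").reset_index(drop=True)
    _check_daily(s["day"].to_numpy(), "series")
    _check_daily(r["day"].to_numpy(), "reference")
    if day_matched:
        merged = s.merge(r[["day", "od_end"]], on="day", suffixes=("", "_ref"))
        if len(merged) != len(s):
            raise ValueError("series and reference days are misaligned")
        potential = 100.0 * merged["od_end"] / merged["od_end_ref"]
        frame = pd.DataFrame(
            {
                "day": merged["day"],
                "pd_cumulative": merged["pd_cumulative"],
                "potential_pct": potential,
            }
        )
    else:
        ref0 = float(r["od_end"].iloc[0])
        if ref0 <= 0:
            raise ValueError("reference day-0 OD600 must be positive")
        frame = pd.DataFrame(
            {
                "day": s["day"],
                "pd_cumulative": s["pd_cumulative"],
                "potential_pct": 100.0 * s["od_end"] / ref0,
            }
        )
    return PotentialSeries(
        clone_id=series.clone_id, condition=series.condition, frame=frame
    )
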