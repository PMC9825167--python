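"""The survivor-associated-senescence (SAS) rate statistic.

SAS rate is quantified as the number of population doublings a clone needs
to reach its lowest replicative potential: the percent-potential profile is
smoothed by averaging consecutive pairs, local minima are admitted only if
no value in a +/-k neighbourhood undercuts them, minima in the erratic
first few days are excluded, and PDs are counted from the start of the
propagation to the selected minimum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .growth import PotentialSeries

__all__ = [
    "SasResult",
    "SasComparison",
    "smooth_pairwise",
    "find_local_minima",
    "select_minimum",
    "sas_pd_count",
    "analyze_series",
    "compare_sas",
]


@dataclass
class SasResult:
    """Outcome of the SAS-rate measurement for one clone."""

    clone_id: str
    condition: str
    minima_indices: list[int]
    selected_index: int
    pd_to_min: float

    def __post_init__(self) -> None:
        if self.selected_index not in self.minima_indices:
            raise ValueError("selected_index must be one of minima_indices")
        if self.pd_to_min < 0:
            raise ValueError("pd_to_min must be non-negative")


@dataclass
class SasComparison:
    """Group comparison of PDs-to-minimum (thin t-test wrapper)."""

    mean_a: float
    mean_b: float
    values_a: list[float]
    values_b: list[float]
    t_statistic: float | None
    p_value: float | None

    @property
    def mean_difference(self) -> float:
        return self.mean_a - self.mean_b


def smooth_pairwise(values: Sequence[float], passes: int = 1) -> np.ndarray:
    """Average consecutive pairs; output is one element shorter per pass."""
    v = np.asarray(values, dtype=float)
    if passes < 1:
        raise ValueError("passes must be >= 1")
    for _ in range(passes):
        if len(v) < 2:
            raise ValueError("need at least 2 values to smooth")
        v = 0.5 * (v[:-1] + v[1:])
    return v


def find_local_minima(values: Sequence[float], k: int = 4) -> list[int]:
    """Positions whose value is undercut nowhere in a full +/-k window.

    Position ``i`` qualifies only if ``i - k`` and ``i + k`` both exist and
    no value in ``values[i-k : i+k+1]`` is strictly less than ``values[i]``.
    Ties do not disqualify a candidate, but a later position tied with an
    already-accepted one is suppressed when it lies inside the same window
    or belongs to the same flat run (so a plateau yields one minimum, at its
    earliest qualifying position).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= 2 * k:
        raise ValueError(f"series of length {n} too short for any full +/-{k} window")
    accepted: list[int] = []
    for i in range(k, n - k):
        window = v[i - k : i + k + 1]
        if np.any(window < v[i]):
            continue
        duplicate = False
        for j in reversed(accepted):
            if v[j] != v[i]:
                continue
            if i - j <= k or np.all(v[j : i + 1] == v[i]):
                duplicate = True
                break
        if not duplicate:
            accepted.append(i)
    return accepted


def select_minimum(
    minima: Sequence[int],
    series: PotentialSeries,
    exclude_days: int = 3,
    forced: int | None = None,
) -> int:
    """Pick the minimum that defines the SAS rate.

    Returns the earliest admissible minimum whose day lies after the
    ``exclude_days`` exclusion window (growth is frequently erratic in the
    first days after transfer from solid media).  ``forced`` overrides the
    rule entirely, supporting a manually chosen minimum, e.g. picked for
    similarity between the profiles of paired conditions.

    ``minima`` are indices into the smoothed profile; index ``i`` is mapped
    to the day of record ``i`` (the first of the averaged pair).
    """
    if forced is not None:
        return int(forced)
    days = series.days
    admissible = [i for i in minima if days[i] > exclude_days]
    if not admissible:
        raise ValueError(
            f"no admissible local minimum after day {exclude_days}; "
            "supply forced= to override"
        )
    return min(admissible)


def sas_pd_count(series: PotentialSeries, selected: int) -> float:
    """PDs between the start of propagation and the selected minimum."""
    pds = series.pd_cumulative
    if not 0 <= selected < len(pds):
        raise ValueError("selected index outside the series")
    return float(pds[selected] - pds[0])


def analyze_series(
    series: PotentialSeries,
    k: int = 4,
    exclude_days: int = 3,
    forced: int | None = None,
    smooth_passes: int = 1,
) -> SasResult:
    """Full SAS-rate measurement on one potential series."""
    smoothed = smooth_pairwise(series.potential_pct, passes=smooth_passes)
    minima = find_local_minima(smoothed, k=k)
    selected = select_minimum(minima, series, exclude_days=exclude_days, forced=forced)
    if selected not in minima:
        minima = sorted(minima + [selected])
    return SasResult(
        clone_id=series.clone_id,
        condition=series.condition,
        minima_indices=list(minima),
        selected_index=selected,
        pd_to_min=sas_pd_count(series, selected),
    )


def compare_sas(
    group_a: Sequence[SasResult],
    group_b: Sequence[SasResult],
    welch: bool = False,
) -> SasComparison:
    """Compare PDs-to-minimum between two groups with a two-sided t-test.

    The test is the standard unpaired two-tailed Student's t-test
    (``welch=True`` drops the equal-variance assumption); with fewer than
    two clones per group only the means are reported.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = [r.pd_to_min for r in group_a]
    b = [r.pd_to_min for r in group_b]
    t_stat = p_val = None
    if len(a) >= 2 and len(b) >= 2:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p_val = float(t_stat), float(p_val)
    return SasComparison(
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        values_a=a,
        values_b=b,
        t_statistic=t_stat,
        p_value=p_val,
    )
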