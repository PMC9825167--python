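"""Telomere length from gel lanes and shortening-rate estimation.

Southern-blot densitometry gives only a monotone migration coordinate, so
blot-derived lengths stay *relative* (normalized to the longest telomere);
absolute bp-valued rates come from telomere-PCR length tables.  Two rate
estimators are provided: the mean of consecutive difference quotients
(bp lost per PD between successive time points) and the ordinary
least-squares slope of length on PD.  Both report shortening as a positive
rate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal, stats

from .simulate import LaneProfile

__all__ = [
    "RateEstimate",
    "detect_bands",
    "relative_length",
    "percent_of_first",
    "rate_diffquot",
    "rate_regression",
    "rate_fold_change",
]


@dataclass
class RateEstimate:
    """A telomere shortening-rate estimate.

    ``rate`` is in bp per PD with shortening positive (for the regression
    method the stored rate is the negated OLS slope).  ``stderr`` is the
    standard error of the regression slope, ``None`` for the difference-
    quotient method.
    """

    clone_id: str
    condition: str
    method: str  # "diffquot" | "regression"
    rate: float
    n_points: int
    intercept: float | None = None
    stderr: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("diffquot", "regression"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_points < 2:
            raise ValueError("a rate estimate needs at least 2 points")


def detect_bands(profile: LaneProfile, min_prominence: float = 0.1) -> np.ndarray:
    """Detect band positions as prominent intensity peaks on a lane profile.

    ``min_prominence`` is a fraction of the profile's dynamic range; peaks
    less prominent than that are treated as background.  Detected positions
    (on the coordinate axis, ascending) are also stored on the profile.
    """
    y = profile.intensities
    dynamic = float(y.max() - y.min())
    if dynamic <= 0:
        raise ValueError("no peak above threshold: profile is flat")
    peaks, _ = signal.find_peaks(y, prominence=min_prominence * dynamic)
    if peaks.size == 0:
        raise ValueError("no peak above threshold")
    positions = profile.coordinates[peaks]
    profile.detected_bands = positions
    return positions


def relative_length(positions: Sequence[float]) -> np.ndarray:
    """Normalize band positions to the longest telomere.

    The position of the longest telomere (largest coordinate) is set to 1
    and all others divided by it, giving values in (0, 1].  Positions tied
    with the maximum all map to 1.
    """
    p = np.asarray(positions, dtype=float)
    if p.size == 0:
        raise ValueError("no positions to normalize")
    if np.any(p <= 0):
        raise ValueError("positions must be positive")
    return p / p.max()


def percent_of_first(lengths: Sequence[float], reference_first: float) -> np.ndarray:
    """Lengths as percent of a reference first-time-point length."""
    if reference_first <= 0:
        raise ValueError("reference_first must be positive")
    L = np.asarray(lengths, dtype=float)
    return 100.0 * L / reference_first


def _check_series(lengths, pds) -> tuple[np.ndarray, np.ndarray]:
    L = np.asarray(lengths, dtype=float)
    P = np.asarray(pds, dtype=float)
    if L.shape != P.shape:
        raise ValueError("lengths and pds must have equal length")
    if L.size < 2:
        raise ValueError("need at least 2 time points")
    return L, P


def rate_diffquot(
    lengths: Sequence[float],
    pds: Sequence[float],
    clone_id: str = "",
    condition: str = "",
) -> RateEstimate:
    """Mean of consecutive difference quotients, (L[i-1] - L[i]) / dPD."""
    L, P = _check_series(lengths, pds)
    dpd = np.diff(P)
    if np.any(dpd <= 0):
        raise ValueError("pds must be strictly increasing (no duplicate PDs)")
    ratios = (L[:-1] - L[1:]) / dpd
    return RateEstimate(
        clone_id=clone_id,
        condition=condition,
        method="diffquot",
        rate=float(ratios.mean()),
        n_points=int(L.size),
    )


def rate_regression(
    lengths: Sequence[float],
    pds: Sequence[float],
    clone_id: str = "",
    condition: str = "",
) -> RateEstimate:
    """Shortening rate as the negated OLS slope of length on PD."""
    L, P = _check_series(lengths, pds)
    if L.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(P) == 0:
        raise ValueError("degenerate design: all PDs equal")
    fit = stats.linregress(P, L)
    return RateEstimate(
        clone_id=clone_id,
        condition=condition,
        method="regression",
        rate=float(-fit.slope),
        n_points=int(L.size),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
    )


def rate_fold_change(treatment: RateEstimate, control: RateEstimate) -> float:
    """Ratio of a treatment shortening rate to its same-day control."""
    if treatment.method != control.method:
        raise ValueError(
            f"method mismatch: {treatment.method!r} vs {control.method!r}"
        )
    if control.rate == 0:
        raise ValueError("control rate is zero; fold change undefined")
    return treatment.rate / control.rate
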