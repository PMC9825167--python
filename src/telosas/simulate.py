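"""Stochastic generator of clonal survivor dynamics and downstream assay data.

The model: a telomerase-negative survivor clone carries one tracked telomere
that loses a few bp per population doubling (PD).  While the telomere is
longer than the critical length nothing else happens; once critically short,
an HDR (break-induced replication) event may fire at each PD, re-extending
the tract either by a fixed Y'-element-like amount (type I) or by a
heavy-tailed lognormal amount of TG repeats (type II).  Replicative
potential tracks the telomere: daily doublings fall from a healthy maximum
to a senescent minimum as the telomere shortens, and TERRA rises up to
``terra_fold_short``-fold as the telomere approaches the critical length.

Every downstream input of the analysis pipeline — daily OD600 tables, TERRA
Ct pairs, gel-lane intensity profiles, ChIP-qPCR signal tables — is emitted
by functions in this module, each with a ground-truth sidecar so that
recovery can be tested without any experimental data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = [
    "TelomereTrajectory",
    "GrowthSeries",
    "LaneProfile",
    "doublings_per_day",
    "terra_fold",
    "simulate_telomere_trajectory",
    "simulate_daily_culture",
    "simulate_terra_cts",
    "generate_lane_profile",
    "generate_chip_dataset",
    "generate_cell_cycle_cts",
]

EVENT_NONE = "none"
EVENT_TYPE1 = "type1"
EVENT_TYPE2 = "type2"

# Telomere length floor (bp); a tract never erodes to nothing because the
# chromosome end would be lost first.
_MIN_LENGTH = 10.0

# Below the critical length, daily doublings halve every this many bp of
# further loss (keeps the growth response strictly monotone in length).
_SUBCRITICAL_HALVING_BP = 25.0

# Gaussian band width (migration-coordinate units) of simulated gel bands.
_BAND_SIGMA = 0.012

# Baseline TERRA abundance at long telomeres, as percent of the actin
# reference transcript (sets the baseline delta-Ct of ~6.6 cycles).
_TERRA_BASELINE_PCT = 1.0

# Mean Ct of the actin reference amplicon.
_REFERENCE_CT = 17.5


# ---------------------------------------------------------------------------
# container types


@dataclass
class TelomereTrajectory:
    """Per-clone telomere length history.

    ``pd`` is strictly increasing cumulative population doublings, ``length``
    the tract length in bp at that PD, and ``event`` annotates HDR
    re-elongations (``"none"``, ``"type1"`` or ``"type2"``).  ``day_starts``
    holds the cumulative PD at each day boundary (length ``n_days + 1``) so
    the culturing protocol can be replayed consistently.
    """

    clone_id: str
    pd: np.ndarray
    length: np.ndarray
    event: np.ndarray
    day_starts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pd = np.asarray(self.pd, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.event = np.asarray(self.event, dtype=object)
        if not (len(self.pd) == len(self.length) == len(self.event)):
            raise ValueError("pd, length and event must have equal lengths")
        if len(self.pd) == 0:
            raise ValueError("trajectory must contain at least one record")
        if np.any(np.diff(self.pd) <= 0):
            raise ValueError("pd must be strictly increasing")
        if np.any(self.length <= 0):
            raise ValueError("lengths must be positive")

    def length_at_pd(self, pd: float) -> float:
        """Length at cumulative PD ``pd`` (step lookup, last record <= pd)."""
        i = int(np.searchsorted(self.pd, pd, side="right")) - 1
        return float(self.length[max(i, 0)])

    def first_event_index(self) -> int | None:
        idx = np.flatnonzero(self.event != EVENT_NONE)
        return int(idx[0]) if idx.size else None

    def pre_event_segment(self) -> tuple[np.ndarray, np.ndarray]:
        """(pds, lengths) of the initial shortening-only segment."""
        i = self.first_event_index()
        stop = len(self.pd) if i is None else i
        return self.pd[:stop], self.length[:stop]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone_id": self.clone_id,
                "pd": self.pd,
                "length_bp": self.length,
                "event": self.event,
            }
        )


@dataclass
class GrowthSeries:
    """Per-clone daily culturing records.

    ``frame`` has columns ``day`` (int), ``od_start``, ``od_end`` (OD600)
    and ``pd_cumulative`` (PD measured as accumulated log2 od ratios).
    ``length_truth`` is the simulator's ground-truth telomere length (bp) at
    the start of each day; it is ``None`` for series read from real tables.
    """

    clone_id: str
    condition: str
    frame: pd.DataFrame
    length_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        required = {"day", "od_start", "od_end", "pd_cumulative"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"growth frame missing columns: {sorted(missing)}")
        if len(self.frame) == 0:
            raise ValueError("growth series must contain at least one day")

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "condition", self.condition)
        out.insert(0, "clone_id", self.clone_id)
        return out


@dataclass
class LaneProfile:
    """A 1-D gel densitometry profile over a migration coordinate.

    ``true_centers`` records the generative band centers (ground truth for
    recovery tests); ``detected_bands`` is filled by band detection.
    """

    coordinates: np.ndarray
    intensities: np.ndarray
    true_centers: np.ndarray | None = None
    detected_bands: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coordinates.shape != self.intensities.shape:
            raise ValueError("coordinates and intensities must match in shape")
        if self.coordinates.size == 0:
            raise ValueError("profile must be non-empty")
        if np.any(np.diff(self.coordinates) <= 0):
            raise ValueError("coordinates must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coordinate": self.coordinates, "intensity": self.intensities}
        )


# ---------------------------------------------------------------------------
# deterministic response functions


def doublings_per_day(length: float | np.ndarray, config: SimConfig) -> float | np.ndarray:
    """Daily population doublings as a function of telomere length.

    Linear between ``min_doublings_per_day`` at the critical length and
    ``max_doublings_per_day`` at the senescence-onset length, clamped at the
    maximum above it.  Below the critical length growth keeps declining
    (halving every ``_SUBCRITICAL_HALVING_BP`` bp of further loss) so that
    the response is strictly increasing in length over the whole senescent
    range — the day a clone grows worst is exactly the day its telomere is
    shortest.
    """
    L = np.asarray(length, dtype=float)
    span = config.senesce_length - config.critical_length
    frac = np.clip((L - config.critical_length) / span, 0.0, 1.0)
    d = config.min_doublings_per_day + frac * (
        config.max_doublings_per_day - config.min_doublings_per_day
    )
    deficit = np.clip(config.critical_length - L, 0.0, None)
    d = np.where(
        deficit > 0,
        config.min_doublings_per_day * 2.0 ** (-deficit / _SUBCRITICAL_HALVING_BP),
        d,
    )
    return float(d) if np.isscalar(length) else d


def terra_fold(length: float | np.ndarray, config: SimConfig) -> float | np.ndarray:
    """Expected TERRA fold over the long-telomere baseline at a given length.

    A logistic in length, centred between the critical and senescence-onset
    lengths with width ``terra_length_scale``, rescaled so the fold is
    exactly 1 at/above ``senesce_length`` and exactly ``terra_fold_short``
    at/below ``critical_length``.  Monotone non-increasing in length.
    """
    L = np.clip(np.asarray(length, dtype=float), config.critical_length,
                config.senesce_length)
    mid = 0.5 * (config.critical_length + config.senesce_length)
    s = config.terra_length_scale

    def _raw(x):
        return 1.0 / (1.0 + np.exp((x - mid) / s))

    lo, hi = _raw(config.senesce_length), _raw(config.critical_length)
    t = (_raw(L) - lo) / (hi - lo)
    f = 1.0 + (config.terra_fold_short - 1.0) * t
    return float(f) if np.isscalar(length) else f


# ---------------------------------------------------------------------------
# stochastic generators


def _draw_loss(rng: np.random.Generator, config: SimConfig, frac: float = 1.0) -> float:
    loss = rng.normal(config.shorten_rate_mean, config.shorten_rate_sd)
    return max(loss, 0.0) * frac


def simulate_telomere_trajectory(
    config: SimConfig, seed: int | np.random.SeedSequence, clone_id: str = "clone"
) -> TelomereTrajectory:
    """Simulate one clone's telomere over ``config.n_days`` of daily culture.

    Each day contributes ``doublings_per_day(length_at_day_start)`` PDs.  Per
    PD the telomere either erodes by a truncated-normal draw or — while
    below the critical length, with probability ``hdr_prob_per_pd`` — is
    re-extended by an HDR event that replaces that division's attrition
    (type II with probability ``type2_fraction``, lognormal gain; otherwise
    type I, fixed gain).  Fractional end-of-day doublings scale both the
    attrition draw and the event probability.
    """
    rng = np.random.default_rng(seed)
    L = float(config.initial_length)
    pd_cum = 0.0
    pds = [0.0]
    lengths = [L]
    events = [EVENT_NONE]
    day_starts = [0.0]

    def _step(frac: float) -> None:
        nonlocal L, pd_cum
        pd_cum += frac
        if L < config.critical_length and rng.random() < config.hdr_prob_per_pd * frac:
            if rng.random() < config.type2_fraction:
                gain = float(
                    rng.lognormal(config.type2_gain_log_mean, config.type2_gain_log_sd)
                )
                ev = EVENT_TYPE2
            else:
                gain = float(config.type1_gain)
                ev = EVENT_TYPE1
            L += gain
        else:
            L = max(L - _draw_loss(rng, config, frac), _MIN_LENGTH)
            ev = EVENT_NONE
        pds.append(pd_cum)
        lengths.append(L)
        events.append(ev)

    for _ in range(config.n_days):
        d = doublings_per_day(L, config)
        whole = int(math.floor(d))
        frac = d - whole
        for _ in range(whole):
            _step(1.0)
        if frac > 1e-12:
            _step(frac)
        day_starts.append(pd_cum)

    return TelomereTrajectory(
        clone_id=clone_id,
        pd=np.array(pds),
        length=np.array(lengths),
        event=np.array(events, dtype=object),
        day_starts=np.array(day_starts),
    )


def simulate_daily_culture(
    traj: TelomereTrajectory,
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    condition: str = "EV",
) -> GrowthSeries:
    """Replay the daily dilution protocol over a trajectory.

    Every morning the culture is diluted to ``dilution_od``; after 24 h the
    OD600 is ``dilution_od * 2**doublings`` times multiplicative lognormal
    noise with CV ``od_noise_cv``.  ``pd_cumulative`` accumulates the
    realized (measured) doublings ``log2(od_end / od_start)``.
    """
    if traj.day_starts is None:
        raise ValueError("trajectory lacks day_starts; simulate it day-by-day")
    rng = np.random.default_rng(seed)
    n_days = len(traj.day_starts) - 1
    if n_days < 1:
        raise ValueError("trajectory spans no full day of growth")
    sigma = math.sqrt(math.log1p(config.od_noise_cv**2))
    rows = []
    lengths = []
    pd_meas = 0.0
    for day in range(n_days):
        pd0, pd1 = traj.day_starts[day], traj.day_starts[day + 1]
        L0 = traj.length_at_pd(pd0)
        lengths.append(L0)
        noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
        od_end = config.dilution_od * 2.0 ** (pd1 - pd0) * noise
        pd_meas += math.log2(od_end / config.dilution_od)
        rows.append((day, config.dilution_od, od_end, pd_meas))
    frame = pd.DataFrame(rows, columns=["day", "od_start", "od_end", "pd_cumulative"])
    return GrowthSeries(
        clone_id=traj.clone_id,
        condition=condition,
        frame=frame,
        length_truth=np.array(lengths),
    )


def simulate_terra_cts(
    traj: TelomereTrajectory,
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    group: str = "EV",
    locus: str = "1L",
) -> pd.DataFrame:
    """Emit a TERRA RT-qPCR Ct table sampled at each trajectory record.

    A fold ``f`` over the long-telomere baseline shifts the target Ct by
    ``-log2(f)`` relative to the reference; both Cts carry independent
    Gaussian noise of SD ``ct_noise_sd``.  Ground-truth columns
    (``length_bp``, ``fold_truth``) accompany the measurements.
    """
    rng = np.random.default_rng(seed)
    n = len(traj.pd)
    fold = np.asarray(terra_fold(traj.length, config))
    baseline_dct = math.log2(100.0 / _TERRA_BASELINE_PCT)
    ct_ref = _REFERENCE_CT + rng.normal(0.0, config.ct_noise_sd, size=n)
    ct_tgt = (
        ct_ref
        + baseline_dct
        - np.log2(fold)
        + rng.normal(0.0, config.ct_noise_sd, size=n)
    )
    return pd.DataFrame(
        {
            "sample_id": [f"{traj.clone_id}_pd{p:.1f}" for p in traj.pd],
            "group": group,
            "locus": locus,
            "pd": traj.pd,
            "length_bp": traj.length,
            "fold_truth": fold,
            "ct_target": ct_tgt,
            "ct_reference": ct_ref,
        }
    )


def generate_lane_profile(
    lengths: Sequence[float],
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    n_points: int = 1024,
    amplitude: float = 1.0,
    background: float = 0.02,
) -> LaneProfile:
    """Render a densitometry lane profile from telomere lengths.

    Band centers are a linear (through-origin, hence ratio-preserving) map
    of length onto the migration coordinate in (0, 1), jittered by
    ``band_position_noise_sd``; each band is a Gaussian of width
    ``_BAND_SIGMA`` on a small non-negative noisy background.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise ValueError("at least one band length is required")
    if np.any(lengths <= 0):
        raise ValueError("band lengths must be positive")
    rng = np.random.default_rng(seed)
    scale = 0.9 / float(lengths.max())
    centers = lengths * scale
    jitter = rng.normal(0.0, config.band_position_noise_sd, size=lengths.size)
    x = np.linspace(0.0, 1.0, n_points)
    y = np.full(n_points, background)
    if background > 0:
        y = y + np.abs(rng.normal(0.0, background / 4.0, size=n_points))
    for c, j in zip(centers, jitter):
        y = y + amplitude * np.exp(-0.5 * ((x - (c + j)) / _BAND_SIGMA) ** 2)
    return LaneProfile(coordinates=x, intensities=y, true_centers=centers)


def generate_chip_dataset(
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    enrichment: dict[str, float] | None = None,
    n_replicates: int = 3,
    input_fraction: float = 0.05,
    tagged_pct: float = 2.0,
    untagged_pct: float = 0.2,
) -> pd.DataFrame:
    """Emit a ChIP-qPCR signal table for survivor vs wild-type cells.

    ``enrichment`` maps locus -> true survivor/wild-type binding ratio
    (default: halved binding at telomeric loci, unchanged at the actin
    control, the structure seen for the Rat1 exonuclease).  For each
    replicate day, IP and Input signals are emitted for every genotype x
    tag x locus cell with multiplicative lognormal noise of CV
    ``od_noise_cv``; untagged strains share a common background percent
    input.  ``true_ratio`` carries the generative ground truth.
    """
    if enrichment is None:
        enrichment = {"1L": 0.5, "15L": 0.5, "6Y": 0.5, "ACT1": 1.0}
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(config.od_noise_cv**2))

    def _noise() -> float:
        return math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0

    rows = []
    for day in range(n_replicates):
        for locus, ratio in enrichment.items():
            for genotype in ("wild-type", "survivor"):
                for tag in ("tagged", "untagged"):
                    if tag == "tagged":
                        pct = tagged_pct * (ratio if genotype == "survivor" else 1.0)
                    else:
                        pct = untagged_pct
                    input_signal = 50.0 * _noise()
                    ip_signal = pct / 100.0 * (input_signal / input_fraction) * _noise()
                    rows.append(
                        (
                            f"{genotype}_{tag}_{locus}_d{day}",
                            genotype,
                            tag,
                            locus,
                            day,
                            ip_signal,
                            input_signal,
                            input_fraction,
                            ratio,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "genotype",
            "tag",
            "locus",
            "day",
            "ip_signal",
            "input_signal",
            "input_fraction",
            "true_ratio",
        ],
    )


def generate_cell_cycle_cts(
    config: SimConfig,
    seed: int | np.random.SeedSequence,
    decline_pct: float = 29.0,
    early_s_pct: float = 2.0,
    n_replicates: int = 4,
    group: str = "wild-type",
) -> pd.DataFrame:
    """Emit TERRA Ct pairs for an early-S vs G2 cell-cycle comparison.

    TERRA peaks in early S phase and declines by ``decline_pct`` percent as
    replication completes; ``early_s_pct`` is the early-S TERRA level as
    percent of the actin reference.  Ct noise as in ``simulate_terra_cts``.
    """
    if not 0.0 <= decline_pct < 100.0:
        raise ValueError("decline_pct must be in [0, 100)")
    rng = np.random.default_rng(seed)
    g2_pct = early_s_pct * (1.0 - decline_pct / 100.0)
    rows = []
    for rep in range(n_replicates):
        for phase, pct in (("early_S", early_s_pct), ("G2", g2_pct)):
            ct_ref = _REFERENCE_CT + rng.normal(0.0, config.ct_noise_sd)
            ct_tgt = (
                ct_ref
                + math.log2(100.0 / pct)
                + rng.normal(0.0, config.ct_noise_sd)
            )
            rows.append((f"{group}_{phase}_r{rep}", group, phase, ct_tgt, ct_ref, pct))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "phase", "ct_target", "ct_reference", "pct_truth"],
    )
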