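"""Simulation parameters for clonal survivor telomere/growth dynamics.

A :class:`SimConfig` bundles every knob of the stochastic generator:
telomere attrition, HDR-mediated re-elongation, the TERRA/length coupling,
the daily dilution-culturing protocol, and measurement noise.  Defaults
describe a telomerase-negative type II survivor clone propagated by daily
dilution: a single natural telomere starting near 350 bp that shortens at
~2.7 bp per population doubling (PD) and recombines only once critically
short.
"""
from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass

import yaml

__all__ = ["SimConfig"]


@dataclass(frozen=True)
class SimConfig:
    """All simulator parameters, with units.

    Parameters
    ----------
    shorten_rate_mean, shorten_rate_sd : float
        Mean and SD of the per-PD telomere loss in bp.  Draws are truncated
        at zero (a division never lengthens a telomere by attrition).
    initial_length : float
        Starting telomere tract length in bp.
    critical_length : float
        Length in bp below which the telomere is "critically short": HDR
        becomes permissive and TERRA induction saturates.
    senesce_length : float
        Length in bp at which the growth penalty begins; above it the
        culture doubles at ``max_doublings_per_day``.  Must lie strictly
        between ``critical_length`` and ``initial_length``.
    hdr_prob_per_pd : float
        Per-PD probability of an HDR elongation event while the telomere is
        below ``critical_length``.
    type2_fraction : float
        Probability that a firing HDR event is type II (heterogeneous
        TG-repeat addition) rather than type I (fixed Y'-element-like gain).
    type1_gain : float
        Fixed bp gain of a type I event.
    type2_gain_log_mean, type2_gain_log_sd : float
        Parameters of the lognormal bp gain of a type II event
        (heavy-tailed, strictly positive).
    terra_fold_short : float
        Fold increase of TERRA at/below ``critical_length`` relative to the
        long-telomere baseline (>= 1).
    terra_length_scale : float
        Width (bp) of the logistic transition of TERRA induction between
        ``senesce_length`` and ``critical_length``.
    max_doublings_per_day, min_doublings_per_day : float
        Population doublings per 24 h at healthy length (>= senesce_length)
        and at exactly ``critical_length``.  Below the critical length
        growth keeps declining smoothly (see ``simulate.doublings_per_day``).
    dilution_od : float
        OD600 to which every culture is diluted each morning.
    od_noise_cv : float
        Coefficient of variation of the multiplicative (lognormal) noise on
        OD600 readings; also used for ChIP signal noise.
    ct_noise_sd : float
        SD in cycles of the additive Gaussian noise on qPCR Ct values.
    band_position_noise_sd : float
        SD (migration-coordinate units) of the jitter on gel band centers.
    n_days : int
        Number of daily dilution/growth cycles simulated.
    seed : int
        Default random seed; individual operations accept an explicit seed.
    """

    shorten_rate_mean: float = 2.7
    shorten_rate_sd: float = 0.5
    initial_length: float = 350.0
    critical_length: float = 120.0
    senesce_length: float = 220.0
    hdr_prob_per_pd: float = 0.25
    type2_fraction: float = 0.7
    type1_gain: float = 150.0
    type2_gain_log_mean: float = 5.3
    type2_gain_log_sd: float = 0.5
    terra_fold_short: float = 6.0
    terra_length_scale: float = 25.0
    max_doublings_per_day: float = 6.5
    min_doublings_per_day: float = 1.0
    dilution_od: float = 0.01
    od_noise_cv: float = 0.05
    ct_noise_sd: float = 0.15
    band_position_noise_sd: float = 0.005
    n_days: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any out-of-range parameter."""
        if self.initial_length <= 0:
            raise ValueError("initial_length must be positive")
        if not (self.critical_length < self.senesce_length < self.initial_length):
            raise ValueError(
                "require critical_length < senesce_length < initial_length"
            )
        if self.critical_length <= 0:
            raise ValueError("critical_length must be positive")
        if self.shorten_rate_mean <= 0:
            raise ValueError("shorten_rate_mean must be positive")
        if self.shorten_rate_sd < 0:
            raise ValueError("shorten_rate_sd must be non-negative")
        for name in ("hdr_prob_per_pd", "type2_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.type1_gain <= 0:
            raise ValueError("type1_gain must be positive")
        if self.type2_gain_log_sd < 0:
            raise ValueError("type2_gain_log_sd must be non-negative")
        if self.terra_fold_short < 1.0:
            raise ValueError("terra_fold_short must be >= 1")
        if self.terra_length_scale <= 0:
            raise ValueError("terra_length_scale must be positive")
        if self.min_doublings_per_day <= 0:
            raise ValueError("min_doublings_per_day must be positive")
        if self.max_doublings_per_day < self.min_doublings_per_day:
            raise ValueError("max_doublings_per_day < min_doublings_per_day")
        if self.dilution_od <= 0:
            raise ValueError("dilution_od must be positive")
        for name in ("od_noise_cv", "ct_noise_sd", "band_position_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_days < 1:
            raise ValueError("n_days must be at least 1")

    def replace(self, **changes) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "SimConfig":
        """Load a config from a YAML or JSON file."""
        path = pathlib.Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
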