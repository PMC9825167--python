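"""ChIP-qPCR normalization: percent input, fold to wild-type, TAP correction.

Enrichment at a locus is expressed as percent input — IP signal over the
dilution-corrected input chromatin signal.  Survivor enrichment is then
divided by the isogenic wild-type value collected on the same day; for
TAP-tagged factors, each genotype's tagged signal is first divided by its
untagged equivalent to subtract antibody background multiplicatively.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_input",
    "fold_change_to_wildtype",
    "tap_normalize",
    "chip_fold_table",
]

DEFAULT_INPUT_FRACTION = 0.05  # 50 ul of a 1 ml ChIP extract kept as Input


def percent_input(ip_signal, input_signal, input_fraction: float = DEFAULT_INPUT_FRACTION):
    """IP signal as percent of the dilution-corrected input.

    ``100 * ip / (input / input_fraction)``.  ``input_fraction`` is the
    fraction of the ChIP extract stored as Input (default 5%); use 1/60 for
    the R-ChIP dot-blot convention.
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    ip = np.asarray(ip_signal, dtype=float)
    inp = np.asarray(input_signal, dtype=float)
    if np.any(inp <= 0):
        raise ValueError("input signal must be positive")
    if np.any(ip < 0):
        raise ValueError("IP signal must be non-negative")
    out = 100.0 * ip / (inp / input_fraction)
    return float(out) if out.ndim == 0 else out


def fold_change_to_wildtype(survivor_pct, wildtype_pct):
    """Survivor percent input over the same-day wild-type percent input."""
    s = np.asarray(survivor_pct, dtype=float)
    w = np.asarray(wildtype_pct, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wild-type percent input must be positive")
    out = s / w
    return float(out) if out.ndim == 0 else out


def tap_normalize(tagged_pct, untagged_pct):
    """Tagged over untagged percent input (multiplicative background).

    Applied per genotype *before* the fold change to wild-type, so the full
    TAP chain (survivor tagged/untagged) / (wild-type tagged/untagged) is
    invariant to any common calibration factor.
    """
    t = np.asarray(tagged_pct, dtype=float)
    u = np.asarray(untagged_pct, dtype=float)
    if np.any(u <= 0):
        raise ValueError("untagged percent input must be positive")
    out = t / u
    return float(out) if out.ndim == 0 else out


def chip_fold_table(
    records: pd.DataFrame,
    tap: bool = False,
    input_fraction: float | None = None,
    reference_genotype: str = "wild-type",
) -> pd.DataFrame:
    """Full normalization chain on a long ChIP signal table.

    ``records`` needs columns ``genotype``, ``locus``, ``ip_signal``,
    ``input_signal`` and, for TAP mode, ``tag`` ("tagged"/"untagged").  A
    ``day`` column pairs survivor and reference measurements collected
    together; rows lacking a same-day reference partner fall back to the
    reference genotype's mean at that locus.  ``input_fraction`` overrides
    any per-record ``input_fraction`` column (default 5%).

    Returns one row per (locus, day) for the non-reference genotype with a
    ``fold_change`` column.
    """
    needed = {"genotype", "locus", "ip_signal", "input_signal"}
    missing = needed - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.copy()
    if "day" not in df.columns:
        df["day"] = 0
    if input_fraction is not None:
        frac = np.full(len(df), float(input_fraction))
    elif "input_fraction" in df.columns:
        frac = df["input_fraction"].to_numpy(dtype=float)
    else:
        frac = np.full(len(df), DEFAULT_INPUT_FRACTION)
    df["pct_input"] = [
        percent_input(ip, inp, f)
        for ip, inp, f in zip(df["ip_signal"], df["input_signal"], frac)
    ]

    if tap:
        if "tag" not in df.columns:
            raise ValueError("TAP mode requires a 'tag' column")
        tagged = df[df["tag"] == "tagged"]
        untagged = df[df["tag"] == "untagged"]
        merged = tagged.merge(
            untagged[["genotype", "locus", "day", "pct_input"]],
            on=["genotype", "locus", "day"],
            suffixes=("", "_untagged"),
        )
        if merged.empty:
            raise ValueError("no tagged/untagged pairs found")
        merged["signal"] = tap_normalize(
            merged["pct_input"].to_numpy(), merged["pct_input_untagged"].to_numpy()
        )
        df = merged
    else:
        df = df.copy()
        df["signal"] = df["pct_input"]

    ref = df[df["genotype"] == reference_genotype]
    other = df[df["genotype"] != reference_genotype]
    if ref.empty or other.empty:
        raise ValueError(
            f"need both {reference_genotype!r} and non-reference records"
        )
    ref_by_day = ref.set_index(["locus", "day"])["signal"]
    ref_mean = ref.groupby("locus")["signal"].mean()
    rows = []
    for _, rec in other.iterrows():
        key = (rec["locus"], rec["day"])
        ref_val = float(ref_by_day[key]) if key in ref_by_day.index else float(
            ref_mean[rec["locus"]]
        )
        rows.append(
            (
                rec["genotype"],
                rec["locus"],
                rec["day"],
                rec["signal"],
                ref_val,
                fold_change_to_wildtype(rec["signal"], ref_val),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["genotype", "locus", "day", "signal", "reference_signal", "fold_change"],
    )
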