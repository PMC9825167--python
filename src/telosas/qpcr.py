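"""TERRA RT-qPCR quantification: delta-Ct, percent of reference, folds.

TERRA abundance is read out against a reference transcript (actin mRNA) as
``100 * 2**-(Ct_target - Ct_reference)``, i.e. "% actin mRNA" assuming
perfect per-cycle doubling.  Fold changes divide each sample's percent by
the mean percent of a reference group at the same locus.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "percent_reference",
    "fold_change_to_group",
    "cell_cycle_drop",
    "flag_no_rt",
]


def percent_reference(ct_target, ct_reference, efficiency: float = 2.0):
    """Target abundance as percent of the reference transcript.

    ``100 * efficiency ** -(ct_target - ct_reference)``; the default
    efficiency of 2.0 is the plain delta-Ct convention.  Accepts scalars or
    arrays; Ct values must be finite.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("Ct values must be finite (missing Ct?)")
    out = 100.0 * efficiency ** (-(t - r))
    return float(out) if out.ndim == 0 else out


def fold_change_to_group(
    records: pd.DataFrame,
    reference_group: str,
    group_col: str = "group",
    locus_col: str = "locus",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-record fold change over the mean of a reference group, per locus.

    ``records`` needs columns ``ct_target``, ``ct_reference``, plus the
    group and locus labels.  Returns a copy with ``pct_reference`` (percent
    of the reference transcript) and ``fold_change`` (percent divided by
    the reference group's mean percent at the same locus) columns added.
    The reference group's folds average to exactly 1 at every locus.
    """
    for col in ("ct_target", "ct_reference", group_col, locus_col):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    out = records.copy()
    out["pct_reference"] = percent_reference(
        out["ct_target"].to_numpy(), out["ct_reference"].to_numpy(), efficiency
    )
    ref = out[out[group_col] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_means = ref.groupby(locus_col)["pct_reference"].mean()
    missing = set(out[locus_col]) - set(ref_means.index)
    if missing:
        raise ValueError(
            f"reference group {reference_group!r} has no records at loci "
            f"{sorted(missing)}"
        )
    out["fold_change"] = out["pct_reference"] / out[locus_col].map(ref_means)
    return out


def cell_cycle_drop(early_s: float, g2: float) -> float:
    """Percent decline of TERRA from its early-S peak to G2.

    ``100 * (early_s - g2) / early_s`` on percent-of-reference values.
    """
    if early_s <= 0:
        raise ValueError("early-S value must be positive")
    return 100.0 * (early_s - g2) / early_s


def flag_no_rt(ct_rt, ct_no_rt, min_separation: float = 5.0):
    """Flag samples whose no-RT control is suspiciously close to the RT Ct.

    Returns a boolean (array) that is True where ``ct_no_rt`` is within
    ``min_separation`` cycles of ``ct_rt`` — i.e. where genomic DNA may
    contaminate the cDNA signal.  Controls are only validated, never
    subtracted.
    """
    rt = np.asarray(ct_rt, dtype=float)
    nort = np.asarray(ct_no_rt, dtype=float)
    out = (nort - rt) < min_separation
    return bool(out) if out.ndim == 0 else out
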