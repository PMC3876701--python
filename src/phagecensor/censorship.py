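"""Sequence-specific censorship detection.

If quality filtering removed reads at random, the filtered library would be
one draw of the sampling operator at the measured fraction
f = sum(after)/sum(before), and every sequence's post-filter count would
fall inside the Monte-Carlo band [loC, hiC] built from the pre-filter
library.  A sequence whose count falls below loC lost reads for a
sequence-specific reason; the censorship (bias) operator is the diagonal
matrix with

    B_ii = after_i / (f * before_i)    if after_i < loC_i,
    B_ii = 1                           otherwise.

Sequences with fewer than ``low_copy_threshold`` reads before filtering are
too sparse for the band to discriminate random loss from bias and stay at
B = 1, flagged ``undetermined_low_copy``.  Counts above hiC (apparent
enrichment) are flagged for diagnostics but the bias model assigns them
B = 1: censorship is defined for the loss direction only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .confidence import ConfidenceBand
from .fastq import translate_insert
from .multiset import SequenceMultiset, sum_total

__all__ = ["BiasVector", "measure_fraction", "detect_bias", "censored_table"]

FLAG_WITHIN = "within_band"
FLAG_CENSORED = "censored_below"
FLAG_ABOVE = "above_band"
FLAG_LOW_COPY = "undetermined_low_copy"


@dataclass
class BiasVector:
    """Diagonal of the censorship operator with per-sequence flags."""

    sequences: list[str]
    bias: np.ndarray
    flags: np.ndarray  # of the FLAG_* strings
    fraction: float

    def __post_init__(self) -> None:
        self.bias = np.asarray(self.bias, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        neutral = np.isin(self.flags, [FLAG_WITHIN, FLAG_LOW_COPY, FLAG_ABOVE])
        if not np.allclose(self.bias[neutral], 1.0):
            raise ValueError("bias must be 1 outside censored elements")
        censored = self.bias[self.flags == FLAG_CENSORED]
        if censored.size and (censored.min() < 0 or censored.max() > 1):
            raise ValueError("censored bias must lie in [0, 1]")

    @property
    def censored_mask(self) -> np.ndarray:
        return self.flags == FLAG_CENSORED


def measure_fraction(before: SequenceMultiset, after: SequenceMultiset) -> float:
    """Surviving-read fraction f = sum(after) / sum(before)."""
    if before.sequences != after.sequences:
        raise ValueError("before/after multisets are not aligned")
    if np.any(after.counts > before.counts):
        raise ValueError("filtering cannot create reads: after > before somewhere")
    m = sum_total(before)
    if m == 0:
        raise ValueError("before-library is empty")
    return sum_total(after) / m


def detect_bias(
    before: SequenceMultiset,
    after: SequenceMultiset,
    band: ConfidenceBand,
    low_copy_threshold: int = 10,
) -> BiasVector:
    """Estimate the censorship diagonal by comparing ``after`` to the band.

    ``band`` must have been built from ``before`` at the measured fraction.
    Low-copy sequences (before < threshold) are undetermined; within-band
    counts are unbiased (B=1); counts below loC are censored with
    B = after/(f*before); counts above hiC are flagged as enriched.
    """
    if band.sequences != before.sequences or before.sequences != after.sequences:
        raise ValueError("band and multisets are not aligned")
    f = measure_fraction(before, after)
    n0 = before.counts
    n1 = after.counts
    bias = np.ones(len(n0), dtype=float)
    flags = np.full(len(n0), FLAG_WITHIN, dtype=object)

    low = n0 < low_copy_threshold
    below = (~low) & (n1 < band.lower)
    above = (~low) & (n1 > band.upper)
    flags[low] = FLAG_LOW_COPY
    flags[below] = FLAG_CENSORED
    flags[above] = FLAG_ABOVE
    with np.errstate(divide="ignore", invalid="ignore"):
        bias[below] = n1[below] / (f * n0[below])
    np.clip(bias, 0.0, 1.0, out=bias)
    return BiasVector(list(before.sequences), bias, flags, f)


def censored_table(
    bias: BiasVector,
    before: SequenceMultiset,
    after: SequenceMultiset,
    band: ConfidenceBand | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Ranked report of censored sequences, strongest censorship first.

    Sorted by ascending B, ties by descending before-count then sequence.
    Columns include the peptide translation and the fold-loss 1/B.
    """
    mask = bias.censored_mask
    idx = np.flatnonzero(mask)
    f = bias.fraction
    rows = []
    for i in idx:
        seq = bias.sequences[i]
        b = float(bias.bias[i])
        rows.append(
            {
                "sequence": seq,
                "peptide": translate_insert(seq) if len(seq) % 3 == 0 else "",
                "before": int(before.counts[i]),
                "after": int(after.counts[i]),
                "expected": f * int(before.counts[i]),
                "loC": int(band.lower[i]) if band is not None else np.nan,
                "bias": b,
                "fold_loss": np.inf if b == 0 else 1.0 / b,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "sequence", "peptide", "before", "after",
            "expected", "loC", "bias", "fold_loss",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["bias", "before", "sequence"], ascending=[True, False, True]
        ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table


def write_censorship_csv(
    table: pd.DataFrame, path: str | Path, fraction: float, seed: int | None = None
) -> None:
    """Write the CEN report CSV with a provenance header comment."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# censorship report fraction={fraction} seed={seed}\n")
        table.to_csv(fh, index=False)
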