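"""Phred-cutoff read filtering over the 33-nt analysis window.

Three filtering styles are supported:

* ``min_phred`` (style A) — discard a read if any window position has a
  Phred score below the cutoff.  A cutoff of 1 removes only reads that
  contain a Phred = 0 base (the ``^1n`` library); 13 requires >95%
  per-base confidence (``^13n``); 30 requires 99.9% (``^30n``).
* ``cumulative`` (style B) — discard a read whose cumulative accuracy
  (product of per-base accuracies over the window) falls below the cutoff.
* ``combined`` (style C) — require both.

Filtering is monotone: raising a cutoff can only shrink the surviving
multiset, and it never creates sequences absent before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fastq import WindowedRead, read_accuracy
from .multiset import SequenceMultiset

__all__ = ["FilterSpec", "filter_reads", "accuracy_distribution", "write_histogram_csv"]


@dataclass(frozen=True)
class FilterSpec:
    """One Phred filtering rule."""

    style: str  # min_phred | cumulative | combined
    min_phred_cutoff: int | None = None
    cumulative_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.style not in ("min_phred", "cumulative", "combined"):
            raise ValueError(f"unknown filter style {self.style!r}")
        if self.style in ("min_phred", "combined") and self.min_phred_cutoff is None:
            raise ValueError(f"style {self.style!r} requires min_phred_cutoff")
        if self.style in ("cumulative", "combined"):
            c = self.cumulative_cutoff
            if c is None or not 0.0 <= c <= 1.0:
                raise ValueError(
                    f"style {self.style!r} requires cumulative_cutoff in [0, 1]"
                )

    def keeps(self, window_quals: np.ndarray) -> bool:
        ok = True
        if self.style in ("min_phred", "combined"):
            ok = int(window_quals.min()) >= int(self.min_phred_cutoff)
        if ok and self.style in ("cumulative", "combined"):
            ok = read_accuracy(window_quals) >= float(self.cumulative_cutoff)
        return ok


def filter_reads(
    reads: Sequence[WindowedRead], spec: FilterSpec
) -> SequenceMultiset:
    """Apply a filtering rule to per-read records; count surviving inserts.

    Returns the filtered library (the ``^c n`` multiset), ordered by first
    appearance of each insert among the input reads so that libraries
    filtered at different cutoffs from the same read set align by prefix.
    """
    order: dict[str, int] = {}
    seqs: list[str] = []
    counts: list[int] = []
    # pre-register every insert so differently-filtered libraries share
    # the same sequence order (zero counts encode filtered-out sequences)
    for read in reads:
        if read.insert not in order:
            order[read.insert] = len(seqs)
            seqs.append(read.insert)
            counts.append(0)
    for read in reads:
        if spec.keeps(read.window_quals):
            counts[order[read.insert]] += 1
    return SequenceMultiset(seqs, np.asarray(counts, dtype=np.int64))


def accuracy_distribution(
    reads: Sequence[WindowedRead], bin_edges: np.ndarray | Sequence[float]
) -> tuple[np.ndarray, float]:
    """Histogram of cumulative read accuracies plus their mean.

    ``bin_edges`` follow numpy.histogram conventions (len(edges) - 1 bins,
    last bin closed on the right).
    """
    if len(reads) == 0:
        raise ValueError("accuracy_distribution requires a non-empty read set")
    acc = np.array([read_accuracy(r.window_quals) for r in reads])
    hist, _ = np.histogram(acc, bins=np.asarray(bin_edges, dtype=float))
    return hist, float(acc.mean())


def write_histogram_csv(
    hist: np.ndarray, bin_edges: Sequence[float], path: str | Path
) -> None:
    """Write an accuracy histogram as CSV rows (bin_low, bin_high, count)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("bin_low,bin_high,count\n")
        for lo, hi, c in zip(bin_edges[:-1], bin_edges[1:], hist):
            fh.write(f"{lo},{hi},{int(c)}\n")
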