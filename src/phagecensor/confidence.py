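"""Monte-Carlo confidence bands for the sampling operator.

Repeated application of ``Sa`` at fraction f to a library yields, per
sequence, an empirical distribution of post-sampling copy numbers.  The
band [loC, hiC] brackets that distribution either by the min/max over k
draws (the estimator used for the reference censorship tables, k = 10,000)
or by symmetric empirical quantiles at a stated level.  An observed
post-filtering library that strays below loC for some sequence cannot be
explained by random sampling alone — the entry point of censorship
detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .multiset import SequenceMultiset
from .sampling import sample_counts

__all__ = ["ConfidenceBand", "confidence_interval", "band_contains", "write_band_csv"]


@dataclass
class ConfidenceBand:
    """Per-sequence [loC, hiC] bounds on counts after sampling at ``fraction``."""

    sequences: list[str]
    lower: np.ndarray
    upper: np.ndarray
    fraction: float
    iterations: int
    method: str
    level: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=np.int64)
        self.upper = np.asarray(self.upper, dtype=np.int64)
        if np.any(self.lower < 0) or np.any(self.lower > self.upper):
            raise ValueError("band must satisfy 0 <= loC <= hiC")


def confidence_interval(
    ms: SequenceMultiset,
    fraction: float,
    k: int = 10_000,
    method: str = "minmax",
    level: float = 0.999,
    seed: int | None = None,
) -> ConfidenceBand:
    """Estimate [loC, hiC] from ``k`` Monte-Carlo applications of ``Sa``.

    method="minmax": loC/hiC are the minimum/maximum copy number of each
    sequence over the k draws (effective coverage grows with k).
    method="quantile": symmetric empirical quantiles at ``level`` (integer
    bounds; outward-rounded so the band never under-covers its own draws).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if method not in ("minmax", "quantile"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    draws = sample_counts(ms, fraction, k, rng)
    if method == "minmax":
        lo = draws.min(axis=0)
        hi = draws.max(axis=0)
    else:
        alpha = 1.0 - level
        lo = np.floor(np.quantile(draws, alpha / 2, axis=0)).astype(np.int64)
        hi = np.ceil(np.quantile(draws, 1 - alpha / 2, axis=0)).astype(np.int64)
    # counts can never exceed the source library's copy numbers
    hi = np.minimum(hi, ms.counts)
    lo = np.minimum(lo, hi)
    return ConfidenceBand(
        list(ms.sequences), lo, hi, fraction, k, method, level, seed
    )


def band_contains(
    band: ConfidenceBand, observed: SequenceMultiset
) -> tuple[np.ndarray, bool]:
    """Element-wise ``loC_i <= observed_i <= hiC_i`` plus the overall flag."""
    if observed.sequences != band.sequences:
        raise ValueError("observed multiset is not aligned with the band")
    inside = (band.lower <= observed.counts) & (observed.counts <= band.upper)
    return inside, bool(inside.all())


def write_band_csv(
    band: ConfidenceBand, ms: SequenceMultiset, path: str | Path
) -> None:
    """Export a band as CSV: sequence, n_before, loC, hiC."""
    if ms.sequences != band.sequences:
        raise ValueError("multiset is not aligned with the band")
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# fraction={band.fraction} iterations={band.iterations} "
            f"method={band.method} level={band.level} seed={band.seed}\n"
        )
        fh.write("sequence,n_before,loC,hiC\n")
        for seq, n, lo, hi in zip(band.sequences, ms.counts, band.lower, band.upper):
            fh.write(f"{seq},{int(n)},{int(lo)},{int(hi)}\n")
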