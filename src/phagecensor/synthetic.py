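"""Synthetic libraries and FASTQ reads with known ground truth.

The generator emulates the features of real amplicon runs that the
analysis depends on: copy numbers spanning many orders of magnitude, reads
framed by a constant adapter and the GGGS-encoding tail, per-position
Phred scores, a configurable rate of randomly degraded reads (the
sequence-independent error background that filtering removes), a rate of
corrupted adapters, and planted sequence-specific censorship in which
selected sequences lose reads through low-quality scores clustered at 3-4
fixed window positions.

Under min-Phred filtering at a cutoff between ``low_quality_q`` and
``base_quality``, every degraded read is removed and every clean read
kept, so a sequence planted with censorship strength B survives filtering
with per-read probability B * (1 - degraded_read_rate) while an unbiased
sequence survives with probability (1 - degraded_read_rate).  The planted
B is therefore exactly the expected bias that censorship detection should
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fastq import INSERT_LEN, WINDOW_LEN, AdapterConfig
from .multiset import SequenceMultiset

__all__ = [
    "CensoredSeq",
    "SyntheticSpec",
    "generate_library",
    "generate_fastq",
    "planted_survival_counts",
    "write_truth_csv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CensoredSeq:
    """One planted censorship target.

    ``positions`` are the 3-4 window indices (0..32) whose quality is
    degraded in the affected read instances.
    """

    index: int
    bias: float
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 < self.bias <= 1.0:
            raise ValueError("planted bias must be in (0, 1]")
        if not 3 <= len(self.positions) <= 4:
            raise ValueError("censorship clusters at 3-4 positions")
        if any(p < 0 or p >= WINDOW_LEN for p in self.positions):
            raise ValueError(f"cluster positions must be within 0..{WINDOW_LEN - 1}")


@dataclass
class SyntheticSpec:
    """Ground-truth description of one synthetic library + run."""

    n_unique: int = 1000
    #: "ramp" (counts 1..n_unique), ("log_uniform", min, max), or an
    #: explicit count list
    copy_law: str | tuple | Sequence[int] = "ramp"
    adapter: AdapterConfig = field(default_factory=AdapterConfig)
    base_quality: int = 40
    censored_set: tuple[CensoredSeq, ...] = ()
    flawed_adapter_rate: float = 0.0
    #: sequence-independent rate of reads given one sub-cutoff position;
    #: emulates the ~10% random read loss seen between the ^1n and ^13n
    #: libraries of a typical run
    degraded_read_rate: float = 0.0
    low_quality_q: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_unique < 1:
            raise ValueError("n_unique must be >= 1")
        for rate in (self.flawed_adapter_rate, self.degraded_read_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be probabilities")
        if not 0 <= self.low_quality_q < self.base_quality:
            raise ValueError("low_quality_q must be below base_quality")


def _random_inserts(n: int, rng: np.random.Generator) -> list[str]:
    """Collision-free random 21-nt inserts."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), INSERT_LEN))
        for row in block:
            s = _BASES[row].tobytes().decode("ascii")
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def _counts_for(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    law = spec.copy_law
    if isinstance(law, str):
        if law != "ramp":
            raise ValueError(f"unknown copy law {law!r}")
        return np.arange(1, spec.n_unique + 1, dtype=np.int64)
    if isinstance(law, tuple) and len(law) == 3 and law[0] == "log_uniform":
        _, lo, hi = law
        if not (0 < lo <= hi):
            raise ValueError(f"invalid log_uniform bounds ({lo}, {hi})")
        logs = rng.uniform(np.log10(lo), np.log10(hi), size=spec.n_unique)
        return np.maximum(np.rint(10.0**logs), 1).astype(np.int64)
    counts = np.asarray(list(law), dtype=np.int64)
    if counts.size != spec.n_unique:
        raise ValueError(
            f"explicit copy law has {counts.size} entries for n_unique={spec.n_unique}"
        )
    if np.any(counts < 0):
        raise ValueError("explicit counts must be non-negative")
    return counts


def generate_library(spec: SyntheticSpec) -> tuple[SequenceMultiset, pd.DataFrame]:
    """Generate a library plus its ground-truth record.

    The truth table has one row per sequence: true count, planted bias
    (1.0 when unbiased), the degraded window positions, and the intended
    per-read survival probability under min-Phred filtering.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _counts_for(spec, rng)
    seqs = _random_inserts(spec.n_unique, rng)
    ms = SequenceMultiset(seqs, counts)

    bias = np.ones(spec.n_unique)
    positions = [""] * spec.n_unique
    for c in spec.censored_set:
        if not 0 <= c.index < spec.n_unique:
            raise ValueError(f"censored index {c.index} out of range")
        bias[c.index] = c.bias
        positions[c.index] = ";".join(str(p) for p in c.positions)
    truth = pd.DataFrame(
        {
            "sequence": seqs,
            "true_count": counts,
            "planted_B": bias,
            "cluster_positions": positions,
            "survival_prob": bias * (1.0 - spec.degraded_read_rate),
        }
    )
    return ms, truth


def _degrade_adapter(upstream: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(upstream)))
    old = upstream[i]
    new = str(rng.choice([b for b in "ACGT" if b != old]))
    return upstream[:i] + new + upstream[i + 1 :]


def generate_fastq(
    library: SequenceMultiset,
    spec: SyntheticSpec,
    path: str | Path,
    truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write one FASTQ record per library element instance.

    Each read is upstream adapter + 21-nt insert + 12-nt GGGS tail, all
    positions at ``base_quality`` except: instances of censored sequences
    get their cluster positions dropped to ``low_quality_q`` with
    probability (1 - B); any read independently gets one random window
    position degraded with probability ``degraded_read_rate``; and
    ``flawed_adapter_rate`` of reads get a single upstream-adapter
    mismatch.  Returns the ground-truth table (computes it if not given).
    """
    rng = np.random.default_rng(None if spec.seed is None else spec.seed + 1)
    if truth is None:
        _, truth = generate_library(spec)
    cens = {c.index: c for c in spec.censored_set}
    up = spec.adapter.upstream
    tail = spec.adapter.constant_tail
    base_q = chr(spec.base_quality + 33)
    low_q = chr(spec.low_quality_q + 33)

    with Path(path).open("w", encoding="ascii", newline="\n") as fh:
        read_no = 0
        for i, (seq, count) in enumerate(zip(library.sequences, library.counts)):
            c = cens.get(i)
            for _ in range(int(count)):
                read_no += 1
                window_q = [base_q] * WINDOW_LEN
                if c is not None and rng.random() > c.bias:
                    for p in c.positions:
                        window_q[p] = low_q
                if spec.degraded_read_rate and rng.random() < spec.degraded_read_rate:
                    window_q[int(rng.integers(WINDOW_LEN))] = low_q
                this_up = up
                if spec.flawed_adapter_rate and rng.random() < spec.flawed_adapter_rate:
                    this_up = _degrade_adapter(up, rng)
                bases = this_up + seq + tail
                quals = base_q * len(this_up) + "".join(window_q)
                fh.write(f"@synthetic_read_{read_no}\n{bases}\n+\n{quals}\n")
    return truth


def planted_survival_counts(
    library: SequenceMultiset,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> SequenceMultiset:
    """Post-filtering counts drawn directly from the read-level law.

    Under min-Phred filtering each read instance survives independently
    with its sequence's ``survival_prob``, so the per-sequence surviving
    count is Binomial(n_i, p_i) — identical in distribution to writing
    the reads with :func:`generate_fastq`, ingesting and filtering them,
    at a fraction of the cost for deep libraries.
    """
    p = truth["survival_prob"].to_numpy(dtype=float)
    after = rng.binomial(library.counts, p)
    return library.with_counts(after)


def write_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    """Persist the ground-truth sidecar as CSV."""
    truth.to_csv(path, index=False)
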