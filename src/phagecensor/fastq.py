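"""FASTQ ingestion for amplicon reads of a 7-mer peptide library.

Each usable read carries a 33-nt analysis window: a 21-nt variable insert
(seven NNN codons) followed by a 12-nt constant region encoding the GGGS
linker.  The window is located by exact ("perfect") adapter matching — an
upstream constant region immediately preceding the insert plus the exact
constant tail.  Reads whose adapters carry mismatches or indels are tagged
``flawed_adapter`` for reporting but never rescued, since such reads show
elevated error rates; reads without a recognizable adapter are
``unmapped``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np
from Bio.Seq import Seq

from .multiset import SequenceMultiset

__all__ = [
    "AdapterConfig",
    "QualityRead",
    "WindowedRead",
    "IngestReport",
    "decode_phred",
    "nucleotide_accuracy",
    "read_accuracy",
    "map_adapter",
    "translate_insert",
    "ingest_fastq",
]

INSERT_LEN = 21
TAIL_LEN = 12
WINDOW_LEN = INSERT_LEN + TAIL_LEN  # the 33-nt analysis segment

#: Placeholder upstream constant region (the vector sequence immediately
#: 5' of the variable insert); override per experiment.
DEFAULT_UPSTREAM = "CCTTTCTATTCTCACTCT"
#: One standard codon spelling of the GGGS linker.
DEFAULT_CONSTANT_TAIL = "GGTGGAGGTTCG"


@dataclass(frozen=True)
class AdapterConfig:
    """Constant regions flanking the 21-nt variable insert."""

    upstream: str = DEFAULT_UPSTREAM
    constant_tail: str = DEFAULT_CONSTANT_TAIL
    #: edit-distance budget within which a damaged adapter is still
    #: recognized (and the read tagged flawed rather than unmapped)
    flaw_budget: int = 2
    phred_offset: int = 33  # 64 for legacy Illumina 1.3 encoding

    def __post_init__(self) -> None:
        if len(self.constant_tail) != TAIL_LEN:
            raise ValueError(f"constant_tail must be {TAIL_LEN} nt")
        if str(Seq(self.constant_tail).translate()) != "GGGS":
            raise ValueError("constant_tail must encode the GGGS linker")
        if not self.upstream:
            raise ValueError("upstream adapter must be non-empty")


@dataclass
class QualityRead:
    """One sequencing read with per-position Phred scores and adapter tag."""

    bases: str
    quals: np.ndarray
    tag: str = "unmapped"  # perfect_adapter | flawed_adapter | unmapped
    insert_start: int | None = None

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if self.quals.size != len(self.bases):
            raise ValueError("quals and bases lengths differ")
        if self.insert_start is not None and self.insert_start + WINDOW_LEN > len(
            self.bases
        ):
            raise ValueError("33-nt window extends past the end of the read")

    @property
    def window_bases(self) -> str:
        assert self.insert_start is not None
        return self.bases[self.insert_start : self.insert_start + WINDOW_LEN]

    @property
    def window_quals(self) -> np.ndarray:
        assert self.insert_start is not None
        return self.quals[self.insert_start : self.insert_start + WINDOW_LEN]


@dataclass
class WindowedRead:
    """The retained association read -> (21-nt insert, 33-nt window quals)."""

    insert: str
    window_quals: np.ndarray


@dataclass
class IngestReport:
    """Per-tag read accounting for one FASTQ file."""

    total: int = 0
    perfect: int = 0
    flawed: int = 0
    unmapped: int = 0

    def as_text(self) -> str:
        return (
            f"total: {self.total}\nperfect: {self.perfect}\n"
            f"flawed: {self.flawed}\nunmapped: {self.unmapped}\n"
        )


def decode_phred(quality_string: str, offset: int = 33) -> np.ndarray:
    """Decode an ASCII quality string to integer Phred scores."""
    codes = np.frombuffer(quality_string.encode("ascii"), dtype=np.uint8)
    if codes.size and (codes.min() < offset or codes.max() > 126):
        raise ValueError("quality characters outside the printable Phred range")
    return (codes - offset).astype(np.int64)


def nucleotide_accuracy(Q: float | np.ndarray) -> float | np.ndarray:
    """Probability that a base call with Phred score Q is correct: 1 - 10^(-Q/10)."""
    return 1.0 - 10.0 ** (-np.asarray(Q, dtype=float) / 10.0)


def read_accuracy(quals: np.ndarray, window: slice | None = None) -> float:
    """Cumulative accuracy: product of per-base accuracies over the window."""
    quals = np.asarray(quals)
    if window is not None:
        quals = quals[window]
    if quals.size == 0:
        raise ValueError("empty quality window")
    return float(np.prod(nucleotide_accuracy(quals)))


_N_WILDCARD = [("N", b) for b in "ACGT"]


def _approximate_hit(pattern: str, text: str, budget: int) -> bool:
    if budget <= 0:
        return False
    result = edlib.align(
        pattern, text, mode="HW", task="distance", k=budget,
        additionalEqualities=_N_WILDCARD,
    )
    return result["editDistance"] != -1


def map_adapter(read: QualityRead, cfg: AdapterConfig) -> QualityRead:
    """Tag a read by adapter status and locate the 33-nt window.

    perfect_adapter: the upstream region occurs exactly and the 12-nt
    constant tail matches exactly right after the 21-nt insert (every exact
    upstream occurrence is tried in order).  flawed_adapter: adapter
    present only within the configured edit-distance budget.  unmapped:
    neither.  insert_start is set only for perfect reads.
    """
    bases = read.bases.upper()
    start = 0
    while True:
        hit = bases.find(cfg.upstream, start)
        if hit < 0:
            break
        ins = hit + len(cfg.upstream)
        tail_at = ins + INSERT_LEN
        if tail_at + TAIL_LEN <= len(bases) and (
            bases[tail_at : tail_at + TAIL_LEN] == cfg.constant_tail
        ):
            return QualityRead(read.bases, read.quals, "perfect_adapter", ins)
        start = hit + 1
    flawed = _approximate_hit(
        cfg.upstream + "N" * INSERT_LEN + cfg.constant_tail, bases, cfg.flaw_budget
    ) or _approximate_hit(cfg.upstream, bases, cfg.flaw_budget)
    tag = "flawed_adapter" if flawed else "unmapped"
    return QualityRead(read.bases, read.quals, tag, None)


def translate_insert(dna: str) -> str:
    """Standard-genetic-code translation; stop codons rendered as '*'."""
    dna = dna.upper()
    if len(dna) % 3:
        raise ValueError(f"insert length {len(dna)} not divisible by 3")
    if set(dna) - {"A", "C", "G", "T"}:
        raise ValueError("insert contains non-DNA characters")
    return str(Seq(dna).translate())


def ingest_fastq(
    path: str | Path, cfg: AdapterConfig | None = None
) -> tuple[SequenceMultiset, list[WindowedRead], IngestReport]:
    """Parse a FASTQ file and extract perfect-adapter inserts.

    Returns the multiset of 21-nt inserts (one count per surviving read),
    the per-read (insert, 33-nt window quals) records needed for quality
    filtering, and the per-tag ingest report.  Malformed records raise
    ``ValueError`` naming the record index.
    """
    cfg = cfg or AdapterConfig()
    path = Path(path)
    reads: list[WindowedRead] = []
    report = IngestReport()
    order: dict[str, int] = {}
    counts: list[int] = []
    seqs: list[str] = []

    with path.open("r", encoding="ascii") as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            record_idx += 1
            if not lines[3] or not header.startswith("@") or not lines[2].startswith("+"):
                raise ValueError(f"malformed FASTQ record #{record_idx} in {path}")
            bases = lines[1].strip().upper()
            qual_str = lines[3].strip()
            if len(bases) != len(qual_str):
                raise ValueError(
                    f"malformed FASTQ record #{record_idx}: "
                    "sequence/quality length mismatch"
                )
            quals = decode_phred(qual_str, cfg.phred_offset)
            read = map_adapter(QualityRead(bases, quals), cfg)
            report.total += 1
            if read.tag == "perfect_adapter":
                report.perfect += 1
                insert = read.window_bases[:INSERT_LEN]
                reads.append(WindowedRead(insert, read.window_quals))
                i = order.get(insert)
                if i is None:
                    order[insert] = len(seqs)
                    seqs.append(insert)
                    counts.append(1)
                else:
                    counts[i] += 1
            elif read.tag == "flawed_adapter":
                report.flawed += 1
            else:
                report.unmapped += 1

    ms = SequenceMultiset(seqs, np.asarray(counts, dtype=np.int64))
    return ms, reads, report
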