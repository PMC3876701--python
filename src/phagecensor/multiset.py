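"""Library-as-multiset data model.

A deep-sequenced phage-display library is a multiset: an ordered set of
unique sequences ``S`` together with a copy-number vector ``n``.  The two
elementary summaries are the total element count ``sum`` (total reads,
``m``) and the unique element count ``uni`` (observed diversity).  Storage
is sparse — only observed sequences are kept — with the theoretical
diversity ``N`` (e.g. 20**7 for 7-mer peptides) carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "SequenceMultiset",
    "sum_total",
    "uni_count",
    "theoretical_diversity_for",
    "point_mutation_neighborhood",
    "read_multiset_text",
    "write_multiset_text",
]


class MultisetFormatError(ValueError):
    """Raised when a multiset text file cannot be parsed."""


@dataclass
class SequenceMultiset:
    """Ordered set of unique, equal-length sequences with copy numbers.

    Parameters
    ----------
    sequences
        Unique strings over {A,C,G,T} (DNA mode) or the 20 amino acids
        (peptide mode), all of the same length.
    counts
        Non-negative integer copy numbers, aligned with ``sequences``.
        Zero counts are representable (they encode observed absence).
    theoretical_diversity
        Size ``N`` of the full sequence space.  Defaults to ``4**L`` when
        every character is a nucleotide, else ``20**L``.
    """

    sequences: list[str]
    counts: np.ndarray
    theoretical_diversity: int | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequences = [str(s).upper() for s in self.sequences]
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.array_equal(rounded, counts):
                raise ValueError("counts must be integers")
            counts = rounded
        self.counts = counts.astype(np.int64).reshape(-1)
        if len(self.sequences) != self.counts.size:
            raise ValueError(
                f"{len(self.sequences)} sequences but {self.counts.size} counts"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self._index = {s: i for i, s in enumerate(self.sequences)}
        if len(self._index) != len(self.sequences):
            raise ValueError("duplicate sequences in multiset")
        if self.theoretical_diversity is None and self.sequences:
            L = len(self.sequences[0])
            alphabet = set().union(*(set(s) for s in self.sequences))
            base = 4 if alphabet <= DNA_ALPHABET else 20
            self.theoretical_diversity = base**L
        if self.theoretical_diversity is not None:
            observed = int(np.count_nonzero(self.counts))
            if self.theoretical_diversity < observed:
                raise ValueError(
                    "theoretical_diversity smaller than observed diversity"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceMultiset):
            return NotImplemented
        return self.sequences == other.sequences and np.array_equal(
            self.counts, other.counts
        )

    def count_of(self, sequence: str) -> int:
        """Copy number of ``sequence`` (0 if absent from the support)."""
        i = self._index.get(sequence.upper())
        return 0 if i is None else int(self.counts[i])

    def with_counts(self, counts: Iterable[int]) -> "SequenceMultiset":
        """New multiset over the same sequences with replaced counts."""
        return SequenceMultiset(
            list(self.sequences),
            np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts),
            self.theoretical_diversity,
        )

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, int]],
        theoretical_diversity: int | None = None,
    ) -> "SequenceMultiset":
        seqs, counts = [], []
        for s, c in pairs:
            seqs.append(s)
            counts.append(c)
        return cls(seqs, np.asarray(counts, dtype=np.int64), theoretical_diversity)


def sum_total(ms: SequenceMultiset) -> int:
    """Total number of elements (the library's ``m``): sum of copy numbers."""
    return int(ms.counts.sum())


def uni_count(ms: SequenceMultiset) -> int:
    """Number of unique sequences actually observed (copy number > 0)."""
    return int(np.count_nonzero(ms.counts))


def theoretical_diversity_for(alphabet_size: int, length: int) -> int:
    """Size of the full sequence space: ``alphabet_size ** length``.

    A 7-mer peptide library spans 20**7 = 1.28e9 possible peptides.
    """
    if alphabet_size < 1 or length < 1:
        raise ValueError("alphabet_size and length must be positive")
    return alphabet_size**length


def point_mutation_neighborhood(seq: str) -> list[str]:
    """All sequences at Hamming distance exactly 1 from a DNA sequence.

    A length-L sequence has 3*L one-letter misspellings (63 for a 21-mer).
    The input itself is never included and the result has no duplicates.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    out = []
    for i, orig in enumerate(seq):
        for sub in "ACGT":
            if sub != orig:
                out.append(seq[:i] + sub + seq[i + 1 :])
    return out


def write_multiset_text(ms: SequenceMultiset, path: str | Path) -> None:
    """Write a multiset as tab-separated ``sequence<TAB>count`` lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for seq, count in zip(ms.sequences, ms.counts):
            fh.write(f"{seq}\t{int(count)}\n")


def read_multiset_text(
    path: str | Path, theoretical_diversity: int | None = None
) -> SequenceMultiset:
    """Read a tab-separated multiset file.

    One record per line, ``<sequence><TAB><count>``; blank lines and lines
    starting with ``#`` are ignored; sequences are case-folded to upper.
    Raises :class:`MultisetFormatError` naming the offending line number.
    """
    path = Path(path)
    seqs: list[str] = []
    counts: list[int] = []
    valid = DNA_ALPHABET | PROTEIN_ALPHABET | {"*"}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) != 2:
                raise MultisetFormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            seq, count_str = fields[0].upper(), fields[1]
            if set(seq) - valid:
                raise MultisetFormatError(
                    f"{path}:{lineno}: invalid characters in sequence {seq!r}"
                )
            try:
                count = int(count_str)
            except ValueError as exc:
                raise MultisetFormatError(
                    f"{path}:{lineno}: count {count_str!r} is not an integer"
                ) from exc
            if count < 0:
                raise MultisetFormatError(f"{path}:{lineno}: negative count {count}")
            seqs.append(seq)
            counts.append(count)
    return SequenceMultiset(
        seqs, np.asarray(counts, dtype=np.int64), theoretical_diversity
    )
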