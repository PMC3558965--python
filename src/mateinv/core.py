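"""Coordinate conventions, domain types and sequence primitives.

Every genomic coordinate in this package is 1-based and closed (both
endpoints included), the convention used by genome-report tables and GFF.
Conversion to 0-based half-open happens only at the BED boundary.

Circular replicons (the normal case for prokaryotic chromosomes and
extra-chromosomal elements) permit intervals and fragments that wrap past
the origin; a wrapping interval is represented canonically with
``start > end``.  All interval arithmetic therefore takes the sequence
length explicitly where wrapping is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(ValueError):
    """An interval violates the coordinate conventions of its sequence."""


class ConfigError(ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


def validate_dna(seq: str) -> str:
    """Return *seq* uppercased, raising :class:`AlphabetError` on bad characters."""
    s = seq.upper()
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        raise AlphabetError(f"illegal DNA characters: {bad!r}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}.

    An involution: ``revcomp(revcomp(s)) == s``.
    """
    s = validate_dna(seq)
    return s.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among non-N bases."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise AlphabetError("sequence has no A/C/G/T bases")
    return (seq.count("G") + seq.count("C")) / acgt


@dataclass
class SequenceRecord:
    """A named DNA sequence with an explicit topology flag.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header token).
    seq : str
        Uppercase DNA over {A, C, G, T, N}; length >= 1.
    circular : bool
        True for circular replicons; permits wrapping intervals and
        fragments that cross the origin.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.seq = validate_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Extract the 1-based closed interval [start, end].

        On a circular sequence ``start > end`` wraps through the origin.
        """
        L = len(self.seq)
        if not (1 <= start <= L and 1 <= end <= L):
            raise CoordinateError(
                f"interval ({start}, {end}) outside sequence {self.id!r} of length {L}"
            )
        if start <= end:
            return self.seq[start - 1 : end]
        if not self.circular:
            raise CoordinateError(
                f"wrapping interval ({start}, {end}) on linear sequence {self.id!r}"
            )
        return self.seq[start - 1 :] + self.seq[:end]


@dataclass(frozen=True)
class Interval:
    """A 1-based, closed, stranded genomic interval.

    Wrapping intervals (``start > end``) are legal only on circular
    sequences and cover ``[start, L] ∪ [1, end]``.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"coordinates are 1-based: ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, seq_len: Optional[int] = None) -> int:
        return interval_length(self, seq_len)

    def contains(self, pos: int, seq_len: Optional[int] = None) -> bool:
        """Whether 1-based position *pos* lies inside the interval."""
        if not self.wraps:
            return self.start <= pos <= self.end
        if seq_len is None:
            raise CoordinateError("seq_len required for a wrapping interval")
        return pos >= self.start or pos <= self.end


def interval_length(iv: Interval, seq_len: Optional[int] = None) -> int:
    """Length in bp of a 1-based closed interval.

    Non-wrapping intervals have length ``end - start + 1``.  A wrapping
    interval on a circular sequence of length ``seq_len`` covers
    ``(seq_len - start + 1) + end`` bases.
    """
    if not iv.wraps:
        return iv.end - iv.start + 1
    if seq_len is None:
        raise CoordinateError(
            f"wrapping interval ({iv.start}, {iv.end}) needs the sequence length"
        )
    return (seq_len - iv.start + 1) + iv.end


def to_bed(iv: Interval) -> tuple[str, int, int]:
    """Convert to BED convention: (chrom, 0-based start, half-open end).

    Wrapping intervals have no single-record BED representation and must
    be split by the caller.
    """
    if iv.wraps:
        raise CoordinateError("wrapping interval must be split into two BED records")
    return (iv.seq_id, iv.start - 1, iv.end)


def from_bed(chrom: str, bed_start: int, bed_end: int, strand: str = "+") -> Interval:
    """Inverse of :func:`to_bed`."""
    return Interval(chrom, bed_start + 1, bed_end, strand)


@dataclass(frozen=True)
class LibrarySpec:
    """Mate-pair library geometry.

    ``expected_relative_strand`` encodes the chemistry: ``"same"`` for a
    mate-pair (circularised-fragment) library whose two reads report on
    the same strand of the original fragment, ``"opposite"`` for a
    conventional paired-end library.  With a ``"same"`` library an
    inverted genomic segment shows up as opposite-strand read pairs.
    """

    insert_min: int = 1000
    insert_max: int = 3500
    read_length: int = 25
    expected_relative_strand: str = "same"

    def __post_init__(self) -> None:
        if not (0 < self.read_length < self.insert_min <= self.insert_max):
            raise ConfigError(
                "require 0 < read_length < insert_min <= insert_max, got "
                f"read_length={self.read_length}, insert_min={self.insert_min}, "
                f"insert_max={self.insert_max}"
            )
        if self.expected_relative_strand not in ("same", "opposite"):
            raise ConfigError("expected_relative_strand must be 'same' or 'opposite'")

    @property
    def insert_mean(self) -> float:
        return (self.insert_min + self.insert_max) / 2.0


@dataclass
class PairTruth:
    """Simulation provenance for one mate pair (absent on real data)."""

    haplotype_states: tuple[bool, ...]
    fragment: Interval
    fragment_length: int


@dataclass
class MatePair:
    """Two reads sequenced from the ends of one long fragment."""

    pair_id: str
    read1: str
    read2: str
    truth: Optional[PairTruth] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.read1) != len(self.read2):
            raise ValueError(f"pair {self.pair_id!r}: reads differ in length")
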