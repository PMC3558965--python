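"""Exact, uniqueness-aware mapping of short mate-pair reads.

Reads are mapped by exact k-mer lookup (k = read length) against both
strands of every target; only reads with exactly one match anywhere are
kept, and only pairs whose two reads both map uniquely survive.  This is
the strictest realisation of "uniquely mapping read pairs": a 25 bp read
inside a two-copy repeat is ambiguous by construction and contributes no
long-range information.

Circular targets contribute origin-crossing k-mers, so every position of
a circular replicon is a valid match start.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pysam

from .core import ConfigError, MatePair, SequenceRecord, revcomp

PathLike = Union[str, Path]


class MapStatus(enum.Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Alignment:
    """A unique exact match of one read.

    ``pos`` is the 1-based leftmost coordinate of the matched substring
    on the forward strand of ``seq_id`` (for strand ``-`` the reverse
    complement of the read matches there).
    """

    read_id: str
    seq_id: str
    pos: int
    strand: str
    unique: bool = True


@dataclass(frozen=True)
class PairedAlignment:
    pair_id: str
    aln1: Alignment
    aln2: Alignment


class KmerIndex:
    """Exact-match index over the forward-strand k-mers of the targets."""

    def __init__(self, targets: Sequence[SequenceRecord], k: int):
        if not targets:
            raise ConfigError("no targets to index")
        if k > min(len(t) for t in targets):
            raise ConfigError(f"k={k} exceeds the shortest target")
        self.k = k
        self.targets = {t.id: t for t in targets}
        self.lengths = {t.id: len(t) for t in targets}
        index: dict[str, list[tuple[str, int]]] = {}
        for t in targets:
            seq = t.seq + t.seq[: k - 1] if t.circular else t.seq
            n_starts = len(t) if t.circular else len(t) - k + 1
            for i in range(n_starts):
                index.setdefault(seq[i : i + k], []).append((t.id, i + 1))
        self._index = index

    def lookup(self, read: str) -> list[tuple[str, int, str]]:
        """All exact matches of *read* over both strands of all targets."""
        hits = [(sid, pos, "+") for sid, pos in self._index.get(read, ())]
        hits += [(sid, pos, "-") for sid, pos in self._index.get(revcomp(read), ())]
        return hits

    def map_read(self, read: str, read_id: str = "") -> tuple[MapStatus, Alignment | None]:
        """Classify one read as unique / ambiguous / unmapped.

        Reads containing N never map (they are counted, not wildcarded).
        """
        if len(read) != self.k:
            raise ConfigError(f"read length {len(read)} != index k {self.k}")
        if "N" in read:
            return MapStatus.UNMAPPED, None
        hits = self.lookup(read)
        if len(hits) == 1:
            sid, pos, strand = hits[0]
            return MapStatus.UNIQUE, Alignment(read_id, sid, pos, strand)
        if not hits:
            return MapStatus.UNMAPPED, None
        return MapStatus.AMBIGUOUS, None


def build_index(targets: Sequence[SequenceRecord], k: int) -> KmerIndex:
    return KmerIndex(targets, k)


def map_pairs(
    index: KmerIndex, pairs: Iterable[MatePair]
) -> tuple[list[PairedAlignment], dict[str, int]]:
    """Map both reads of every pair, keeping only doubly-unique pairs.

    The summary bins each input pair into exactly one of ``both_unique``,
    ``any_ambiguous`` (at least one ambiguous read) or ``any_unmapped``
    (no ambiguity, at least one unmapped read); the bins sum to the
    input count.  ``reads_with_n`` additionally counts N-containing
    reads inside the unmapped bin.
    """
    kept: list[PairedAlignment] = []
    counts = {"both_unique": 0, "any_ambiguous": 0, "any_unmapped": 0,
              "total": 0, "reads_with_n": 0}
    for p in pairs:
        counts["total"] += 1
        counts["reads_with_n"] += ("N" in p.read1) + ("N" in p.read2)
        s1, a1 = index.map_read(p.read1, f"{p.pair_id}/1")
        s2, a2 = index.map_read(p.read2, f"{p.pair_id}/2")
        if s1 is MapStatus.UNIQUE and s2 is MapStatus.UNIQUE:
            counts["both_unique"] += 1
            kept.append(PairedAlignment(p.pair_id, a1, a2))
        elif MapStatus.AMBIGUOUS in (s1, s2):
            counts["any_ambiguous"] += 1
        else:
            counts["any_unmapped"] += 1
    return kept, counts


def write_alignments_tsv(alignments: Iterable[PairedAlignment], path: PathLike) -> None:
    """Dump paired alignments as TSV, one read per line."""
    with open(path, "w") as fh:
        fh.write("pair_id\tread\tseq_id\tpos\tstrand\n")
        for pa in alignments:
            for n, a in ((1, pa.aln1), (2, pa.aln2)):
                fh.write(f"{pa.pair_id}\t{n}\t{a.seq_id}\t{a.pos}\t{a.strand}\n")


def read_alignments_tsv(path: PathLike) -> list[PairedAlignment]:
    """Inverse of :func:`write_alignments_tsv`."""
    by_pair: dict[str, dict[int, Alignment]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["pair_id", "read", "seq_id", "pos", "strand"]:
            raise ValueError(f"unexpected alignment TSV header: {header}")
        for line in fh:
            pid, n, sid, pos, strand = line.rstrip("\n").split("\t")[:5]
            if pid not in by_pair:
                by_pair[pid] = {}
                order.append(pid)
            by_pair[pid][int(n)] = Alignment(f"{pid}/{n}", sid, int(pos), strand)
    out = []
    for pid in order:
        reads = by_pair[pid]
        if set(reads) != {1, 2}:
            raise ValueError(f"pair {pid!r} lacks one of its two reads")
        out.append(PairedAlignment(pid, reads[1], reads[2]))
    return out


def write_sam(
    alignments: Iterable[PairedAlignment],
    targets: Sequence[SequenceRecord],
    read_length: int,
    path: PathLike,
) -> None:
    """Write paired alignments as a minimal SAM file (exact matches, CIGAR kM)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.id, "LN": len(t)} for t in targets],
    }
    tid = {t.id: i for i, t in enumerate(targets)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pa in alignments:
            for n, a, mate in ((1, pa.aln1, pa.aln2), (2, pa.aln2, pa.aln1)):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = pa.pair_id
                flag = 0x1 | 0x2  # paired, both mapped uniquely
                flag |= 0x40 if n == 1 else 0x80
                if a.strand == "-":
                    flag |= 0x10
                if mate.strand == "-":
                    flag |= 0x20
                seg.flag = flag
                seg.reference_id = tid[a.seq_id]
                seg.reference_start = a.pos - 1
                seg.mapping_quality = 60
                seg.cigarstring = f"{read_length}M"
                seg.next_reference_id = tid[mate.seq_id]
                seg.next_reference_start = mate.pos - 1
                out.write(seg)
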