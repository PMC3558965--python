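"""File-format boundaries: FASTA, BED, TSV tables.

Topology is carried in the FASTA description as a ``[topology=circular]``
token (the convention used by several prokaryotic annotation pipelines),
so a round trip through FASTA preserves circularity.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .core import Interval, MatePair, SequenceRecord, to_bed

PathLike = Union[str, Path]

_TOPOLOGY_RE = re.compile(r"\[topology=(circular|linear)\]")


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    A ``[topology=circular]`` token anywhere in the description marks the
    record circular; records default to linear.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _TOPOLOGY_RE.search(rec.description)
        circular = bool(m and m.group(1) == "circular")
        records.append(SequenceRecord(rec.id, str(rec.seq), circular=circular))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike) -> None:
    """Write records as 70-column FASTA with topology tokens."""
    bio = []
    for r in records:
        topo = "circular" if r.circular else "linear"
        bio.append(
            BioSeqRecord(Seq(r.seq), id=r.id, description=f"[topology={topo}]")
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(bio)


def read_reads(path: PathLike) -> list[tuple[str, str]]:
    """Read sequences from FASTA or FASTQ as (id, seq); qualities are ignored."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_interleaved_pairs(pairs: Iterable[MatePair], path: PathLike) -> None:
    """Write mate pairs as interleaved FASTA (``<pair_id>/1``, ``<pair_id>/2``)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.pair_id}/1\n{p.read1}\n>{p.pair_id}/2\n{p.read2}\n")


def read_interleaved_pairs(path: PathLike) -> list[MatePair]:
    """Inverse of :func:`write_interleaved_pairs` (truth is not serialised)."""
    reads = read_reads(path)
    if len(reads) % 2:
        raise ValueError("interleaved pair file has an odd number of records")
    pairs = []
    for (id1, r1), (id2, r2) in zip(reads[0::2], reads[1::2]):
        base1, base2 = id1.rsplit("/", 1)[0], id2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"interleaving broken at {id1!r} / {id2!r}")
        pairs.append(MatePair(base1, r1, r2))
    return pairs


def write_bed(intervals: Iterable[Interval], path: PathLike, names: Iterable[str] | None = None) -> None:
    """Write intervals as 6-column BED (0-based half-open)."""
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            chrom, b_start, b_end = to_bed(iv)
            name = names[i] if names else f"iv{i + 1}"
            fh.write(f"{chrom}\t{b_start}\t{b_end}\t{name}\t0\t{iv.strand}\n")
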