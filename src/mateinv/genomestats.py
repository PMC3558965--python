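"""Genome-level summary arithmetic: GC%, coding fraction, category counts.

Percentages are rounded half away from zero to two decimals, the
convention of genome-report tables.  "Coding region" is the union of all
annotated gene intervals (protein-coding and RNA), with overlaps merged
and origin-wrapping genes handled on circular replicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .core import AlphabetError, CoordinateError, Interval, SequenceRecord

PathLike = Union[str, Path]

CATEGORIES = ("protein_coding", "rna", "pseudogene")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    interval: Interval
    category: str
    subcategory: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")


def round2(x: float) -> float:
    """Round half away from zero at 2 decimal places (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def gc_percent(seq: str) -> float:
    """G+C percent over the non-N bases, to 2 dp."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise AlphabetError("GC% undefined: no A/C/G/T bases")
    return round2(100.0 * (counts["G"] + counts["C"]) / denom)


def category_percent(count: int, total: int) -> float:
    """Percent of a category count over its reference total, to 2 dp."""
    if total <= 0:
        raise ZeroDivisionError("category percent undefined for total <= 0")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    return round2(100.0 * count / total)


def orf_count_difference(count_a: int, count_b: int) -> int:
    """Difference in predicted ORF counts between two genomes."""
    if count_a < 0 or count_b < 0:
        raise ValueError("ORF counts must be non-negative")
    return count_a - count_b


def merged_interval_length(
    intervals: Iterable[Interval], genome_len: int, circular: bool = True
) -> int:
    """Total bp covered by the union of intervals (overlaps merged).

    Wrapping intervals on circular replicons are split at the origin
    before merging.
    """
    spans: list[tuple[int, int]] = []
    for iv in intervals:
        if iv.end > genome_len or iv.start > genome_len:
            raise CoordinateError(
                f"interval ({iv.start}, {iv.end}) beyond genome of {genome_len} bp"
            )
        if iv.wraps:
            if not circular:
                raise CoordinateError("wrapping interval on a linear genome")
            spans.append((iv.start, genome_len))
            spans.append((1, iv.end))
        else:
            spans.append((iv.start, iv.end))
    if not spans:
        return 0
    spans.sort()
    total = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def coding_percent(
    annotations: Sequence[GeneAnnotation], genome_len: int, circular: bool = True
) -> tuple[int, float]:
    """(coding bp, percent of genome) from the union of gene intervals."""
    coding = [a.interval for a in annotations if a.category in ("protein_coding", "rna")]
    bp = merged_interval_length(coding, genome_len, circular)
    return bp, round2(100.0 * bp / genome_len)


@dataclass
class GenomeStatsReport:
    """Rows of (attribute, value, percent-of-total) plus inversion rows."""

    rows: list[tuple[str, object, Optional[float]]] = field(default_factory=list)
    inversion_rows: list[tuple[str, int, int, int, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["attribute", "value", "percent_of_total"])

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("attribute\tvalue\tpercent_of_total\n")
            for name, value, pct in self.rows:
                fh.write(f"{name}\t{value}\t{'' if pct is None else f'{pct:.2f}'}\n")
            if self.inversion_rows:
                fh.write("\ninversion\tstart\tend\tlength\tfrequency\n")
                for name, s, e, ln, f in self.inversion_rows:
                    fh.write(f"{name}\t{s}\t{e}\t{ln}\t{f:.2f}\n")

    def to_markdown(self) -> str:
        lines = ["| Attribute | Value | % of total |", "| --- | --- | --- |"]
        for name, value, pct in self.rows:
            p = "" if pct is None else f"{pct:.2f}"
            lines.append(f"| {name} | {value} | {p} |")
        if self.inversion_rows:
            lines += ["", "| Inversion | Start | End | Length | Frequency |",
                      "| --- | --- | --- | --- | --- |"]
            for name, s, e, ln, f in self.inversion_rows:
                lines.append(f"| {name} | {s} | {e} | {ln} | {f:.2f} |")
        return "\n".join(lines)


def build_report(
    genome: SequenceRecord,
    annotations: Sequence[GeneAnnotation] = (),
    inversion_calls: Sequence = (),
) -> GenomeStatsReport:
    """Summary table: size, coding bp, GC bp, gene counts and percentages.

    Gene-count percentages use total genes as the reference total;
    bp rows use the genome size.  Supplied inversion calls are appended
    as (name, start, end, length, frequency) rows.
    """
    L = len(genome)
    seq = genome.seq
    gc_bp = seq.count("G") + seq.count("C")
    coding_bp, coding_pct = coding_percent(annotations, L, genome.circular)
    n_total = len(annotations)
    n_rna = sum(a.category == "rna" for a in annotations)
    n_cds = sum(a.category == "protein_coding" for a in annotations)

    rows: list[tuple[str, object, Optional[float]]] = [
        ("Genome size (bp)", L, 100.0),
        ("DNA coding region (bp)", coding_bp, coding_pct),
        ("DNA G+C content (bp)", gc_bp, gc_percent(seq)),
        ("Total genes", n_total, 100.0 if n_total else None),
    ]
    if n_total:
        rows.append(("RNA genes", n_rna, category_percent(n_rna, n_total)))
        rows.append(("Protein-coding genes", n_cds, category_percent(n_cds, n_total)))
    else:
        rows.append(("RNA genes", 0, None))
        rows.append(("Protein-coding genes", 0, None))

    inv_rows = [
        (c.name, c.start, c.end, c.length, c.frequency) for c in inversion_calls
    ]
    return GenomeStatsReport(rows=rows, inversion_rows=inv_rows)


def read_annotations_gff3(path: PathLike) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (``gene`` / RNA / CDS-bearing types)."""
    type_map = {
        "gene": "protein_coding", "CDS": "protein_coding", "mRNA": "protein_coding",
        "tRNA": "rna", "rRNA": "rna", "ncRNA": "rna", "pseudogene": "pseudogene",
    }
    out: list[GeneAnnotation] = []
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8 or f[2] not in type_map:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            ) if len(f) > 8 else {}
            n += 1
            out.append(
                GeneAnnotation(
                    gene_id=attrs.get("ID", f"gene{n}"),
                    interval=Interval(f[0], int(f[3]), int(f[4]), f[6] if f[6] in "+-" else "+"),
                    category=type_map[f[2]],
                    subcategory=f[2],
                )
            )
    return out


def read_annotations_tsv(path: PathLike) -> list[GeneAnnotation]:
    """Read annotations from a 5-column TSV: gene_id, seq_id, start, end, category."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "seq_id", "start", "end", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            interval=Interval(str(r.seq_id), int(r.start), int(r.end),
                              getattr(r, "strand", "+")),
            category=str(r.category),
            subcategory=str(getattr(r, "subcategory", "")),
        )
        for r in df.itertuples()
    ]
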