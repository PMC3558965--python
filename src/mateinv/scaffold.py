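"""Contig scaffolding from uniquely-mapping mate pairs.

Each doubly-unique inter-contig pair witnesses a junction between one
*end* of each contig (head = coordinate 1 side, tail = high-coordinate
side): the fragment leaves the first-read contig through the end its
direction points at and enters the second-read contig likewise.  Counts
are accumulated per contig pair per relative orientation:

* ``same``       — head-to-tail junction, contigs co-oriented (``→ →``)
* ``converging`` — tail-to-tail junction (``→ ←``)
* ``diverging``  — head-to-head junction (``← →``)

Scaffolding then greedily accepts the best-supported end-to-end links
subject to each contig end taking at most one partner and no premature
sub-cycle; a closure that joins all contigs into one cycle yields a
circular scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .core import LibrarySpec, SequenceRecord, revcomp
from .mapping import Alignment, PairedAlignment

PathLike = Union[str, Path]

HEAD = "head"
TAIL = "tail"

End = tuple[str, str]  # (contig_id, side)

SAME = "same"
CONVERGING = "converging"
DIVERGING = "diverging"

# intra-contig / intra-chromosome pair classes
CONCORDANT = "concordant"
INVERTED = "inverted"
LONG = "long"
SHORT = "short"


class ScaffoldConflictError(RuntimeError):
    """A link contradicts orientations already propagated through the scaffold."""


@dataclass(frozen=True)
class SeqInfo:
    length: int
    circular: bool = False


def _seq_info(targets: Sequence[SequenceRecord]) -> dict[str, SeqInfo]:
    return {t.id: SeqInfo(len(t), t.circular) for t in targets}


def fragment_directions(
    aln1: Alignment, aln2: Alignment, library: LibrarySpec
) -> tuple[str, str]:
    """Direction of the original fragment through each read's target.

    The first read is sequenced from the fragment's 5' end, so the
    fragment runs in read 1's mapped direction at read 1's locus; for a
    same-strand (mate-pair) library read 2 also reports the fragment
    strand, for an opposite-strand (paired-end) library it reports the
    reverse.
    """
    d1 = aln1.strand
    d2 = aln2.strand
    if library.expected_relative_strand == "opposite":
        d2 = "-" if d2 == "+" else "+"
    return d1, d2


@dataclass(frozen=True)
class PairClass:
    """Classification of one doubly-unique pair."""

    kind: str  # "inter" or "intra"
    orientation: Optional[str] = None  # inter: same/converging/diverging
    link: Optional[tuple[End, End]] = None  # inter: canonicalised end pair
    intra_class: Optional[str] = None  # intra: concordant/inverted/long/short
    separation: Optional[int] = None  # intra: implied fragment length


def _canonical_link(a: End, b: End) -> tuple[End, End]:
    return (a, b) if a <= b else (b, a)


def link_orientation(link: tuple[End, End]) -> str:
    sides = (link[0][1], link[1][1])
    if sides == (TAIL, TAIL):
        return CONVERGING
    if sides == (HEAD, HEAD):
        return DIVERGING
    return SAME


def classify_relative_orientation(
    aln1: Alignment,
    aln2: Alignment,
    library: LibrarySpec,
    info: dict[str, SeqInfo],
) -> PairClass:
    """Classify a pair as inter-contig (orientation + end link) or intra-contig.

    Intra-contig pairs are subdivided into concordant (expected strands,
    implied fragment length within the insert range), inverted (strand
    convention violated) and long / short (distance-only discordance).
    On circular targets the implied fragment length is taken in the
    fragment direction modulo the sequence length.
    """
    for a in (aln1, aln2):
        if a.seq_id not in info:
            raise ValueError(f"alignment target {a.seq_id!r} not in the contig set")
    d1, d2 = fragment_directions(aln1, aln2, library)
    if aln1.seq_id != aln2.seq_id:
        end_a: End = (aln1.seq_id, TAIL if d1 == "+" else HEAD)  # fragment exits
        end_b: End = (aln2.seq_id, HEAD if d2 == "+" else TAIL)  # fragment enters
        link = _canonical_link(end_a, end_b)
        return PairClass(kind="inter", orientation=link_orientation(link), link=link)

    target = info[aln1.seq_id]
    if d1 != d2:
        return PairClass(kind="intra", intra_class=INVERTED)
    # implied fragment: read1 start to read2 end, walking in the fragment direction
    delta = aln2.pos - aln1.pos if d1 == "+" else aln1.pos - aln2.pos
    if target.circular:
        delta %= target.length
    frag_len = delta + library.read_length
    if delta < 0:
        cls = SHORT  # linear target, mate behind the first read
    elif frag_len < library.insert_min:
        cls = SHORT
    elif frag_len > library.insert_max:
        cls = LONG
    else:
        cls = CONCORDANT
    return PairClass(kind="intra", intra_class=cls, separation=frag_len)


@dataclass
class OrientationCountTable:
    """The From::To table: support per contig pair per relative orientation.

    End-level counts (which contig ends the fragments join) are the
    primary record — ``same`` alone cannot distinguish A-before-B from
    B-before-A — and the three-orientation table is a view of them.
    """

    contig_ids: list[str]
    link_counts: dict[tuple[End, End], int] = field(default_factory=dict)
    intra_counts: dict[str, int] = field(default_factory=dict)
    n_inter_pairs: int = 0

    def add_link(self, link: tuple[End, End]) -> None:
        self.link_counts[link] = self.link_counts.get(link, 0) + 1
        self.n_inter_pairs += 1

    def count(self, contig_i: str, contig_j: str, orientation: str) -> int:
        """Support for an unordered contig pair in one relative orientation."""
        total = 0
        for link, n in self.link_counts.items():
            (ca, _), (cb, _) = link
            if {ca, cb} == {contig_i, contig_j} and link_orientation(link) == orientation:
                total += n
        return total

    @property
    def total(self) -> int:
        return sum(self.link_counts.values())

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("contig_i\tside_i\tcontig_j\tside_j\torientation\tcount\n")
            for link in sorted(self.link_counts):
                (ci, si), (cj, sj) = link
                fh.write(
                    f"{ci}\t{si}\t{cj}\t{sj}\t{link_orientation(link)}"
                    f"\t{self.link_counts[link]}\n"
                )

    @classmethod
    def from_tsv(cls, path: PathLike, contig_ids: Sequence[str]) -> "OrientationCountTable":
        table = cls(contig_ids=list(contig_ids))
        with open(path) as fh:
            fh.readline()
            for line in fh:
                ci, si, cj, sj, _ori, n = line.rstrip("\n").split("\t")[:6]
                link = _canonical_link((ci, si), (cj, sj))
                table.link_counts[link] = table.link_counts.get(link, 0) + int(n)
        table.n_inter_pairs = table.total
        return table


def accumulate_from_to_table(
    pairs: Iterable[PairedAlignment],
    library: LibrarySpec,
    targets: Sequence[SequenceRecord],
) -> OrientationCountTable:
    """Accumulate the From::To orientation-count table over uniquely-mapped pairs.

    Every inter-contig pair increments exactly one end-link cell;
    intra-contig pairs are routed to a separate summary, so the table
    total always equals the number of inter-contig pairs seen.
    """
    info = _seq_info(targets)
    table = OrientationCountTable(contig_ids=[t.id for t in targets])
    for pa in pairs:
        cls = classify_relative_orientation(pa.aln1, pa.aln2, library, info)
        if cls.kind == "inter":
            table.add_link(cls.link)
        else:
            table.intra_counts[cls.intra_class] = (
                table.intra_counts.get(cls.intra_class, 0) + 1
            )
    return table


@dataclass
class Scaffold:
    """An ordered, signed contig list with per-junction gap estimates."""

    order: list[tuple[str, str]]
    gaps: list[Optional[float]] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.gaps:
            n_junctions = len(self.order) if self.circular else len(self.order) - 1
            self.gaps = [None] * max(n_junctions, 0)

    @property
    def n_contigs(self) -> int:
        return len(self.order)


@dataclass
class ScaffoldResult:
    scaffolds: list[Scaffold]
    accepted_links: list[tuple[tuple[End, End], int]]
    warnings: list[str] = field(default_factory=list)

    @property
    def is_single_circle(self) -> bool:
        return len(self.scaffolds) == 1 and self.scaffolds[0].circular

    @property
    def scaffold(self) -> Scaffold:
        if len(self.scaffolds) != 1:
            raise ScaffoldConflictError(
                f"{len(self.scaffolds)} scaffolds present; closure incomplete"
            )
        return self.scaffolds[0]


def build_scaffold(
    table: OrientationCountTable,
    min_support: int = 5,
    dominance_ratio: float = 4.0,
) -> ScaffoldResult:
    """Close contigs into scaffolds by greedy maximum-support link acceptance.

    For each contig pair, minority orientation cells are ignored when the
    dominant cell exceeds them by at least ``dominance_ratio`` (pairs
    spanning an inversion-polymorphic junction produce such minority
    cells; they are inversion evidence, not scaffold evidence).  Links
    with support below ``min_support`` are never accepted.  Ties break
    lexicographically for determinism.  If the accepted links form one
    cycle over all contigs the scaffold is circular; otherwise the
    linear pieces are returned with a warning.
    """
    # dominance filter per unordered contig pair
    by_pair: dict[frozenset, list[tuple[tuple[End, End], int]]] = {}
    for link, n in table.link_counts.items():
        key = frozenset((link[0][0], link[1][0]))
        by_pair.setdefault(key, []).append((link, n))
    candidates: list[tuple[tuple[End, End], int]] = []
    for cells in by_pair.values():
        cmax = max(n for _, n in cells)
        for link, n in cells:
            if n == cmax or n * dominance_ratio > cmax:
                candidates.append((link, n))
    candidates = [(l, n) for l, n in candidates if n >= min_support]
    candidates.sort(key=lambda ln: (-ln[1], ln[0]))

    n_contigs = len(table.contig_ids)
    if n_contigs == 1:
        only = Scaffold(order=[(table.contig_ids[0], "+")], circular=True)
        return ScaffoldResult(scaffolds=[only], accepted_links=[])
    parent = {c: c for c in table.contig_ids}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    comp_size = {c: 1 for c in table.contig_ids}
    end_used: set[End] = set()
    accepted: list[tuple[tuple[End, End], int]] = []
    closed_cycle = False
    for link, n in candidates:
        (ci, si), (cj, sj) = link
        if (ci, si) in end_used or (cj, sj) in end_used or closed_cycle:
            continue
        if ci == cj:
            continue  # self-link cannot be a junction between distinct placements
        ri, rj = find(ci), find(cj)
        if ri == rj:
            # would close a cycle: allowed only for the final full circle
            if comp_size[ri] == n_contigs:
                accepted.append((link, n))
                end_used.update(link)
                closed_cycle = True
            continue
        parent[ri] = rj
        comp_size[rj] += comp_size[ri]
        end_used.update(link)
        accepted.append((link, n))

    scaffolds, warnings = _traverse(table.contig_ids, accepted, closed_cycle)
    return ScaffoldResult(scaffolds=scaffolds, accepted_links=accepted, warnings=warnings)


def _traverse(
    contig_ids: Sequence[str],
    accepted: list[tuple[tuple[End, End], int]],
    closed_cycle: bool,
) -> tuple[list[Scaffold], list[str]]:
    partner: dict[End, End] = {}
    for link, _ in accepted:
        a, b = link
        if a in partner or b in partner:
            raise ScaffoldConflictError(f"contig end used twice by link {link}")
        partner[a] = b
        partner[b] = a

    seen: set[str] = set()
    scaffolds: list[Scaffold] = []
    warnings: list[str] = []

    def walk(start: str, start_strand: str) -> tuple[list[tuple[str, str]], bool]:
        order = [(start, start_strand)]
        seen.add(start)
        cur, strand = start, start_strand
        while True:
            exit_side = TAIL if strand == "+" else HEAD
            nxt = partner.get((cur, exit_side))
            if nxt is None:
                return order, False
            nc, nside = nxt
            if nc == start:
                entry = HEAD if start_strand == "+" else TAIL
                if nside != entry:
                    raise ScaffoldConflictError(
                        f"cycle-closing link {((cur, exit_side), nxt)} contradicts "
                        f"the propagated orientation of {start!r}"
                    )
                return order, True  # cycle closed
            if nc in seen:
                raise ScaffoldConflictError(
                    f"orientation propagation revisited {nc!r} via link "
                    f"{((cur, exit_side), nxt)}"
                )
            strand = "+" if nside == HEAD else "-"
            order.append((nc, strand))
            seen.add(nc)
            cur = nc

    # pass 1: linear chains, started from a free head/tail so the walk
    # covers the whole chain; isolated contigs are length-1 chains
    for cid in contig_ids:
        if cid in seen:
            continue
        head_free = (cid, HEAD) not in partner
        tail_free = (cid, TAIL) not in partner
        if head_free and tail_free:
            scaffolds.append(Scaffold(order=[(cid, "+")], circular=False))
            seen.add(cid)
        elif head_free:
            order, _ = walk(cid, "+")
            scaffolds.append(Scaffold(order=order, circular=False))
        elif tail_free:
            order, _ = walk(cid, "-")
            scaffolds.append(Scaffold(order=order, circular=False))

    # pass 2: remaining contigs all sit on cycles
    for cid in contig_ids:
        if cid in seen:
            continue
        order, cyc = walk(cid, "+")
        if not cyc:
            raise ScaffoldConflictError(
                f"walk from doubly-linked contig {cid!r} ended without closing"
            )
        scaffolds.append(Scaffold(order=order, circular=True))

    if len(scaffolds) > 1 or (scaffolds and not scaffolds[0].circular):
        warnings.append(
            f"closure incomplete: {len(scaffolds)} scaffold(s), "
            f"circular={[s.circular for s in scaffolds]}"
        )
    return scaffolds, warnings


def estimate_gaps(
    pairs: Iterable[PairedAlignment],
    scaffold: Scaffold,
    library: LibrarySpec,
    targets: Sequence[SequenceRecord],
) -> list[Optional[float]]:
    """Estimate each junction gap from the pairs that span it.

    For a spanning pair, read-to-contig-end distances ``d_a`` and ``d_b``
    on the two sides satisfy ``fragment = d_a + gap + d_b``.  Fragments
    observed spanning a junction are a size-biased sample (a fragment of
    length L crosses a gap g from L - g - 2k + 1 start positions), so the
    naive ``mean_insert - mean(d_a + d_b)`` underestimates gaps by
    roughly Var(L)/E(L); instead the gap solves the moment condition
    ``mean(d_a + d_b) = E[L | spanning; g] - g`` under the library's
    uniform insert distribution.  Junctions with no spanning pairs get
    ``None`` (unknown).  Estimates may be negative (overlapping contigs).
    """
    info = _seq_info(targets)
    lengths = {t.id: len(t) for t in targets}
    junctions: list[tuple[End, End]] = []
    n = len(scaffold.order)
    n_j = n if scaffold.circular else n - 1
    for i in range(n_j):
        ca, sa = scaffold.order[i]
        cb, sb = scaffold.order[(i + 1) % n]
        end_a: End = (ca, TAIL if sa == "+" else HEAD)
        end_b: End = (cb, HEAD if sb == "+" else TAIL)
        junctions.append(_canonical_link(end_a, end_b))
    j_index = {j: i for i, j in enumerate(junctions)}

    spans: list[list[int]] = [[] for _ in range(n_j)]
    rl = library.read_length
    for pa in pairs:
        cls = classify_relative_orientation(pa.aln1, pa.aln2, library, info)
        if cls.kind != "inter" or cls.link not in j_index:
            continue
        d = 0
        for a in (pa.aln1, pa.aln2):
            side = next(s for c, s in cls.link if c == a.seq_id)
            if side == TAIL:
                d += lengths[a.seq_id] - a.pos + 1
            else:
                d += a.pos + rl - 1
        spans[j_index[cls.link]].append(d)
    estimates: list[Optional[float]] = [
        (_solve_gap(sum(s) / len(s), library) if s else None) for s in spans
    ]
    scaffold.gaps = estimates
    return estimates


def _expected_span(gap: float, library: LibrarySpec) -> float:
    """E[d_a + d_b] for pairs spanning a junction with the given gap."""
    L = np.arange(library.insert_min, library.insert_max + 1, dtype=float)
    w = np.clip(L - gap - 2 * library.read_length + 1, 0.0, None)
    total = w.sum()
    if total == 0:
        return 0.0
    return float((L * w).sum() / total - gap)


def _solve_gap(mean_span: float, library: LibrarySpec) -> float:
    """Invert the spanning-pair moment condition for the gap (bisection;
    E[span | gap] is strictly decreasing in the gap)."""
    lo = -float(library.insert_max)
    hi = float(library.insert_max - 2 * library.read_length - 1)
    if mean_span >= _expected_span(lo, library):
        return lo
    if mean_span <= _expected_span(hi, library):
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if _expected_span(mid, library) > mean_span:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def same_layout(
    a: Sequence[tuple[str, str]],
    b: Sequence[tuple[str, str]],
    circular: bool = True,
) -> bool:
    """Whether two signed contig orders agree up to rotation and reflection."""
    if len(a) != len(b):
        return False
    a = list(a)

    def reflected(order):
        return [(c, "+" if s == "-" else "-") for c, s in reversed(order)]

    variants = [list(b), reflected(b)]
    if circular:
        rotated = []
        for v in variants:
            rotated.extend(v[i:] + v[:i] for i in range(len(v)))
        variants = rotated
    return any(a == v for v in variants)


def write_agp(
    scaffold: Scaffold,
    contig_lengths: dict[str, int],
    path: PathLike,
    object_name: str = "scaffold1",
    default_gap: int = 100,
) -> None:
    """Write the scaffold as AGP v2.1.

    Unknown gaps become 100 bp ``U`` gaps; estimated gaps become ``N``
    gaps of the rounded estimate (floored at 1 bp).  A circular scaffold
    is linearised starting at its first contig, with the wrap-around
    junction noted in a comment.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        if scaffold.circular:
            fh.write(f"# circular scaffold; junction after last component wraps to first\n")
        obj_pos = 1
        part = 1
        n = len(scaffold.order)
        for i, (cid, strand) in enumerate(scaffold.order):
            clen = contig_lengths[cid]
            fh.write(
                f"{object_name}\t{obj_pos}\t{obj_pos + clen - 1}\t{part}\tW\t"
                f"{cid}\t1\t{clen}\t{strand}\n"
            )
            obj_pos += clen
            part += 1
            last = i == n - 1
            if last and not scaffold.circular:
                break
            if last and scaffold.circular:
                break  # wrap gap not representable in linear AGP
            gap = scaffold.gaps[i] if i < len(scaffold.gaps) else None
            if gap is None:
                glen, gtype = default_gap, "U"
            else:
                glen, gtype = max(int(round(gap)), 1), "N"
            fh.write(
                f"{object_name}\t{obj_pos}\t{obj_pos + glen - 1}\t{part}\t{gtype}\t"
                f"{glen}\tscaffold\tyes\tpaired-ends\n"
            )
            obj_pos += glen
            part += 1


def scaffold_fasta(
    scaffold: Scaffold,
    contigs: Sequence[SequenceRecord],
    default_gap: int = 100,
    name: str = "scaffold1",
) -> SequenceRecord:
    """Materialise the scaffold sequence with N-runs for the gaps."""
    seqs = {c.id: c.seq for c in contigs}
    parts: list[str] = []
    n = len(scaffold.order)
    for i, (cid, strand) in enumerate(scaffold.order):
        s = seqs[cid]
        parts.append(revcomp(s) if strand == "-" else s)
        if i == n - 1 and not scaffold.circular:
            break
        gap = scaffold.gaps[i] if i < len(scaffold.gaps) else None
        if i == n - 1 and scaffold.circular:
            break  # circular: wrap junction carries no inserted N-run
        glen = default_gap if gap is None else max(int(round(gap)), 1)
        parts.append("N" * glen)
    return SequenceRecord(name, "".join(parts), circular=scaffold.circular)
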