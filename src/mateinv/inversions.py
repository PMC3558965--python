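"""Population-polymorphic inversion detection from mate-pair orientation.

On a closed circular chromosome, a mate pair drawn from a cell whose
genome carries an inverted segment — and whose fragment straddles one of
the two breakpoints — maps with its two reads on opposite strands
(under a same-strand mate-pair library), one read just outside the
breakpoint and its mate reflected to just inside the *other* breakpoint.
Pairs bracketing the segment's start are distinguished from pairs
bracketing its end by the mapped strand of the fragment's 5' read: the
fragment runs left-to-right in reference coordinates at its 5' read
exactly when it straddles the start breakpoint.

The caller clusters inverted pairs per breakpoint side, pairs start-side
with end-side clusters into candidate inverted segments, reports the
innermost uniquely-mappable coordinates (flanking inverted repeats are
unmappable at 25 bp and widen the reported uncertainty windows, which
always bracket the true breakpoints on error-free data), and estimates
each locus's population frequency as the inverted fraction of
uniquely-mapping pairs spanning the breakpoints, with a Wilson score
interval.  Fragments cannot span both breakpoints of a segment much
longer than the insert, so the two breakpoints contribute independent
spanning pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.proportion import proportion_confint

from .core import Interval, LibrarySpec, SequenceRecord
from .mapping import PairedAlignment
from .scaffold import (
    CONCORDANT,
    INVERTED,
    SeqInfo,
    classify_relative_orientation,
    fragment_directions,
)

PathLike = Union[str, Path]

START_SIDE = "start"  # pairs bracketing the segment's start breakpoint
END_SIDE = "end"


class FrequencyUndefinedError(ZeroDivisionError):
    """No spanning pairs at all: the inverted fraction is undefined."""


@dataclass(frozen=True)
class InvertedPair:
    """One inverted-orientation pair, reduced to its mapped footprint."""

    pair_id: str
    lo: int  # leftmost mapped read start (reference coordinates)
    hi: int  # rightmost mapped read start
    side: str  # START_SIDE or END_SIDE


@dataclass
class ConcordantFootprint:
    pair_id: str
    frag_start: int  # implied fragment interval, 1-based closed, may wrap
    frag_end: int


@dataclass
class DiscordantCluster:
    """A breakpoint-side cluster of inverted pairs.

    Footprint extrema are stored in a rotated (origin-free) frame shared
    by all clusters of one run; ``rotation`` maps back to reference
    coordinates.  ``breakpoint_window`` is the interval of reference
    coordinates in which this cluster alone places its breakpoint; its
    span never exceeds the maximum insert size.
    """

    seq_id: str
    side: str
    members: list[str]
    lo_min: int
    lo_max: int
    hi_min: int
    hi_max: int
    mean_separation: float
    rotation: int = 0
    seq_len: int = 0

    @property
    def support(self) -> int:
        return len(self.members)

    def _to_ref(self, pos: int) -> int:
        return (pos - 1 + self.rotation) % self.seq_len + 1

    def breakpoint_window(self, library: LibrarySpec) -> Interval:
        k = library.read_length
        if self.side == START_SIDE:
            a = self.lo_max + k
            b = self.lo_min + library.insert_max
        else:
            a = self.hi_max + k - 1 - library.insert_max
            b = self.hi_min - 1
        a, b = max(a, min(a, b)), max(a, b)
        return Interval(self.seq_id, self._to_ref(a), self._to_ref(b))


@dataclass
class InversionCall:
    """A called inverted segment with its population frequency.

    ``interval`` carries the innermost uniquely-mappable coordinates;
    ``start_window`` / ``end_window`` are the uncertainty intervals
    (reference coordinates) bracketing the true breakpoints — wide when
    the boundaries sit inside inverted repeats longer than a read.
    """

    name: str
    interval: Interval
    length: int
    frequency: float
    ci_low: float
    ci_high: float
    support_inverted: int
    support_concordant: int
    start_window: tuple[int, int]
    end_window: tuple[int, int]
    ambiguous: bool = False
    # (inverted, concordant) spanning counts at the start and end breakpoints
    support_by_breakpoint: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def support_total(self) -> int:
        """All uniquely-mapping pairs spanning either breakpoint."""
        return self.support_inverted + self.support_concordant


def classify_intra_pairs(
    alignments: Iterable[PairedAlignment],
    library: LibrarySpec,
    chromosome: SequenceRecord,
) -> tuple[list[InvertedPair], list[ConcordantFootprint], dict[str, int]]:
    """Split intra-chromosome pairs into inverted / concordant / other.

    Every pair lands in exactly one class (counts returned).  Raises if
    alignments touch more than one sequence — the caller runs
    per-replicon.
    """
    info = {chromosome.id: SeqInfo(len(chromosome), chromosome.circular)}
    L = len(chromosome)
    k = library.read_length
    inverted: list[InvertedPair] = []
    concordant: list[ConcordantFootprint] = []
    counts = {CONCORDANT: 0, INVERTED: 0, "other_discordant": 0}
    for pa in alignments:
        if pa.aln1.seq_id != chromosome.id or pa.aln2.seq_id != chromosome.id:
            raise ValueError(
                f"pair {pa.pair_id!r} maps to {pa.aln1.seq_id!r}/{pa.aln2.seq_id!r}; "
                f"inversion analysis runs against {chromosome.id!r} only"
            )
        cls = classify_relative_orientation(pa.aln1, pa.aln2, library, info)
        if cls.intra_class == INVERTED:
            counts[INVERTED] += 1
            d1, _ = fragment_directions(pa.aln1, pa.aln2, library)
            lo, hi = sorted((pa.aln1.pos, pa.aln2.pos))
            side = START_SIDE if d1 == "+" else END_SIDE
            inverted.append(InvertedPair(pa.pair_id, lo, hi, side))
        elif cls.intra_class == CONCORDANT:
            counts[CONCORDANT] += 1
            d1, _ = fragment_directions(pa.aln1, pa.aln2, library)
            sep = cls.separation
            if d1 == "+":
                fs = pa.aln1.pos
            else:
                fs = (pa.aln1.pos + k - 1 - sep) % L + 1 if chromosome.circular else pa.aln1.pos + k - sep
            fe = (fs + sep - 2) % L + 1 if chromosome.circular else fs + sep - 1
            concordant.append(ConcordantFootprint(pa.pair_id, fs, fe))
        else:
            counts["other_discordant"] += 1
    return inverted, concordant, counts


def collect_inverted_pairs(
    alignments: Iterable[PairedAlignment],
    library: LibrarySpec,
    chromosome: SequenceRecord,
) -> list[InvertedPair]:
    """Pairs whose relative strands violate the library convention."""
    inverted, _, _ = classify_intra_pairs(alignments, library, chromosome)
    return inverted


def _rotation_offset(pairs: Sequence[InvertedPair], L: int) -> int:
    """Offset of the largest inverted-pair-free arc, so clustering is linear.

    Rotating reference coordinates by this offset puts the origin inside
    the widest gap between inverted-pair footprints; clusters then never
    straddle the rotated origin.
    """
    pos = sorted({p for ip in pairs for p in (ip.lo, ip.hi)})
    if not pos:
        return 0
    gaps = [(pos[0] + L - pos[-1], pos[-1])]
    gaps += [(b - a, a) for a, b in zip(pos, pos[1:])]
    _, gap_start = max(gaps)
    return gap_start  # rotated coord = (ref - 1 - offset) % L + 1 with offset=gap_start


def cluster_breakpoints(
    inverted: Sequence[InvertedPair],
    library: LibrarySpec,
    min_support: int,
    chromosome: SequenceRecord,
) -> list[DiscordantCluster]:
    """Single-linkage clustering of inverted-pair footprints per breakpoint side.

    Two pairs of the same side link when both footprint coordinates lie
    within one maximum insert of each other (pairs witnessing one
    breakpoint of one segment can never be farther apart).  Clusters
    below ``min_support`` are dropped.  Circular chromosomes are rotated
    into the widest footprint-free arc first, so origin-wrapping loci
    cluster correctly.
    """
    L = len(chromosome)
    rot = _rotation_offset(inverted, L) if chromosome.circular else 0
    k = library.read_length
    clusters: list[DiscordantCluster] = []
    for side in (START_SIDE, END_SIDE):
        group = [ip for ip in inverted if ip.side == side]
        if not group:
            continue
        # rotate both read positions, then reassign the left/right roles:
        # a footprint straddling the reference origin has them swapped
        p1 = np.array([(ip.lo - 1 - rot) % L + 1 for ip in group])
        p2 = np.array([(ip.hi - 1 - rot) % L + 1 for ip in group])
        lo = np.minimum(p1, p2)
        hi = np.maximum(p1, p2)
        n = len(group)
        close = (np.abs(lo[:, None] - lo[None, :]) <= library.insert_max) & (
            np.abs(hi[:, None] - hi[None, :]) <= library.insert_max
        )
        n_comp, labels = connected_components(coo_matrix(close), directed=False)
        for c in range(n_comp):
            idx = np.nonzero(labels == c)[0]
            if len(idx) < min_support:
                continue
            clusters.append(
                DiscordantCluster(
                    seq_id=chromosome.id,
                    side=side,
                    members=[group[i].pair_id for i in idx],
                    lo_min=int(lo[idx].min()),
                    lo_max=int(lo[idx].max()),
                    hi_min=int(hi[idx].min()),
                    hi_max=int(hi[idx].max()),
                    mean_separation=float(np.mean(hi[idx] - lo[idx] + k)),
                    rotation=rot,
                    seq_len=L,
                )
            )
    clusters.sort(key=lambda c: (c.lo_min, c.side))
    return clusters


@dataclass
class ClusterPairing:
    start_cluster: DiscordantCluster
    end_cluster: DiscordantCluster
    ambiguous: bool = False

    @property
    def support(self) -> int:
        return self.start_cluster.support + self.end_cluster.support


def pair_clusters_to_inversions(
    clusters: Sequence[DiscordantCluster],
    library: LibrarySpec,
    max_bracket_gap: Optional[int] = None,
) -> tuple[list[ClusterPairing], list[DiscordantCluster]]:
    """Match start-side with end-side clusters into inverted segments.

    A start-side cluster (outside reads left of the segment start,
    mates just inside its end) is viable with an end-side cluster
    (reads just inside the start, mates outside the end) when the
    start-side footprints precede the end-side footprints at both
    breakpoints by at most ``max_bracket_gap`` (default twice the
    maximum insert, which accommodates gene-scale unmappable flanking
    repeats).  Best-support pairings win greedily; clusters viable in
    more than one pairing are flagged ambiguous; unpaired clusters are
    returned as orphans.
    """
    if max_bracket_gap is None:
        max_bracket_gap = 2 * library.insert_max
    starts = [c for c in clusters if c.side == START_SIDE]
    ends = [c for c in clusters if c.side == END_SIDE]
    viable: list[tuple[int, int, int]] = []  # (support, i_start, i_end)
    for i, a in enumerate(starts):
        for j, b in enumerate(ends):
            if not (a.lo_max < b.lo_min and a.hi_max < b.hi_min):
                continue
            if b.lo_min - a.lo_max > max_bracket_gap:
                continue
            if b.hi_min - a.hi_max > max_bracket_gap:
                continue
            if b.lo_min <= a.hi_max + library.read_length - 1:
                # implied segment start precedes its end
                viable.append((a.support + b.support, i, j))
    viable.sort(key=lambda t: (-t[0], t[1], t[2]))
    start_uses = [si for _, si, _ in viable]
    end_uses = [ej for _, _, ej in viable]
    multi_start = {i for i in start_uses if start_uses.count(i) > 1}
    multi_end = {j for j in end_uses if end_uses.count(j) > 1}
    used_s: set[int] = set()
    used_e: set[int] = set()
    pairings: list[ClusterPairing] = []
    for _, i, j in viable:
        if i in used_s or j in used_e:
            continue
        used_s.add(i)
        used_e.add(j)
        pairings.append(
            ClusterPairing(
                starts[i], ends[j], ambiguous=(i in multi_start or j in multi_end)
            )
        )
    orphans = [c for k, c in enumerate(starts) if k not in used_s]
    orphans += [c for k, c in enumerate(ends) if k not in used_e]
    return pairings, orphans


def wilson_interval(successes: int, total: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, total, alpha=alpha, method="wilson")
    # guard against float drift just past the unit interval at k=0 / k=n
    return max(float(lo), 0.0), min(float(hi), 1.0)


def estimate_inversion_frequency(
    support_inverted: int, support_concordant: int
) -> tuple[float, float, float]:
    """Inverted fraction of spanning pairs with its Wilson 95% interval."""
    total = support_inverted + support_concordant
    if total < 1:
        raise FrequencyUndefinedError("no pairs span the breakpoints")
    freq = support_inverted / total
    lo, hi = wilson_interval(support_inverted, total)
    # Wilson always contains the point estimate; enforce it against float dust
    return freq, min(lo, freq), max(hi, freq)


def _circ_contains(a: int, b: int, q: int, L: int, circular: bool) -> bool:
    if a <= b:
        return a <= q <= b
    if not circular:
        return False
    return q >= a or q <= b


def call_inversions(
    alignments: Iterable[PairedAlignment],
    library: LibrarySpec,
    chromosome: SequenceRecord,
    min_support: int = 10,
    min_frequency: float = 0.05,
    annotations: Optional[Sequence[tuple[str, Interval]]] = None,
) -> list[InversionCall]:
    """Full pipeline: collect → cluster → pair → localise → estimate.

    Returns one call per paired cluster couple, with the segment's
    innermost uniquely-mappable coordinates, uncertainty windows
    bracketing the true breakpoints, and the population frequency
    (inverted fraction of pairs spanning either breakpoint) with a
    Wilson 95% interval.  Calls below ``min_frequency`` are suppressed;
    cluster support below ``min_support`` never reaches a call.  Names
    come from the first overlapping annotation when given, else from the
    called coordinates.
    """
    inverted, concordant, _ = classify_intra_pairs(alignments, library, chromosome)
    clusters = cluster_breakpoints(inverted, library, min_support, chromosome)
    pairings, _orphans = pair_clusters_to_inversions(clusters, library)
    L = len(chromosome)
    k = library.read_length
    rot_all = clusters[0].rotation if clusters else 0
    # concordant fragments in the clusters' rotated frame, unrolled so a
    # fragment crossing the rotated origin has end > L
    frag_s = np.array(
        [(cf.frag_start - 1 - rot_all) % L + 1 for cf in concordant], dtype=np.int64
    )
    frag_e = np.array(
        [(cf.frag_end - 1 - rot_all) % L + 1 for cf in concordant], dtype=np.int64
    )
    frag_e = np.where(frag_e < frag_s, frag_e + L, frag_e)

    def n_concordant_bracketing(left_end_max: int, right_start_min: int) -> int:
        """Concordant pairs whose two reads bracket a breakpoint region.

        The left read must end by ``left_end_max`` and the right read
        start at or after ``right_start_min`` — the extremes the
        inverted evidence itself attains around the (possibly
        repeat-widened) breakpoint.  Using the same acceptance region
        for both classes keeps the inverted fraction an unbiased
        estimate of the haplotype fraction.
        """
        if frag_s.size == 0:
            return 0
        n = 0
        for le, rs in (
            (left_end_max, right_start_min),
            (left_end_max + L, right_start_min + L),
        ):
            n += int(
                np.count_nonzero((frag_s + k - 1 <= le) & (frag_e - k + 1 >= rs))
            )
        return n

    calls: list[InversionCall] = []
    for p in pairings:
        a, b = p.start_cluster, p.end_cluster
        rot = a.rotation
        start_r = b.lo_min  # innermost unique coordinate after the start flank
        end_r = a.hi_max + k - 1  # innermost unique coordinate before the end flank
        # uncertainty windows bracketing the observable sequence-change
        # junctions.  Deterministic bounds: every read anchors at least one
        # genuinely matching base on its own side of a junction, but may
        # overhang the junction by up to read_length-1 chance-matching (or
        # repeat-mirrored) bases, so each bound concedes that allowance.
        sw = (a.lo_max + 1, b.lo_min + k - 1)
        ew = (a.hi_max, b.hi_min + k - 2)

        def to_ref(pos: int) -> int:
            return (pos - 1 + rot) % L + 1

        start, end = to_ref(start_r), to_ref(end_r)
        support_inv = a.support + b.support
        conc_start = n_concordant_bracketing(a.lo_max + k - 1, b.lo_min)
        conc_end = n_concordant_bracketing(a.hi_max + k - 1, b.hi_min)
        span_conc = conc_start + conc_end
        freq, ci_lo, ci_hi = estimate_inversion_frequency(support_inv, span_conc)
        if freq < min_frequency:
            continue
        iv = Interval(chromosome.id, start, end)
        length = iv.length(L)
        name = f"inv_{start}_{end}"
        if annotations:
            for ann_name, ann_iv in annotations:
                if ann_iv.seq_id == chromosome.id and _overlaps(iv, ann_iv, L):
                    name = ann_name
                    break
        calls.append(
            InversionCall(
                name=name,
                interval=iv,
                length=length,
                frequency=freq,
                ci_low=ci_lo,
                ci_high=ci_hi,
                support_inverted=support_inv,
                support_concordant=span_conc,
                start_window=(to_ref(sw[0]), to_ref(sw[1])),
                end_window=(to_ref(ew[0]), to_ref(ew[1])),
                ambiguous=p.ambiguous,
                support_by_breakpoint=((a.support, conc_start), (b.support, conc_end)),
            )
        )
    calls.sort(key=lambda c: (c.interval.start, c.interval.end))
    return calls


def _overlaps(a: Interval, b: Interval, L: int) -> bool:
    def positions(iv: Interval) -> tuple[int, int, bool]:
        return iv.start, iv.end, iv.wraps

    a_s, a_e, a_w = positions(a)
    b_s, b_e, b_w = positions(b)
    if not a_w and not b_w:
        return a_s <= b_e and b_s <= a_e
    # wrap-aware: check endpoint containment both ways
    return (
        _circ_contains(a_s, a_e, b_s, L, True)
        or _circ_contains(a_s, a_e, b_e, L, True)
        or _circ_contains(b_s, b_e, a_s, L, True)
    )


def calls_to_tsv(calls: Sequence[InversionCall], path: PathLike) -> None:
    """Write calls as a TSV mirroring a genome-report inversion table."""
    with open(path, "w") as fh:
        fh.write(
            "name\tstart\tend\tlength\tfrequency\tci_low\tci_high"
            "\tsupport_inverted\tsupport_concordant"
            "\tstart_window_lo\tstart_window_hi\tend_window_lo\tend_window_hi\n"
        )
        for c in calls:
            fh.write(
                f"{c.name}\t{c.start}\t{c.end}\t{c.length}\t{c.frequency:.4f}"
                f"\t{c.ci_low:.4f}\t{c.ci_high:.4f}\t{c.support_inverted}"
                f"\t{c.support_concordant}\t{c.start_window[0]}\t{c.start_window[1]}"
                f"\t{c.end_window[0]}\t{c.end_window[1]}\n"
            )


def calls_to_bed(calls: Sequence[InversionCall], path: PathLike) -> None:
    """Write non-wrapping calls as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in calls:
            if c.interval.wraps:
                continue  # wrapping calls need two records; TSV carries them
            fh.write(f"{c.interval.seq_id}\t{c.start - 1}\t{c.end}\t{c.name}\t0\t+\n")
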