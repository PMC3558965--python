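"""Synthetic genomes, heterogeneous populations and mate-pair libraries.

The generator emulates the sequencing design used to close a small
circular archaeal genome: a circular main chromosome (~55% GC) plus a
small circular extra-chromosomal element (ECE), interspersed random
repeat families (paREP-like in their mapping consequences), inversion
loci flanked by inverted repeat copies, a not-quite-clonal population in
which each inversion is carried by a stated fraction of cells, a
mate-pair library with 1,000-3,500 bp inserts and 25 bp reads, and a
~20-contig long-read-like fragmentation of the chromosome.

Everything is a pure function of ``(config, seed)``; no global RNG state
is touched.  Truth metadata (haplotype states, fragment intervals,
contig layout, repeat placements) rides along with every output so that
downstream stages can be scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    Interval,
    LibrarySpec,
    MatePair,
    PairTruth,
    SequenceRecord,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CHROM_ID = "chr"
ECE_ID = "ece"


@dataclass(frozen=True)
class InversionLocus:
    """An invertible segment segregating in the population.

    ``frequency`` is the fraction of cells carrying the inverted state;
    ``flank_repeat_len`` is the length of the inverted repeat copy placed
    just inside each boundary (the copies are exact reverse complements
    of each other, so the inverted allele is locally identical to the
    reference across the repeats — the feature that blurs breakpoint
    mapping in real data).
    """

    name: str
    start: int
    end: int
    frequency: float
    flank_repeat_len: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ConfigError(f"locus {self.name!r}: frequency outside [0, 1]")
        if self.start >= self.end:
            raise ConfigError(f"locus {self.name!r}: start must be < end")
        if self.flank_repeat_len < 0:
            raise ConfigError(f"locus {self.name!r}: negative flank_repeat_len")
        if 2 * self.flank_repeat_len >= self.end - self.start + 1:
            raise ConfigError(f"locus {self.name!r}: flanks longer than the locus")

    @property
    def interval(self) -> Interval:
        return Interval(CHROM_ID, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def default_loci(genome_len: int) -> tuple[InversionLocus, ...]:
    """Three polymorphic inversion loci emulating the study population.

    Frequencies are the observed population fractions (0.17, 0.18,
    0.35).  Segment lengths are kept in the tens of kilobases — far
    above the maximum insert size, as in the real genome — rather than
    scaled strictly proportionally, so that no mate pair can span an
    entire inversion.  The first locus carries a gene-scale (1.5 kb)
    inverted duplication at its boundaries, mirroring the glutamate
    dehydrogenase duplication; the others carry short flanking repeats.
    """
    if genome_len < 280_000:
        raise ConfigError("default loci require genome_len >= 280,000")
    return (
        InversionLocus("inv_gdh", 40_000, 65_000, 0.17, flank_repeat_len=1500),
        InversionLocus("inv_ramp", 130_000, 152_000, 0.18, flank_repeat_len=300),
        InversionLocus("inv_c8", 210_000, 231_000, 0.35, flank_repeat_len=300),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Exactly one of ``pair_count`` and ``physical_coverage`` is given;
    physical coverage is the mean number of fragments spanning a
    position, so ``pair_count = coverage * genome_len / mean_insert``.
    """

    genome_len: int = 300_000
    gc_target: float = 0.5508
    n_contigs: int = 20
    library: LibrarySpec = field(default_factory=LibrarySpec)
    pair_count: Optional[int] = None
    physical_coverage: Optional[float] = None
    substitution_error_rate: float = 0.0
    seed: int = 0
    loci: tuple[InversionLocus, ...] = ()
    repeat_families: tuple[tuple[int, int], ...] = ((300, 8), (500, 5), (1000, 3))
    ece_len: int = 16_887
    ece_gc: float = 0.5058

    def __post_init__(self) -> None:
        if self.genome_len < 4 * self.library.insert_max:
            raise ConfigError("genome_len must be >= 4 * insert_max")
        if not 0.0 <= self.substitution_error_rate < 0.1:
            raise ConfigError("substitution_error_rate must be in [0, 0.1)")
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        if self.pair_count is not None and self.physical_coverage is not None:
            raise ConfigError("give pair_count or physical_coverage, not both")
        starts = sorted((l.start, l.end) for l in self.loci)
        for (s1, e1), (s2, _) in zip(starts, starts[1:]):
            if s2 <= e1:
                raise ConfigError("inversion loci must be pairwise non-overlapping")
        for loc in self.loci:
            if loc.end > self.genome_len:
                raise ConfigError(f"locus {loc.name!r} extends past the genome")

    @property
    def n_pairs(self) -> int:
        if self.pair_count is not None:
            return self.pair_count
        cov = self.physical_coverage if self.physical_coverage is not None else 10.0
        return int(round(cov * self.genome_len / self.library.insert_mean))


@dataclass
class PopulationModel:
    """A reference chromosome plus the polymorphisms segregating on it."""

    reference: SequenceRecord
    loci: tuple[InversionLocus, ...]
    ece: Optional[SequenceRecord] = None
    repeat_placements: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    return comp[arr][::-1]


def simulate_reference(config: SimConfig) -> tuple[PopulationModel, dict[str, pd.DataFrame]]:
    """Build the reference replicons, inversion flanks and repeat families.

    Returns the population model and truth tables (``loci``, ``repeats``)
    recording every placement.  Repeat copies are placed uniformly,
    rejecting positions that would overlap an inversion flank, a locus
    boundary or a previously placed copy; a placement that cannot be
    satisfied after bounded retries raises :class:`ConfigError`.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_len
    seq = _random_dna(rng, L, config.gc_target)

    # inverted repeat copies just inside each locus boundary
    for loc in config.loci:
        r = loc.flank_repeat_len
        if r > 0:
            flank = _random_dna(rng, r, config.gc_target)
            seq[loc.start - 1 : loc.start - 1 + r] = flank
            seq[loc.end - r : loc.end] = _revcomp_arr(flank)

    # exclusion zones: flanks (or bare boundaries) of every locus
    exclude: list[tuple[int, int]] = []
    for loc in config.loci:
        r = max(loc.flank_repeat_len, 1)
        exclude.append((loc.start, loc.start + r - 1))
        exclude.append((loc.end - r + 1, loc.end))

    def overlaps(a: int, b: int, zones: list[tuple[int, int]]) -> bool:
        return any(a <= ze and b >= zs for zs, ze in zones)

    placements = []
    taken = list(exclude)
    for fam_idx, (motif_len, copies) in enumerate(config.repeat_families):
        motif = _random_dna(rng, motif_len, config.gc_target)
        for copy_idx in range(copies):
            for _ in range(1000):
                s = int(rng.integers(1, L - motif_len + 1))
                e = s + motif_len - 1
                if not overlaps(s, e, taken):
                    break
            else:
                raise ConfigError(
                    f"could not place copy {copy_idx} of repeat family {fam_idx} "
                    "without overlap after 1000 retries"
                )
            seq[s - 1 : e] = motif
            taken.append((s, e))
            placements.append(
                {"family": fam_idx, "copy": copy_idx, "motif_len": motif_len,
                 "start": s, "end": e, "strand": "+"}
            )

    repeats_df = pd.DataFrame(
        placements, columns=["family", "copy", "motif_len", "start", "end", "strand"]
    )
    loci_df = pd.DataFrame(
        [
            {"name": l.name, "start": l.start, "end": l.end, "length": l.length,
             "frequency": l.frequency, "flank_repeat_len": l.flank_repeat_len}
            for l in config.loci
        ],
        columns=["name", "start", "end", "length", "frequency", "flank_repeat_len"],
    )

    reference = SequenceRecord(CHROM_ID, _to_str(seq), circular=True)
    ece = None
    if config.ece_len:
        ece = SequenceRecord(
            ECE_ID, _to_str(_random_dna(rng, config.ece_len, config.ece_gc)), circular=True
        )
    model = PopulationModel(
        reference=reference, loci=config.loci, ece=ece, repeat_placements=repeats_df
    )
    return model, {"loci": loci_df, "repeats": repeats_df}


def realize_haplotype(model: PopulationModel, states: Sequence[bool]) -> SequenceRecord:
    """Apply the inverted state of each flagged locus to the reference.

    Each flagged segment is replaced by its reverse complement in place,
    so sequence length is always conserved and applying the same states
    twice returns the reference.
    """
    if len(states) != len(model.loci):
        raise ValueError(f"need {len(model.loci)} states, got {len(states)}")
    seq = model.reference.seq
    parts: list[str] = []
    cursor = 0
    for loc, inverted in zip(model.loci, states):
        parts.append(seq[cursor : loc.start - 1])
        segment = seq[loc.start - 1 : loc.end]
        parts.append(revcomp(segment) if inverted else segment)
        cursor = loc.end
    parts.append(seq[cursor:])
    tag = "".join("I" if s else "R" for s in states)
    return SequenceRecord(
        f"{model.reference.id}|{tag}" if tag else model.reference.id,
        "".join(parts),
        circular=model.reference.circular,
    )


def simulate_mate_pairs(
    model: PopulationModel, config: SimConfig, with_truth: bool = True
) -> list[MatePair]:
    """Draw a mate-pair library from the heterogeneous population.

    Per pair: the haplotype is drawn independently per locus at the
    locus frequency; the fragment start is uniform on the circle, its
    length uniform on [insert_min, insert_max], its strand uniform; the
    two reads are the first and last ``read_length`` bases of the
    fragment, both reported on the fragment strand (mate-pair chemistry)
    unless the library specifies ``opposite`` (paired-end chemistry).
    Substitution errors are i.i.d. per base.  When the model carries an
    ECE, fragments fall on either replicon proportionally to length.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lib = config.library
    n = config.n_pairs
    L = len(model.reference)
    if not model.reference.circular and L < lib.insert_max:
        raise ConfigError("linear reference shorter than insert_max")

    ece_len = len(model.ece) if model.ece is not None else 0
    from_ece = (
        rng.random(n) < ece_len / (ece_len + L) if ece_len else np.zeros(n, dtype=bool)
    )
    n_loci = len(model.loci)
    freqs = np.array([l.frequency for l in model.loci])
    states = (
        rng.random((n, n_loci)) < freqs[None, :]
        if n_loci
        else np.zeros((n, 0), dtype=bool)
    )
    states[from_ece] = False

    frag_len = rng.integers(lib.insert_min, lib.insert_max + 1, size=n)
    strand_minus = rng.random(n) < 0.5
    u = rng.random(n)  # fragment start, scaled per-replicon below

    rl = lib.read_length
    pad = lib.insert_max
    hap_cache: dict[tuple[bool, ...], str] = {}

    def hap_seq(key: tuple[bool, ...]) -> str:
        if key not in hap_cache:
            s = realize_haplotype(model, key).seq
            hap_cache[key] = s + s[:pad]  # doubled head for origin-crossing slices
        return hap_cache[key]

    ece_doubled = (model.ece.seq + model.ece.seq[:pad]) if model.ece is not None else ""

    err = config.substitution_error_rate
    pairs: list[MatePair] = []
    for i in range(n):
        Lf = int(frag_len[i])
        if from_ece[i]:
            seq_id, rep_len = ECE_ID, ece_len
            doubled = ece_doubled
        else:
            seq_id, rep_len = CHROM_ID, L
            doubled = hap_seq(tuple(states[i]))
        if model.reference.circular or seq_id == ECE_ID:
            start = int(u[i] * rep_len) + 1  # 1-based, may wrap the origin
        else:
            start = int(u[i] * (rep_len - Lf + 1)) + 1  # linear: fragment must fit
        frag = doubled[start - 1 : start - 1 + Lf]
        if strand_minus[i]:
            frag = revcomp(frag)
        read1, read2 = frag[:rl], frag[-rl:]
        if lib.expected_relative_strand == "opposite":
            read2 = revcomp(read2)
        if err > 0:
            read1 = _mutate(rng, read1, err)
            read2 = _mutate(rng, read2, err)
        truth = None
        if with_truth:
            end = (start + Lf - 2) % rep_len + 1
            truth = PairTruth(
                haplotype_states=tuple(states[i]),
                fragment=Interval(seq_id, start, end, "-" if strand_minus[i] else "+"),
                fragment_length=Lf,
            )
        pairs.append(MatePair(f"p{i:07d}", read1, read2, truth=truth))
    return pairs


def _mutate(rng: np.random.Generator, read: str, rate: float) -> str:
    hits = np.nonzero(rng.random(len(read)) < rate)[0]
    if hits.size == 0:
        return read
    chars = list(read)
    for j in hits:
        choices = [b for b in "ACGT" if b != chars[j]]
        chars[j] = choices[int(rng.integers(3))]
    return "".join(chars)


def fragment_into_contigs(
    model: PopulationModel,
    n_contigs: int,
    seed: int,
    gap_len: int = 0,
    min_contig_len: Optional[int] = None,
    insert_max: int = 3500,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Cut the reference circle into contigs with known layout.

    Cut points are uniform on the circle subject to every contig being at
    least ``min_contig_len`` (default ``2 * insert_max``) after dropping
    ``gap_len`` bases at each junction; the constrained spacing is drawn
    directly (minimum arc plus uniform spacings of the slack), so the
    constraint always holds.  Each contig is emitted in a random
    orientation.  The returned layout table records true order, reference
    arc and emitted strand per contig.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    L = len(model.reference)
    if min_contig_len is None:
        min_contig_len = 2 * insert_max
    m = min_contig_len + gap_len
    if n_contigs * m > L:
        raise ConfigError(
            f"{n_contigs} contigs of >= {min_contig_len} bp (+{gap_len} bp gaps) "
            f"do not fit in {L} bp"
        )
    slack = L - n_contigs * m
    if n_contigs == 1:
        arcs = np.array([L])
    else:
        y = np.sort(rng.uniform(0, slack, size=n_contigs - 1))
        extras = np.diff(np.concatenate(([0.0], y, [float(slack)])))
        arcs = m + np.floor(extras).astype(int)
        arcs[-1] = L - arcs[:-1].sum()
    origin = int(rng.integers(1, L + 1))
    starts = (origin - 1 + np.concatenate(([0], np.cumsum(arcs[:-1])))) % L + 1

    contigs: list[SequenceRecord] = []
    rows = []
    for k in range(n_contigs):
        arc_start = int(starts[k])
        span = int(arcs[k]) - gap_len
        arc_end = (arc_start + span - 2) % L + 1
        seq = model.reference.fetch(arc_start, arc_end)
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            seq = revcomp(seq)
        cid = f"ctg{k + 1:02d}"
        contigs.append(SequenceRecord(cid, seq, circular=False))
        rows.append(
            {"contig_id": cid, "order": k, "ref_start": arc_start,
             "ref_end": arc_end, "strand": strand, "length": span,
             "gap_after": gap_len}
        )
    layout = pd.DataFrame(
        rows, columns=["contig_id", "order", "ref_start", "ref_end",
                       "strand", "length", "gap_after"]
    )
    return contigs, layout


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, truth included."""

    config: SimConfig
    model: PopulationModel
    truth: dict[str, pd.DataFrame]
    contigs: list[SequenceRecord]
    layout: pd.DataFrame
    pairs: list[MatePair]


def simulate_dataset(config: SimConfig, gap_len: int = 0) -> SimulatedDataset:
    """Run the full generator: reference, contigs and mate-pair library."""
    model, truth = simulate_reference(config)
    contigs, layout = fragment_into_contigs(
        model, config.n_contigs, config.seed, gap_len=gap_len,
        insert_max=config.library.insert_max,
    )
    pairs = simulate_mate_pairs(model, config)
    return SimulatedDataset(config, model, truth, contigs, layout, pairs)


def pairs_truth_table(pairs: Sequence[MatePair]) -> pd.DataFrame:
    """Truth metadata of a simulated library as a tidy table."""
    rows = []
    for p in pairs:
        t = p.truth
        if t is None:
            continue
        rows.append(
            {"pair_id": p.pair_id,
             "states": "".join("1" if s else "0" for s in t.haplotype_states),
             "seq_id": t.fragment.seq_id, "frag_start": t.fragment.start,
             "frag_end": t.fragment.end, "frag_strand": t.fragment.strand,
             "frag_len": t.fragment_length}
        )
    return pd.DataFrame(
        rows, columns=["pair_id", "states", "seq_id", "frag_start",
                       "frag_end", "frag_strand", "frag_len"]
    )
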