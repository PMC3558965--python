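"""From::To table accumulation and greedy circular closure."""

import numpy as np
import pytest

import mateinv as mi
from mateinv.core import LibrarySpec, SequenceRecord, revcomp
from mateinv.mapping import Alignment, PairedAlignment
from mateinv.scaffold import (
    CONCORDANT,
    CONVERGING,
    DIVERGING,
    INVERTED,
    LONG,
    SAME,
    SHORT,
    SeqInfo,
    classify_relative_orientation,
    link_orientation,
    same_layout,
    scaffold_fasta,
    write_agp,
)

LIB = LibrarySpec(1000, 3500, 25)


def _simulate_junction_pairs(rng, genome, cut, strand_a, strand_b, n=200):
    """Mate pairs whose fragments straddle ``cut`` on a linear genome,
    mapped onto the two contigs emitted with the given strands."""
    len_a = cut
    contig_a = genome[:cut]
    contig_b = genome[cut:]
    if strand_a == "-":
        contig_a = revcomp(contig_a)
    if strand_b == "-":
        contig_b = revcomp(contig_b)
    targets = [
        SequenceRecord("A", contig_a),
        SequenceRecord("B", contig_b),
    ]
    index = mi.build_index(targets, 25)
    pairs = []
    for i in range(n):
        L = int(rng.integers(1000, 3501))
        start = int(rng.integers(cut - L + 26, cut - 24))  # read1 in A, read2 in B
        frag = genome[start : start + L]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        pairs.append(mi.MatePair(f"p{i}", frag[:25], frag[-25:]))
    kept, _ = mi.map_pairs(index, pairs)
    return targets, kept


@pytest.mark.parametrize(
    "strand_a,strand_b,expected",
    [
        ("+", "+", SAME),
        ("+", "-", CONVERGING),
        ("-", "+", DIVERGING),
        ("-", "-", SAME),
    ],
)
def test_junction_orientation_matches_emission_enumeration(strand_a, strand_b, expected):
    """All four contig-emission strand combinations classify as derived by
    enumerating the junction geometry of a two-contig toy genome."""
    rng = np.random.default_rng(31)
    genome = "".join(rng.choice(list("ACGT"), size=30_000))
    targets, kept = _simulate_junction_pairs(rng, genome, 15_000, strand_a, strand_b)
    assert len(kept) > 150
    table = mi.accumulate_from_to_table(kept, LIB, targets)
    assert table.total == len(kept)
    orientations = {link_orientation(l) for l in table.link_counts}
    assert orientations == {expected}
    assert table.count("A", "B", expected) == len(kept)


def _aln(seq_id, pos, strand, read="r"):
    return Alignment(read, seq_id, pos, strand)


def test_intra_contig_classification_by_strand_and_separation():
    info = {"c": SeqInfo(100_000, circular=False)}
    concordant = classify_relative_orientation(
        _aln("c", 1_000, "+"), _aln("c", 3_000, "+"), LIB, info
    )
    assert concordant.intra_class == CONCORDANT
    assert concordant.separation == 2_025

    inverted = classify_relative_orientation(
        _aln("c", 1_000, "+"), _aln("c", 3_000, "-"), LIB, info
    )
    assert inverted.intra_class == INVERTED

    long_pair = classify_relative_orientation(
        _aln("c", 1_000, "+"), _aln("c", 50_000, "+"), LIB, info
    )
    assert long_pair.intra_class == LONG

    short_pair = classify_relative_orientation(
        _aln("c", 1_000, "+"), _aln("c", 1_100, "+"), LIB, info
    )
    assert short_pair.intra_class == SHORT


def test_intra_separation_wraps_on_circular_targets():
    info = {"c": SeqInfo(50_000, circular=True)}
    # read1 near the end, mate just past the origin: concordant across the origin
    cls = classify_relative_orientation(
        _aln("c", 49_500, "+"), _aln("c", 1_000, "+"), LIB, info
    )
    assert cls.intra_class == CONCORDANT
    assert cls.separation == 1_525


def test_unknown_target_rejected():
    info = {"c": SeqInfo(1_000)}
    with pytest.raises(ValueError):
        classify_relative_orientation(_aln("x", 10, "+"), _aln("c", 10, "+"), LIB, info)


def test_empty_input_gives_empty_table():
    targets = [SequenceRecord("A", "ACGT" * 500), SequenceRecord("B", "GGCA" * 500)]
    table = mi.accumulate_from_to_table([], LIB, targets)
    assert table.total == 0 and not table.link_counts


def test_single_contig_scaffold_is_circular():
    table = mi.OrientationCountTable(contig_ids=["only"])
    result = mi.build_scaffold(table)
    assert result.is_single_circle
    assert result.scaffold.order == [("only", "+")]


def test_all_cells_below_threshold_leave_singletons(scaffold_sim):
    ds, aligned, _ = scaffold_sim
    table = mi.accumulate_from_to_table(aligned, ds.config.library, ds.contigs)
    result = mi.build_scaffold(table, min_support=10**6)
    assert len(result.scaffolds) == 20
    assert all(s.n_contigs == 1 for s in result.scaffolds)
    assert result.warnings


def test_circular_recovery_matches_truth_layout(scaffold_sim):
    ds, aligned, counts = scaffold_sim
    table = mi.accumulate_from_to_table(aligned, ds.config.library, ds.contigs)
    # conservation through accumulation
    assert table.total + sum(table.intra_counts.values()) == counts["both_unique"]
    result = mi.build_scaffold(table, min_support=2)
    assert result.is_single_circle
    truth = [(r.contig_id, r.strand) for r in ds.layout.itertuples()]
    assert same_layout(result.scaffold.order, truth, circular=True)


def test_reverse_complementing_contigs_reflects_the_scaffold(scaffold_sim):
    ds, _, _ = scaffold_sim
    flipped = [SequenceRecord(c.id, revcomp(c.seq)) for c in ds.contigs]
    index = mi.build_index(flipped, 25)
    aligned, _ = mi.map_pairs(index, ds.pairs)
    table = mi.accumulate_from_to_table(aligned, ds.config.library, flipped)
    result = mi.build_scaffold(table, min_support=2)
    assert result.is_single_circle
    mirrored_truth = [
        (r.contig_id, "+" if r.strand == "-" else "-") for r in ds.layout.itertuples()
    ]
    assert same_layout(result.scaffold.order, mirrored_truth, circular=True)


def test_gap_estimates_recover_simulated_gap():
    config = mi.SimConfig(
        genome_len=120_000, seed=33, loci=(), repeat_families=(),
        physical_coverage=50, n_contigs=8, ece_len=0,
    )
    model, _ = mi.simulate_reference(config)
    contigs, layout = mi.fragment_into_contigs(
        model, 8, seed=33, gap_len=500, insert_max=3_500
    )
    pairs = mi.simulate_mate_pairs(model, config)
    index = mi.build_index(contigs, 25)
    aligned, _ = mi.map_pairs(index, pairs)
    table = mi.accumulate_from_to_table(aligned, config.library, contigs)
    result = mi.build_scaffold(table, min_support=2)
    assert result.is_single_circle
    gaps = mi.estimate_gaps(aligned, result.scaffold, config.library, contigs)
    assert all(g is not None for g in gaps)
    # uniform-insert noise: sd ~ 2500/sqrt(12)/sqrt(n) ~ 130 bp at ~30 spanners
    assert all(abs(g - 500) < 600 for g in gaps)
    assert abs(np.mean(gaps) - 500) < 150


def test_no_spanning_pairs_leaves_gap_unknown():
    scaf = mi.Scaffold(order=[("A", "+"), ("B", "+")], circular=False)
    targets = [SequenceRecord("A", "ACGT" * 2000), SequenceRecord("B", "ACGT" * 2000)]
    gaps = mi.estimate_gaps([], scaf, LIB, targets)
    assert gaps == [None]


def test_same_layout_rotation_reflection_and_mismatch():
    a = [("c1", "+"), ("c2", "-"), ("c3", "+")]
    rotated = [("c2", "-"), ("c3", "+"), ("c1", "+")]
    reflected = [("c3", "-"), ("c2", "+"), ("c1", "-")]
    scrambled = [("c1", "+"), ("c3", "+"), ("c2", "-")]
    assert same_layout(a, rotated)
    assert same_layout(a, reflected)
    assert not same_layout(a, scrambled)
    assert not same_layout(a, a[:2])
    # linear: rotation is not an equivalence
    assert not same_layout(a, rotated, circular=False)
    assert same_layout(a, list(reversed([(c, "-" if s == "+" else "+") for c, s in a])),
                       circular=False)


def test_agp_and_fasta_outputs(tmp_path, scaffold_sim):
    ds, aligned, _ = scaffold_sim
    table = mi.accumulate_from_to_table(aligned, ds.config.library, ds.contigs)
    result = mi.build_scaffold(table, min_support=2)
    scaf = result.scaffold
    mi.estimate_gaps(aligned, scaf, ds.config.library, ds.contigs)
    agp = tmp_path / "scaffold.agp"
    write_agp(scaf, {c.id: len(c) for c in ds.contigs}, agp)
    lines = [l for l in agp.read_text().splitlines() if not l.startswith("#")]
    w_lines = [l for l in lines if l.split("\t")[4] == "W"]
    assert len(w_lines) == 20  # every contig placed exactly once
    fasta_rec = scaffold_fasta(scaf, ds.contigs)
    assert fasta_rec.circular
    total_contig = sum(len(c) for c in ds.contigs)
    assert len(fasta_rec) >= total_contig  # contigs plus N gap runs


def test_table_tsv_round_trip(tmp_path, scaffold_sim):
    ds, aligned, _ = scaffold_sim
    table = mi.accumulate_from_to_table(aligned, ds.config.library, ds.contigs)
    path = tmp_path / "from_to.tsv"
    table.to_tsv(path)
    back = mi.OrientationCountTable.from_tsv(path, table.contig_ids)
    assert back.link_counts == table.link_counts
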