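"""Inverted-pair collection, breakpoint clustering and frequency estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mateinv as mi
from mateinv.core import LibrarySpec, SequenceRecord, revcomp
from mateinv.inversions import (
    END_SIDE,
    START_SIDE,
    DiscordantCluster,
    FrequencyUndefinedError,
    classify_intra_pairs,
    pair_clusters_to_inversions,
)

LIB = LibrarySpec(1000, 3500, 25)


def _chrom_pairs(bundle):
    chrom = bundle.model.reference
    return [
        pa for pa in bundle.aligned
        if pa.aln1.seq_id == chrom.id and pa.aln2.seq_id == chrom.id
    ]


def test_clonal_population_yields_no_calls(clonal_sim):
    chrom = clonal_sim.model.reference
    pairs = _chrom_pairs(clonal_sim)
    inverted = mi.collect_inverted_pairs(pairs, clonal_sim.config.library, chrom)
    assert len(inverted) == 0  # error-free clonal data has no inverted stragglers
    assert mi.call_inversions(pairs, clonal_sim.config.library, chrom) == []


def test_intra_pair_classes_conserve_totals(inversion_sim):
    chrom = inversion_sim.model.reference
    pairs = _chrom_pairs(inversion_sim)
    inverted, concordant, counts = classify_intra_pairs(
        pairs, inversion_sim.config.library, chrom
    )
    assert sum(counts.values()) == len(pairs)
    assert counts["inverted"] == len(inverted)
    assert counts["concordant"] == len(concordant)
    assert counts["inverted"] > 0


def test_multi_replicon_alignments_rejected(inversion_sim):
    chrom = inversion_sim.model.reference
    other = SequenceRecord("other", "ACGT" * 2000, circular=True)
    pairs = _chrom_pairs(inversion_sim)[:5]
    with pytest.raises(ValueError):
        classify_intra_pairs(pairs, inversion_sim.config.library, other)


def test_single_locus_gives_one_cluster_per_breakpoint_side(inversion_sim):
    chrom = inversion_sim.model.reference
    inverted = mi.collect_inverted_pairs(
        _chrom_pairs(inversion_sim), inversion_sim.config.library, chrom
    )
    clusters = mi.cluster_breakpoints(
        inverted, inversion_sim.config.library, 10, chrom
    )
    assert len(clusters) == 2
    assert {c.side for c in clusters} == {START_SIDE, END_SIDE}
    lib = inversion_sim.config.library
    for c in clusters:
        win = c.breakpoint_window(lib)
        assert win.length(len(chrom)) <= lib.insert_max


def test_no_inverted_pairs_gives_no_clusters(clonal_sim):
    clusters = mi.cluster_breakpoints(
        [], clonal_sim.config.library, 10, clonal_sim.model.reference
    )
    assert clusters == []


@pytest.fixture(scope="module")
def three_locus_bundle():
    """Three well-separated inversions on a 200 kb circle, deep coverage."""
    loci = (
        mi.InversionLocus("l1", 30_000, 55_000, 0.17, flank_repeat_len=12),
        mi.InversionLocus("l2", 90_000, 112_000, 0.18, flank_repeat_len=12),
        mi.InversionLocus("l3", 150_000, 171_000, 0.35, flank_repeat_len=12),
    )
    config = mi.SimConfig(
        genome_len=200_000, seed=41, loci=loci, physical_coverage=150,
        repeat_families=(), ece_len=0,
    )
    model, _ = mi.simulate_reference(config)
    pairs = mi.simulate_mate_pairs(model, config, with_truth=False)
    index = mi.build_index([model.reference], 25)
    aligned, _ = mi.map_pairs(index, pairs)
    return config, model, aligned


def test_three_loci_give_six_clusters_and_three_calls(three_locus_bundle):
    config, model, aligned = three_locus_bundle
    chrom = model.reference
    inverted = mi.collect_inverted_pairs(aligned, config.library, chrom)
    clusters = mi.cluster_breakpoints(inverted, config.library, 10, chrom)
    assert len(clusters) == 6

    pairings, orphans = pair_clusters_to_inversions(clusters, config.library)
    assert len(pairings) == 3 and orphans == []

    calls = mi.call_inversions(aligned, config.library, chrom)
    assert len(calls) == 3
    for call, locus in zip(calls, config.loci):
        # no cross-pairing: each call lands on its own locus
        assert abs(call.start - locus.start) <= config.library.insert_max
        assert abs(call.end - locus.end) <= config.library.insert_max
        sigma = np.sqrt(locus.frequency * (1 - locus.frequency) / call.support_total)
        assert abs(call.frequency - locus.frequency) <= 5 * sigma + 0.01


def test_orphan_cluster_produces_no_call():
    lone = DiscordantCluster(
        seq_id="chr", side=START_SIDE, members=["p1"] * 15,
        lo_min=10_000, lo_max=10_200, hi_min=30_000, hi_max=30_200,
        mean_separation=20_000.0, rotation=0, seq_len=100_000,
    )
    pairings, orphans = pair_clusters_to_inversions([lone], LIB)
    assert pairings == [] and orphans == [lone]


def test_min_frequency_and_min_support_thresholds(inversion_sim):
    chrom = inversion_sim.model.reference
    pairs = _chrom_pairs(inversion_sim)
    lib = inversion_sim.config.library
    assert mi.call_inversions(pairs, lib, chrom, min_frequency=0.5) == []
    assert mi.call_inversions(pairs, lib, chrom, min_support=10**6) == []


def test_call_recovers_locus_and_windows_cover_junctions(inversion_sim):
    chrom = inversion_sim.model.reference
    locus = inversion_sim.config.loci[0]
    calls = mi.call_inversions(
        _chrom_pairs(inversion_sim), inversion_sim.config.library, chrom
    )
    assert len(calls) == 1
    call = calls[0]
    r = locus.flank_repeat_len
    # observable sequence-change junctions sit just inside the flank repeats
    j_left, j_right = locus.start + r, locus.end - r
    assert call.start_window[0] <= j_left <= call.start_window[1]
    assert call.end_window[0] <= j_right <= call.end_window[1]
    assert abs(call.start - locus.start) <= inversion_sim.config.library.insert_max
    assert abs(call.end - locus.end) <= inversion_sim.config.library.insert_max
    assert abs(call.frequency - locus.frequency) <= 0.05
    assert call.ci_low <= call.frequency <= call.ci_high


def test_reverse_complement_symmetry(inversion_sim):
    """Calling on the reverse-complemented chromosome mirrors coordinates
    and preserves frequencies."""
    chrom = inversion_sim.model.reference
    L = len(chrom)
    lib = inversion_sim.config.library
    flipped = SequenceRecord(chrom.id, revcomp(chrom.seq), circular=True)
    index = mi.build_index([flipped], lib.read_length)
    aligned, _ = mi.map_pairs(index, inversion_sim.pairs)
    fwd = mi.call_inversions(_chrom_pairs(inversion_sim), lib, chrom)
    rev = mi.call_inversions(aligned, lib, flipped)
    assert len(fwd) == len(rev) == 1
    f, r = fwd[0], rev[0]
    assert (r.start, r.end) == (L - f.end + 1, L - f.start + 1)
    assert r.frequency == pytest.approx(f.frequency, abs=1e-12)


def test_flank_repeat_longer_than_insert_hides_the_locus():
    """An inverted repeat longer than the maximum insert leaves no uniquely
    mapping breakpoint evidence: no pair can bracket it."""
    loci = (mi.InversionLocus("hidden", 20_000, 60_000, 0.5, flank_repeat_len=4_000),)
    config = mi.SimConfig(
        genome_len=100_000, seed=43, loci=loci, physical_coverage=100,
        repeat_families=(), ece_len=0,
    )
    model, _ = mi.simulate_reference(config)
    pairs = mi.simulate_mate_pairs(model, config, with_truth=False)
    index = mi.build_index([model.reference], 25)
    aligned, _ = mi.map_pairs(index, pairs)
    inverted = mi.collect_inverted_pairs(aligned, config.library, model.reference)
    assert inverted == []
    assert mi.call_inversions(aligned, config.library, model.reference) == []


def test_origin_wrapping_inversion_is_called():
    """A locus realised across the origin clusters and calls correctly."""
    loci = (mi.InversionLocus("wrap", 5_000, 30_000, 0.4, flank_repeat_len=12),)
    config = mi.SimConfig(
        genome_len=100_000, seed=44, loci=loci, physical_coverage=80,
        repeat_families=(), ece_len=0,
    )
    model, _ = mi.simulate_reference(config)
    # rotate the chromosome so the locus straddles the new origin
    shift = 20_000  # old coordinate x -> x - shift (locus spans 85001..10000)
    rotated = SequenceRecord(
        "chr", model.reference.seq[shift:] + model.reference.seq[:shift], circular=True
    )
    pairs = mi.simulate_mate_pairs(model, config, with_truth=False)
    index = mi.build_index([rotated], 25)
    aligned, _ = mi.map_pairs(index, pairs)
    calls = mi.call_inversions(aligned, config.library, rotated)
    assert len(calls) == 1
    call = calls[0]
    assert call.interval.wraps
    assert abs(call.start - 85_000) <= config.library.insert_max
    assert abs(call.end - 10_000) <= config.library.insert_max


@pytest.mark.parametrize(
    "inv,conc,expected",
    [(17, 83, 0.17), (0, 100, 0.0), (35, 65, 0.35)],
)
def test_frequency_point_estimates(inv, conc, expected):
    freq, lo, hi = mi.estimate_inversion_frequency(inv, conc)
    assert freq == pytest.approx(expected)
    assert 0.0 <= lo <= freq <= hi <= 1.0
    if inv == 0:
        assert lo == 0.0


def test_wilson_interval_against_closed_form():
    """The reported interval matches an independent evaluation of the Wilson
    score formula."""
    z = 1.959963984540054  # 97.5% normal quantile
    for inv, conc in [(35, 65), (17, 83), (3, 197), (120, 40)]:
        n = inv + conc
        p = inv / n
        denom = 1 + z**2 / n
        centre = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        freq, lo, hi = mi.estimate_inversion_frequency(inv, conc)
        assert lo == pytest.approx(centre - half, abs=1e-9)
        assert hi == pytest.approx(centre + half, abs=1e-9)
    # the canonical small-sample check: 35/100 gives roughly (0.26, 0.45)
    _, lo, hi = mi.estimate_inversion_frequency(35, 65)
    assert lo == pytest.approx(0.262, abs=0.01)
    assert hi == pytest.approx(0.450, abs=0.01)


def test_zero_spanning_pairs_is_an_error():
    with pytest.raises(FrequencyUndefinedError):
        mi.estimate_inversion_frequency(0, 0)


@given(st.integers(0, 500), st.integers(0, 500))
@settings(max_examples=200, derandomize=True)
def test_frequency_estimate_properties(inv, conc):
    if inv + conc == 0:
        return
    freq, lo, hi = mi.estimate_inversion_frequency(inv, conc)
    assert freq == pytest.approx(inv / (inv + conc))
    assert 0.0 <= lo <= freq <= hi <= 1.0
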