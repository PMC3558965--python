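"""Shared simulated datasets (built once per session; everything is seeded)."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import mateinv as mi


@dataclass
class SimBundle:
    """One simulated dataset mapped back to its own reference."""

    config: mi.SimConfig
    model: mi.PopulationModel
    pairs: list
    index: mi.KmerIndex
    aligned: list
    map_counts: dict


def _run_sim(config: mi.SimConfig) -> SimBundle:
    model, _ = mi.simulate_reference(config)
    pairs = mi.simulate_mate_pairs(model, config)
    targets = [model.reference] + ([model.ece] if model.ece else [])
    index = mi.build_index(targets, config.library.read_length)
    aligned, counts = mi.map_pairs(index, pairs)
    return SimBundle(config, model, pairs, index, aligned, counts)


@pytest.fixture(scope="session")
def inversion_sim() -> SimBundle:
    """100 kb circular chromosome, one 25 kb inversion at frequency 0.35.

    Short (12 bp) flanking inverted repeats, default interspersed repeat
    families, no extra-chromosomal element; ~80x physical coverage.
    """
    loci = (mi.InversionLocus("invA", 40_000, 65_000, 0.35, flank_repeat_len=12),)
    config = mi.SimConfig(
        genome_len=100_000, seed=3, loci=loci, physical_coverage=80,
        n_contigs=5, ece_len=0,
    )
    return _run_sim(config)


@pytest.fixture(scope="session")
def clonal_sim() -> SimBundle:
    """Same design with no inversion loci: the clonal negative control."""
    config = mi.SimConfig(
        genome_len=100_000, seed=5, loci=(), physical_coverage=60,
        n_contigs=5, ece_len=0,
    )
    return _run_sim(config)


@pytest.fixture(scope="session")
def scaffold_sim():
    """20 contigs from a 300 kb circle at 10x physical coverage, mapped to contigs."""
    config = mi.SimConfig(
        genome_len=300_000, seed=2, loci=(), physical_coverage=10,
        n_contigs=20, ece_len=0,
    )
    ds = mi.simulate_dataset(config)
    index = mi.build_index(ds.contigs, config.library.read_length)
    aligned, counts = mi.map_pairs(index, ds.pairs)
    return ds, aligned, counts
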