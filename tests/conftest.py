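"""Shared fixtures: small deterministic simulations reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from dsbskew.simulate import (
    FactorProfile,
    SimulationConfig,
    fragments_to_records,
    simulate_fragments,
    simulate_genome,
)
from dsbskew.tracks import compute_coverage


@pytest.fixture(scope="session")
def small_sim():
    """20k fragments, two cuts, defaults: general-purpose round-trip fixture."""
    cfg = SimulationConfig(seed=101, n_fragments=20_000)
    genome, sites = simulate_genome(cfg)
    fragments = simulate_fragments(cfg, genome, sites)
    return cfg, genome, sites, fragments


def skew_sim(seed: int, n_fragments: int = 100_000, resected: float = 1.0):
    """Symmetric-resection simulation with the break footprint disabled.

    The resection skew is read from the excess of 3'-retained-strand
    fragments; a break-centered binding footprint adds signal but not
    strand information, so resection-extent measurements switch it off.
    """
    cfg = SimulationConfig(
        seed=seed,
        genome_length=200_000,
        dsb_sites=[50_000, 150_000],
        cut_efficiency=0.8,
        resected_fraction=resected,
        resection_mean=1_500,
        rejoined_fraction=0.0,
        n_fragments=n_fragments,
        factor_profile=FactorProfile(dsb_induction_fold=1.0),
    )
    genome, sites = simulate_genome(cfg)
    fragments = simulate_fragments(cfg, genome, sites)
    records = fragments_to_records(fragments, cfg)
    chrom_lengths = {r.name: len(r.seq) for r in genome}
    tracks = compute_coverage(records, chrom_lengths, bin_size=50)
    return cfg, sites, fragments, records, tracks


@pytest.fixture(scope="session")
def resection_sim():
    """q=0.8, r=1, L=1500, 100k fragments: the skew sign/antisymmetry fixture."""
    return skew_sim(seed=11)


@pytest.fixture(scope="session")
def resection_sims_3seeds(resection_sim):
    """Three independent seeds of the symmetric-resection simulation."""
    return [resection_sim, skew_sim(seed=12), skew_sim(seed=13)]


@pytest.fixture(scope="session")
def null_sim():
    """Cutting without resection: skew carries only binomial strand noise."""
    cfg = SimulationConfig(
        seed=21,
        genome_length=200_000,
        dsb_sites=[50_000, 150_000],
        cut_efficiency=0.8,
        resected_fraction=0.0,
        rejoined_fraction=0.2,
        n_fragments=50_000,
    )
    genome, sites = simulate_genome(cfg)
    fragments = simulate_fragments(cfg, genome, sites)
    records = fragments_to_records(fragments, cfg)
    chrom_lengths = {r.name: len(r.seq) for r in genome}
    tracks = compute_coverage(records, chrom_lengths, bin_size=50)
    return cfg, sites, fragments, records, tracks


def random_fragment_records(rng: np.random.Generator, n: int, chrom_len: int = 100_000):
    """Plain random fragment records for brute-force classification oracles."""
    from dsbskew.tracks import FragmentRecord

    starts = rng.integers(0, chrom_len - 700, size=n)
    lengths = rng.integers(100, 700, size=n)
    strands = rng.choice(["+", "-"], size=n)
    return [
        FragmentRecord(
            chrom="chr1",
            start=int(s),
            end=int(s + l),
            flags=(99, 147) if st == "+" else (83, 163),
            template_strand=str(st),
        )
        for s, l, st in zip(starts, lengths, strands)
    ]
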