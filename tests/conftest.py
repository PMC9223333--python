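"""Shared fixtures.

Simulated datasets are session-scoped because coalescent simulation dominates
test runtime; sizes are chosen so the whole suite stays desk-scale while
keeping enough genome for stable decay profiles (see docs/methods.md).
"""
from __future__ import annotations

import numpy as np
import pytest

import ascdecay as ad


def make_dataset(
    genotypes,
    pos_morgans,
    chroms=None,
    populations=None,
    pos_bp=None,
    ploidy_mode="diploid",
):
    """Small hand-built GenotypeDataset for unit tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    pos = np.asarray(pos_morgans, dtype=np.float64)
    chroms = np.asarray(chroms if chroms is not None else ["1"] * n, dtype=object)
    pops = list(populations) if populations is not None else ["A"] * m
    return ad.GenotypeDataset(
        snp_ids=np.array([f"rs{i}" for i in range(n)], dtype=object),
        chromosomes=chroms,
        genetic_pos=pos,
        physical_pos=(
            np.asarray(pos_bp, dtype=np.int64)
            if pos_bp is not None
            else np.rint(pos * 1e8).astype(np.int64)
        ),
        ref_alleles=np.full(n, "A", dtype=object),
        alt_alleles=np.full(n, "G", dtype=object),
        individual_ids=[f"ind{k}" for k in range(m)],
        populations=pops,
        sexes=["U"] * m,
        genotypes=g,
        ploidy_mode=ploidy_mode,
    )


@pytest.fixture(scope="session")
def tiny_founder():
    """3 x 5 Mb founder-model dataset (T_f=10, N_f=100, D_f=20), filtered."""
    cfg = ad.DemographyConfig(n_chromosomes=3, chromosome_length_bp=5e6, seed=3)
    ds = ad.simulate_founder_model(cfg)
    return ad.filter_sites(ds, "A", ds.members_of("O"))


@pytest.fixture(scope="session")
def founder_2x50(request):
    """2 x 50 Mb founder-model dataset for the engine-equivalence check."""
    cfg = ad.DemographyConfig(n_chromosomes=2, chromosome_length_bp=5e7, seed=7)
    ds = ad.simulate_founder_model(cfg)
    return ad.filter_sites(ds, "A", ds.members_of("O"))


@pytest.fixture(scope="session")
def founder_mid():
    """6 x 20 Mb founder-model dataset (truth T_f=10, D_f=20, I_f=0.10)."""
    cfg = ad.DemographyConfig(n_chromosomes=6, chromosome_length_bp=2e7, seed=33)
    ds = ad.simulate_founder_model(cfg)
    return ad.filter_sites(ds, "A", ds.members_of("O"))
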