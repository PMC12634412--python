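"""Shared fixtures: small simulated communities reused across test modules.

The study conditions are fixed here once: a clean (error-free,
single-haplotype) community at 30x for the closure checks, and a deep (200x)
strain-diverse community with planted islands for the diversity, enrichment
and graph-structure checks.  Session scope keeps the suite fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from srlens.pipeline import run_simulated_pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from srlens.sim import (
    CommunityConfig,
    simulate_community,
    simulate_reads,
    suggested_min_count,
    window_truth,
)

CLEAN_CFG = dict(
    n_genomes=2,
    genome_length=20_000,
    abundance_lognormal=(0.0, 0.0),
    islands_per_genome=0,
    island_snp_density=0.0,
    background_snp_density=0.0,
    minor_haplotype_freq=0.3,  # irrelevant: haplotypes identical
    error_rate=0.0,
    total_bases=30 * 40_000,
    seed=101,
)

# 200x community with diversity islands: island windows must outnumber 50
# per group (2 islands x 6 kb per genome -> >= 10 fully-contained windows each)
DIVERSE_CFG = dict(
    n_genomes=3,
    genome_length=30_000,
    abundance_lognormal=(0.0, 0.0),
    islands_per_genome=2,
    island_length=6_000,
    island_snp_density=0.01,
    background_snp_density=0.0005,
    minor_haplotype_freq=0.3,
    error_rate=0.001,
    total_bases=200 * 90_000,
    seed=202,
)


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("clean_run")
    cfg = CommunityConfig(**CLEAN_CFG)
    result = run_simulated_pipeline(cfg, outdir, assembler_ks=(21, 31), toy_min_count=2)
    return cfg, result, outdir


@pytest.fixture(scope="session")
def diverse_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("diverse_run")
    cfg = CommunityConfig(**DIVERSE_CFG)
    result = run_simulated_pipeline(
        cfg, outdir, assembler_ks=(21, 31), toy_min_count=suggested_min_count(200)
    )
    return cfg, result, outdir


@pytest.fixture(scope="session")
def diverse_truth(diverse_run):
    cfg, result, outdir = diverse_run
    community = simulate_community(cfg)
    reads = simulate_reads(community)
    truth = window_truth(community, reads)
    return community, reads, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
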