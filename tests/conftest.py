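"""Shared fixtures: tiny gene models and a fast pipeline configuration."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from haploscent.genome import GeneModel
from haploscent.synthetic_data import SimulationConfig


def make_gene(gene_id="g1", chrom="chr1", strand="+", exons=None, cds=None,
              rank=0) -> GeneModel:
    exons = exons or [(1001, 1300)]
    cds = cds if cds is not None else exons
    start = min(s for s, _ in exons)
    end = max(e for _, e in exons)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, start=start,
                     end=end, exons=exons, cds=cds, rank=rank)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def mini_sim_config(seed: int = 5) -> SimulationConfig:
    """A fast, small-scale simulation used by non-acceptance tests."""
    return SimulationConfig(
        n_chromosomes=1,
        chrom_length=150_000,
        n_genes=40,
        sv_count=10,
        mean_depth=120.0,
        pop_sites_per_chrom=1_500,
        n_samples_per_pop=10,
        introgressed_interval=("chr1", 30_000, 90_000),
        divergent_interval=("chr1", 90_000, 140_000),
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_bundle():
    """One shared small end-to-end simulation (no files written)."""
    from haploscent.synthetic_data import simulate_all
    return simulate_all(mini_sim_config())
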