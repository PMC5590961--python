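"""Shared fixtures: seeded simulations reused across test modules."""

import numpy as np
import pytest

from paleoks.distribution import build_paranome_distribution
from paleoks.seqio import CodingSequence, PipelineConfig
from paleoks.simulate import SimulationConfig, evolve_to_ks, random_cds, simulate_paranome


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def paranome_run(pipeline_config):
    """A seeded end-to-end paranome analysis on a planted-WGD transcriptome,
    shared by the distribution and acceptance tests."""
    cfg = SimulationConfig(n_base_genes=60, gene_len_codons=200, wgd_ks=0.8,
                           wgd_retention=0.6, ssd_rate=0.3, seed=11)
    genes, truth = simulate_paranome(cfg)
    dist, details = build_paranome_distribution(genes, pipeline_config,
                                                return_details=True)
    return {"config": cfg, "genes": genes, "truth": truth,
            "distribution": dist, "details": details}


def grow_resolved_family(n: int, rng: np.random.Generator,
                         length_codons: int = 300,
                         ages=None) -> list[CodingSequence]:
    """A family of n genes from a caterpillar genealogy with well-separated
    duplication ages, so its tree is fully resolvable.

    Gene i duplicates off the backbone at age ``ages[i-1]`` (descending);
    divergence is split evenly across the two branches, so the pairwise Ks
    between genes on opposite sides of a node equals that node's age.
    """
    if ages is None:
        ages = [0.3 + 0.25 * k for k in range(n - 1)][::-1]  # oldest first
    assert len(ages) == n - 1 and sorted(ages, reverse=True) == list(ages)
    root = random_cds(length_codons, rng)
    # Heights (half path Ks) of the caterpillar's internal nodes.
    heights = [a / 2.0 for a in ages]
    genes: list[CodingSequence] = []
    backbone = root
    prev_h = heights[0]
    # The branch from each node down to the split-off leaf spans the node
    # height; the backbone continues to the next (younger) node.
    for k, h in enumerate(heights):
        drop = prev_h - h if k else 0.0
        backbone = evolve_to_ks(backbone, drop, rng=rng)
        leaf = evolve_to_ks(backbone, h, rng=rng)
        genes.append(CodingSequence.from_nt(f"g{k}", leaf.nt))
        prev_h = h
    tail = evolve_to_ks(backbone, heights[-1], rng=rng)
    genes.append(CodingSequence.from_nt(f"g{n - 1}", tail.nt))
    return genes
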