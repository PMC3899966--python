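"""Shared fixtures: simulated clades and toy genome builders.

Session-scoped fixtures amortize the cost of simulation and all-vs-all
BBH search across the suite.
"""

from __future__ import annotations

import itertools

import pytest

from panforge.io import GeneRecord, GenomeRecord
from panforge.orthology import best_hits, build_families
from panforge.simulate import SimConfig, simulate_clade


def make_genome(gid: str, proteins: dict[str, str],
                annotations: dict[str, str] | None = None) -> GenomeRecord:
    """A minimal in-memory genome: one replicon, genes laid end to end."""
    annotations = annotations or {}
    genes = []
    pos = 1
    for tag, prot in proteins.items():
        length = 3 * len(prot) + 3
        genes.append(GeneRecord(tag, "chr", pos, pos + length - 1, "+",
                                "gene", prot, annotations.get(tag, "")))
        pos += length + 50
    genome = GenomeRecord(genome_id=gid, replicons={"chr": "A" * pos},
                          genes=genes)
    genome.sort_genes()
    genome.validate()
    return genome


def all_pair_edges(genomes: dict[str, GenomeRecord], **kwargs):
    return {frozenset(p): best_hits(genomes[p[0]], genomes[p[1]], **kwargs)
            for p in itertools.combinations(sorted(genomes), 2)}


@pytest.fixture(scope="session")
def default_truth():
    """Five-genome clade at default study conditions (~300 families)."""
    return simulate_clade(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_families(default_truth):
    edges = all_pair_edges(default_truth.genomes)
    return build_families(edges, default_truth.genomes)


@pytest.fixture(scope="session")
def island_truth():
    """Clade built for island recovery: core + islands only, no loss, so
    every planted block is the only source of absence."""
    cfg = SimConfig(seed=2, n_genomes=5, n_core_families=120,
                    n_accessory_families=0, loss_rate=0.0, gain_rate=0.0,
                    n_islands=3, island_gene_counts=(8, 8, 10),
                    gene_len_mean=220)
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def island_families(island_truth):
    edges = all_pair_edges(island_truth.genomes)
    return build_families(edges, island_truth.genomes)
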