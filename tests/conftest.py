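import numpy as np
import pytest

from circasym.genome_io import CircularGenome, GeneRecord, GenomeSet
from circasym.synthetic_data import SimulationConfig, generate


def make_genome_set(entries):
    """entries: list of (genome_id, sequence, topology, genes) where genes are
    (gene_id, start, end, strand[, wraps]) tuples."""
    gs = GenomeSet()
    for gid, seq, topo, genes in entries:
        gs.add_genome(CircularGenome(id=gid, sequence=seq, topology=topo))
        for g in genes:
            wraps = g[4] if len(g) > 4 else False
            gs.add_gene(
                GeneRecord(
                    gene_id=g[0], genome_id=gid, start=g[1], end=g[2], strand=g[3],
                    wraps_origin=wraps,
                )
            )
    return gs


def random_sequence(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests: 6 genomes in 3
    clades, 100 genes, 72 kb genomes; all fractions as in the default."""
    return SimulationConfig(
        n_clades=3,
        strains_per_clade=(2, 2, 2),
        genome_length=72_000,
        n_genes=100,
        rearrangements_per_clade=2,
        rearrangement_block=(3, 8),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size simulated genome set shared by the slower tests."""
    return generate(SimulationConfig(seed=7))
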