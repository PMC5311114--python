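import numpy as np
import pytest

from gatareg import simulate as sim


@pytest.fixture(scope="session")
def small_fixture():
    """Shared 60-gene planted-motif fixture with expression table."""
    genome, genes, truth = sim.gen_genome_and_genes(60, seed=11)
    sim.plant_motifs(genome, genes, truth, sim.DEFAULT_MOTIFS[0], seed=11,
                     offset_range=(-200, 0))
    sim.plant_motifs(genome, genes, truth, sim.DEFAULT_MOTIFS[1], seed=11,
                     offset_range=(-2000, 0))
    expr = sim.gen_expression(truth, seed=11)
    return genome, genes, truth, expr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
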