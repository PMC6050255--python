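import numpy as np
import pandas as pd
import pytest

from stressmeth import simulate as sim


@pytest.fixture(scope="session")
def small_dataset():
    """A compact default-style dataset shared by read-only tests."""
    cfg = sim.SimulationConfig(
        n_chromosomes=2,
        genes_per_chromosome=15,
        n_probes=600,
        methylation=sim.MethylationEffectConfig(n_clusters=4, cluster_width=10),
    )
    return sim.simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def genome():
    return sim.generate_genome(3, 10, seed=3)


@pytest.fixture()
def toy_genome():
    """One + strand gene on one chromosome with one CpG island, hand-placed
    so structure windows can be asserted exactly."""
    from stressmeth.datatypes import GenomeAnnotation

    genes = pd.DataFrame(
        [("GX", "chr1", "+", 5000, 9000)],
        columns=["gene_id", "chrom", "strand", "start", "end"],
    )
    islands = pd.DataFrame([("chr1", 6000, 6400)], columns=["chrom", "start", "end"])
    return GenomeAnnotation([("chr1", 20000)], genes, islands)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
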