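import numpy as np
import pandas as pd
import pytest

import swarmscan as sw
from swarmscan.synth import GenotypeMatrix


def make_genotype_matrix(dosage, sites=None, populations=None, genome=None):
    """Wrap a plain dosage array in a GenotypeMatrix with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if sites is None:
        sites = pd.DataFrame({"chrom": "2L", "pos": np.arange(1, m + 1), "ref": "A", "alt": "T"})
    if populations is None:
        populations = ["A"] * n
    samples = pd.DataFrame(
        {
            "individual_id": [f"s{i}" for i in range(n)],
            "population": populations,
            "generation": "F5",
            "sex": "F",
        }
    )
    kwargs = {} if genome is None else {"genome": genome}
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosage=dosage,
        het_count=np.zeros_like(dosage, dtype=np.uint8),
        unknown=np.zeros_like(dosage, dtype=bool),
        known_part=np.where(dosage >= 0, dosage, 0).astype(np.uint8),
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_panel():
    return sw.synth.simulate_founders(8, n_collections=4, sites=400, het_rate=0.02, seed=11)


@pytest.fixture(scope="session")
def small_swarm(small_panel):
    return sw.synth.simulate_swarm(
        small_panel, generations=5, census=200, n_sample=60, seed=7, population="A"
    )


@pytest.fixture(scope="session")
def swarm_genotypes(small_panel, small_swarm):
    return sw.synth.derive_genotypes(small_swarm, small_panel)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Both swarms, genotypes and phenotypes, sized for mixed-model tests."""
    panel = sw.synth.simulate_founders(10, n_collections=5, sites=600, het_rate=0.01, seed=21)
    mosaics = []
    for pop, seed in (("A", 22), ("B", 23)):
        mosaics += sw.synth.simulate_swarm(
            panel, generations=5, census=260, n_sample=90, seed=seed, population=pop
        )
    gm = sw.synth.derive_genotypes(mosaics, panel)
    pheno = sw.synth.simulate_phenotypes(gm, seed=24)
    return panel, mosaics, gm, pheno
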