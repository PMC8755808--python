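import numpy as np
import pandas as pd
import pytest

from skyisland import (DemographicModel, GenotypeMatrix, SimulationConfig,
                       simulate_dataset)


@pytest.fixture(scope="session")
def divergent_pair():
    """Two populations split 20*(2Ne) generations ago, no migration."""
    model = DemographicModel.two_population(
        ne1=10000, ne2=10000, ne_anc=10000, t_div=20 * 2 * 10000,
        labels=("A", "B"))
    cfg = SimulationConfig(model=model, samples_per_pop=(10, 10), n_sites=5000,
                           seed=42)
    geno, truth = simulate_dataset(cfg)
    return geno, truth


@pytest.fixture(scope="session")
def panmictic_halfsib():
    """One panmictic population, 50k SNPs, one planted half-sib pair."""
    model = DemographicModel.single_population(20000, label="P")
    cfg = SimulationConfig(model=model, samples_per_pop=(10,), n_sites=50_000,
                           callable_length=10 ** 7, seed=7,
                           halfsib_pairs=(("P", "hs1"),))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def panmictic_large():
    """One panmictic population of 20 diploids, 50k SNPs, no relatives."""
    model = DemographicModel.single_population(20000, label="P")
    cfg = SimulationConfig(model=model, samples_per_pop=(20,), n_sites=50_000,
                           callable_length=10 ** 7, seed=17)
    geno, _ = simulate_dataset(cfg)
    return geno


def make_matrix(genotypes, populations=None, qual=60.0, depth=30,
                pos=None, chrom="chr1"):
    """Hand-build a GenotypeMatrix from a (sites x samples) array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if populations is None:
        populations = ["pop1"] * n_samples
    samples = pd.DataFrame({
        "sample_id": [f"s{i:02d}" for i in range(n_samples)],
        "population": populations,
        "elevation_m": None, "species": None,
    })
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "T",
        "qual": qual if np.ndim(qual) else float(qual),
        "is_indel": False, "dist_indel": np.inf, "multiallelic": False,
    })
    d = np.full((n_sites, n_samples), depth, dtype=np.int32)
    return GenotypeMatrix(sites=sites, genotypes=g, samples=samples, depth=d)
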