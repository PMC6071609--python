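import numpy as np
import pandas as pd
import pytest

from halfsibgs import (
    GenotypeMatrix,
    PopulationConfig,
    TraitConfig,
    adjust_phenotypes,
    simulate_population,
    simulate_trait,
)


@pytest.fixture(scope="session")
def small_population():
    """20 half-sib families x 12 progeny, 1000 SNPs: the workhorse fixture."""
    config = PopulationConfig(n_families=20, progeny_per_family=12,
                              n_snps=1000, seed=11)
    return simulate_population(config)


@pytest.fixture(scope="session")
def small_trait(small_population):
    genotypes, _ = small_population
    trait = simulate_trait(
        genotypes, TraitConfig(heritability=0.5, n_qtl=100, seed=7)
    )
    return adjust_phenotypes(trait)


@pytest.fixture()
def hwe_unrelated():
    """200 unrelated individuals at 2000 HWE SNPs (no family structure)."""
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.5, 2000)
    dosage = (rng.binomial(2, p, size=(200, 2000)) - 1).astype(np.int8)
    meta = pd.DataFrame(
        {"chrom": np.ones(2000, dtype=int),
         "pos": 1 + 1000 * np.arange(2000),
         "freq": p}
    )
    g = GenotypeMatrix(dosage=dosage, snp_meta=meta,
                       sample_ids=[f"ind{i}" for i in range(200)])
    return g.recompute_freq()


def toy_genotypes(dosage, chrom=None, pos=None):
    """Helper: wrap a raw dosage array with minimal metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    meta = pd.DataFrame(
        {
            "chrom": np.ones(m, dtype=int) if chrom is None else chrom,
            "pos": (1 + 100 * np.arange(m)) if pos is None else pos,
            "freq": 0.5,
        }
    )
    g = GenotypeMatrix(dosage=dosage, snp_meta=meta,
                       sample_ids=[f"s{i}" for i in range(n)])
    return g.recompute_freq()
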