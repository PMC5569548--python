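import numpy as np
import pandas as pd
import pytest

from gqlscan.genotypes import GenotypeDataset
from gqlscan.pedigree import Pedigree
from gqlscan.simulate import SimConfig, simulate_cohort


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([("1", None, None), ("2", None, None),
                                  ("3", "1", "2")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_dataset(calls, chrom=None, pos=None, animal_ids=None,
                 snp_ids=None) -> GenotypeDataset:
    """Small literal-matrix dataset builder for unit tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n_animals, n_snps = calls.shape
    snps = pd.DataFrame({
        "snp_id": snp_ids or [f"snp{j}" for j in range(n_snps)],
        "chrom": chrom or ["1"] * n_snps,
        "pos": pos or [1000 * (j + 1) for j in range(n_snps)],
        "allele1": "A",
        "allele2": "B",
    })
    ids = animal_ids or [f"a{i}" for i in range(n_animals)]
    return GenotypeDataset(ids, snps, calls)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic mid-sized cohort shared across test modules."""
    cfg = SimConfig(seed=424242, n_chromosomes=3, snps_per_chrom=60,
                    sires_per_generation=10, dams_per_generation=70,
                    offspring_per_generation=80)
    return simulate_cohort(cfg)
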