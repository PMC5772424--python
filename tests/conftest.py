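import numpy as np
import pytest

from borneoabc.datasets import GenotypeDataset
from borneoabc.demography import (DemographyRealization, Epoch,
                                  default_model_specs)


@pytest.fixture(scope="session")
def specs():
    return default_model_specs()


def constant_demography(n_diploid: float) -> DemographyRealization:
    return DemographyRealization("ID", (Epoch(0.0, n_diploid, 0.0, 1),),
                                 ("deme0",))


@pytest.fixture
def const_demog():
    return constant_demography


def random_genotypes(rng: np.random.Generator, n_ind: int, n_loci: int,
                     pops, spread: int = 4, missing: float = 0.0
                     ) -> GenotypeDataset:
    """Random small genotype dataset; every locus keeps >=2 typed copies
    per group (the first individual of each group stays fully typed)."""
    alleles = 200 + rng.integers(-spread, spread + 1,
                                 size=(n_ind, n_loci, 2)).astype(np.int32)
    if missing > 0.0:
        mask = rng.random(alleles.shape) < missing
        alleles[mask] = -1
        labels = np.asarray(pops)
        for p in dict.fromkeys(pops):
            first = int(np.flatnonzero(labels == p)[0])
            alleles[first] = 200 + rng.integers(
                -spread, spread + 1, size=(n_loci, 2))
    return GenotypeDataset(alleles, np.asarray(pops),
                           tuple(f"loc{j}" for j in range(n_loci)))


@pytest.fixture
def genotype_factory():
    return random_genotypes
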