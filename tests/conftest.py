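import numpy as np
import pytest

from patchkin.genotypes import GenotypeMatrix


def make_genotypes(dosage, stage=None, alleles=("A", "G")) -> GenotypeMatrix:
    """GenotypeMatrix from a dosage array with auto-generated ids."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, l = dosage.shape
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        locus_ids=[f"l{k}" for k in range(l)],
        alleles=np.array([list(alleles)] * l, dtype=object),
        dosage=dosage,
        stage=stage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config synthetic dataset shared across tests."""
    from patchkin.simulate import SimulationConfig, generate

    return generate(SimulationConfig(seed=11))
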