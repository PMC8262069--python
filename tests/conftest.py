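import numpy as np
import pytest

from epiblup import simulate_genotypes, simulate_effects, simulate_phenotypes
from epiblup.genotypes import GenotypeMatrix
from epiblup.kernels import build_kernel_set


@pytest.fixture
def toy_g():
    """Hand-made 5 animals x 4 SNPs."""
    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
            [1, 2, 1, 0],
            [0, 1, 1, 1],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(
        animal_ids=[f"a{i}" for i in range(5)],
        snp_ids=[f"s{j}" for j in range(4)],
        dosages=dosages,
        positions=[("1", 100), ("1", 200), ("2", 50), ("2", 150)],
    )


@pytest.fixture(scope="session")
def halfsib_g():
    """20 half-sib families x 25 offspring, ~2000 SNPs (shared, read-only)."""
    return simulate_genotypes(20, 25, 2000, seed=1)


@pytest.fixture(scope="session")
def halfsib_kernels(halfsib_g):
    return build_kernel_set(halfsib_g, which=("A", "D", "AA"))


@pytest.fixture(scope="session")
def simulated_dataset():
    """Small full dataset: genotypes, true effects, phenotypes, kernels."""
    g = simulate_genotypes(25, 20, 1200, seed=7)
    eff = simulate_effects(
        g, {"A": 0.4, "D": 0.1, "AA": 0.1}, n_epistatic_pairs=200, seed=8
    )
    pheno = simulate_phenotypes(
        g,
        eff,
        factor_spec={"sex": 2, "farm": 6},
        covariate_spec={"age_months": 0.2},
        residual_fraction=0.4,
        seed=9,
    )
    kernels = build_kernel_set(g, which=("A", "D", "AA", "AD", "DD"))
    return {"g": g, "effects": eff, "pheno": pheno, "kernels": kernels}
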