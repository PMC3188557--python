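import numpy as np
import pytest

from wingfa import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Compact two-genotype, two-sex bilateral design with replicates."""
    params = sim.default_study_params(
        seed=42, n_per_cell=12, genotypes=("control", "GOF")
    )
    dataset, truth = sim.simulate_landmark_dataset(params)
    return dataset, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    from wingfa import procrustes as pro

    dataset, _ = small_dataset
    fit = pro.gpa(dataset)
    space = pro.shape_pca(fit)
    return fit, space
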