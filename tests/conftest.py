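import numpy as np
import pytest

from phenobalance import GeneratorConfig, default_catalog, generate_experiment


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def noiseless_config():
    """Every stochastic term switched off: outputs are exact functions of the design."""
    return GeneratorConfig(
        tree_cv=0.0,
        batch_cv=0.0,
        measurement_cv=0.0,
        lambda_sd=0.0,
        assimilation_sd=0.0,
        consumption_cv=0.0,
    )


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced experiment (10 caterpillars/host, 3 trees/species) for fast tests."""
    config = GeneratorConfig(
        trees_per_species={"acer": 3, "carpinus": 3, "quercus": 3},
        phase1_counts={"acer": 10, "carpinus": 10, "quercus": 10},
        phase2_counts={
            (p1, p2): 3 for p1 in ("acer", "carpinus", "quercus")
            for p2 in ("acer", "carpinus", "quercus")
        },
    )
    return generate_experiment(config, seed=0)


@pytest.fixture(scope="session")
def default_experiment():
    """The full study-design experiment (Table-style counts), one shared instance."""
    return generate_experiment(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
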