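import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import shellkin as sk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> sk.SimulationConfig:
    return sk.SimulationConfig(rng_seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One study-scale simulated dataset shared across tests."""
    geno, dp, meta, profiles, ped = sk.simulate_dataset(default_config)
    return {
        "genotypes": geno,
        "depth": dp,
        "metadata": meta,
        "profiles": profiles,
        "pedigree": ped,
    }


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    return sk.run_kinship_pipeline(
        default_dataset["genotypes"],
        default_dataset["metadata"],
        default_dataset["profiles"],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
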