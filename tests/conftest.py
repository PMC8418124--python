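import numpy as np
import pandas as pd
import pytest

from tmescore import SimulationConfig, generate_cohort, generate_reference


@pytest.fixture(autouse=True)
def _quiet_warnings(recwarn):
    # package warnings are informative, not failures
    yield


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A fast cohort: 120 samples, 8 types x 15 markers + 280 background."""
    return SimulationConfig(
        n_samples=120,
        markers_per_type=15,
        n_background_genes=280,
        reference_background_genes=40,
        n_planted_degs=40,
        seed=5,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def reference():
    return generate_reference(SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def expr_frame_factory():
    def make(values, genes=None, samples=None):
        values = np.asarray(values, float)
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        return pd.DataFrame(values, index=genes, columns=samples)

    return make
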