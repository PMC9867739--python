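import numpy as np
import pytest

from rcc_regulome.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle():
    """One simulated cohort at the default study conditions, shared across
    the suite (the generator is deterministic given the seed)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def diffpeak_output(bundle):
    from rcc_regulome import pipeline

    return pipeline.run_differential_peaks(bundle)


@pytest.fixture(scope="session")
def master_tf_output(bundle):
    from rcc_regulome import pipeline

    return pipeline.run_master_tf(bundle)


@pytest.fixture(scope="session")
def ai_output(bundle):
    from rcc_regulome import pipeline

    return pipeline.run_allelic_imbalance(bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
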