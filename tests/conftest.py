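import numpy as np
import pytest

from teafuse.pipeline import run_pipeline
from teafuse.simulate import simulate_dataset


@pytest.fixture(scope="session")
def dataset110():
    """One full 110-sample synthetic dataset (default study design)."""
    return simulate_dataset(0)


@pytest.fixture(scope="session")
def pipeline_result(dataset110):
    """One end-to-end run (all three regressors, all three feature sets)."""
    return run_pipeline(0, samples=dataset110)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
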