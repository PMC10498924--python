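import numpy as np
import pytest

from petrad import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient phantom cohort reused across read-only tests."""
    spec = synthdata.PhantomSpec(n_patients=6, grid_shape=(48, 48, 48), seed=11)
    records, truth = synthdata.generate_cohort(spec)
    return spec, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
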