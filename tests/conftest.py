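import numpy as np
import pytest
from hypothesis import settings

from mhdnet.synthetic import make_synthetic_record, preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_record():
    """A 16-s moderately corrupted 3-lead record with known peaks."""
    return make_synthetic_record(
        preset("3T-like", duration_s=16.0, seed=11), "subj0", "rec0"
    )


@pytest.fixture(scope="session")
def clean_record():
    """A 30-s artifact-free record for oracle-detector checks."""
    return make_synthetic_record(
        preset("clean", duration_s=30.0, seed=5), "subjC", "recC"
    )
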