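import numpy as np
import pytest
from hypothesis import settings

from pediclock import BetaMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_matrix(values, probe_prefix="cg", sample_prefix="S") -> BetaMatrix:
    """BetaMatrix from a 2-D array with generated probe/sample ids."""
    values = np.asarray(values, dtype=float)
    return BetaMatrix(
        [f"{probe_prefix}{i:05d}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j:04d}" for j in range(values.shape[1])],
        values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_beta(rng):
    """A complete 30 x 12 random beta matrix."""
    return make_matrix(rng.uniform(0.02, 0.98, size=(30, 12)))
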