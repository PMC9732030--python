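import numpy as np
import pytest

import smmira


@pytest.fixture(scope="session")
def planted():
    """A small planted-block dataset with clear signal, shared read-only."""
    spec = smmira.SyntheticSpec(n_sm=12, n_mirna=30, n_blocks=2,
                                p_in=0.4, p_out=0.02, seed=7)
    return smmira.generate(spec)


@pytest.fixture
def fast_cfg():
    """A run configuration small enough for per-test training."""
    return smmira.RunConfig(embed_dim=16, epochs=30, seed=11, cv_seed=5)


@pytest.fixture
def sim2x2():
    return smmira.SimilarityMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]), ["a", "b"])
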