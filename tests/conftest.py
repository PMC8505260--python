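import numpy as np
import pytest

from fmrpsb.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_config():
    """A quick desk-scale study: every stage runs in well under a second."""
    return SimConfig(
        seed=11,
        n_genes=600,
        target_fraction=0.1,
        n_cases=150,
        n_controls=200,
        n_trios=400,
        n_cnv_cases=200,
        n_cnv_controls=250,
        n_terms=20,
    )
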