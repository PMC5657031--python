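import numpy as np
import pytest

from consortium_lite.federation import ConsortiumState, split_pooled
from consortium_lite.synthdata import simulate_freesurfer_volumes


@pytest.fixture(scope="session")
def pooled_volumes():
    """One pooled FreeSurfer-style regression table (500 subjects)."""
    return simulate_freesurfer_volumes(500, seed=11)


@pytest.fixture
def volume_consortium(pooled_volumes):
    """The pooled table split over three sites."""
    sites = split_pooled(pooled_volumes, 3, seed=4)
    return ConsortiumState(sites=sites, master_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
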