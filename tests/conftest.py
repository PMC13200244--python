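import numpy as np
import pytest

from gctetra.dynamics import run_ensemble
from gctetra.model import SimConfig, gc_tetramer_model


@pytest.fixture(scope="session")
def nonalt_model():
    return gc_tetramer_model("nonalternating")


@pytest.fixture(scope="session")
def small_ensemble(nonalt_model):
    """A 12-trajectory nonalternating ensemble shared across tests."""
    config = SimConfig(ensemble_size=12, seed=42, max_time_fs=1500.0)
    manifest, records = run_ensemble(nonalt_model, config)
    return nonalt_model, config, manifest, records


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
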