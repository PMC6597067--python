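import numpy as np
import pytest

from neuroculture.meanfield import MeanFieldParams


@pytest.fixture
def energy_map_params():
    """Baseline parameters of the activity-energy map used throughout the
    equilibrium analysis (expensive cost regime r = 10)."""
    def make(z: float, r: float = 10.0, E_low: float = 2.0) -> MeanFieldParams:
        return MeanFieldParams(p=0.1, z=z, w=1.5, E_low=E_low, E_bar=4.0,
                               eps=0.05, r=r)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)
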