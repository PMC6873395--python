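import numpy as np
import pytest

from otusim import GroupParams, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """3 features, 2 groups x 3 replicates."""
    return SimulationParams(
        feature_ids=("a", "b", "c"),
        groups=(
            GroupParams(
                name="g1",
                mu=np.array([50.0, 30.0, 20.0]),
                phi=np.array([0.2, 0.2, 0.2]),
                lib_sizes=np.array([100, 120, 90]),
            ),
            GroupParams(
                name="g2",
                mu=np.array([20.0, 30.0, 50.0]),
                phi=np.array([0.1, 0.1, 0.1]),
                lib_sizes=np.array([110, 80, 100]),
            ),
        ),
    )
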