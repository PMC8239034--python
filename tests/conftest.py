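import numpy as np
import pytest

import igparasitoid as ig
from igparasitoid import reference as ref


@pytest.fixture(scope="session")
def selected_spec():
    """The generalized type III model with every mechanism switched on."""
    return ref.SELECTED_SPEC


@pytest.fixture(scope="session")
def reference_values():
    return dict(ref.POSTERIOR_MEANS)


@pytest.fixture(scope="session")
def reference_objects():
    fr, comp, inter = ig.build_params(ref.SELECTED_SPEC, ref.POSTERIOR_MEANS)
    return fr, comp, inter


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated paper-design experiment and its generating truth."""
    config = ig.SimulationConfig(spec=ref.SELECTED_SPEC, values=ref.POSTERIOR_MEANS, seed=11)
    table, truth = ig.simulate_experiment(config)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
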