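import numpy as np
import pytest

from ilvkit import GLVParams, generate_dataset, make_scenario


@pytest.fixture(scope="session")
def periodic():
    """Noise-free periodic 3-species dataset (dt=1, t=10) with its truth."""
    series, truth = generate_dataset(make_scenario("periodic"))
    return series, truth


@pytest.fixture(scope="session")
def ablation():
    """Noise-free periodic dataset on the long coarse grid (dt=1, t=20)."""
    series, truth = generate_dataset(make_scenario("fig2_ablation"))
    return series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def random_params(rng):
    """Mild random 3-species systems that integrate comfortably."""

    def draw():
        r = rng.uniform(-1, 1, 3)
        B = rng.uniform(-0.02, 0.02, (3, 3))
        np.fill_diagonal(B, 0.0)
        return GLVParams(r, B)

    return draw
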