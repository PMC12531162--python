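import numpy as np
import pytest

from wimpgrid import RatingScale, SynthSpec, example_grid, normalize_grid, random_grid


@pytest.fixture
def demo_raw():
    return example_grid()


@pytest.fixture
def demo(demo_raw):
    return normalize_grid(demo_raw)


@pytest.fixture
def grid_factory():
    """Normalized random grids: grid_factory(seed, n=..., density=..., scale=...)."""

    def make(seed, n=5, density=0.5, scale=RatingScale(1, 7)):
        return normalize_grid(random_grid(SynthSpec(n=n, scale=scale, density=density, seed=seed)))

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
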