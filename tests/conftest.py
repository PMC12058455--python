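import numpy as np
import pytest

from ecotone.core import Config, TransectSpec, TreeRecord


@pytest.fixture
def spec180():
    """The standard 180 x 60 m transect with default grid resolutions."""
    return TransectSpec(length=180.0, width=60.0)


@pytest.fixture
def small_spec():
    """A small transect (35 x 20 m, 7 belts x 4 subplots) for hand checks."""
    return TransectSpec(length=35.0, width=20.0)


@pytest.fixture
def config():
    return Config()


def make_tree(x, y, height, crown=None):
    return TreeRecord(x=x, y=y, height=height,
                      crown_diameter=crown if crown is not None else 0.5 * height)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trees(rng, spec, n, h_max=12.0):
    """Uniformly scattered trees with uniform heights, crowns at ratio 1/2."""
    return [
        make_tree(x, y, h)
        for x, y, h in zip(
            rng.uniform(0, spec.width, n),
            rng.uniform(0, spec.length, n),
            rng.uniform(0.1, h_max, n),
        )
    ]
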