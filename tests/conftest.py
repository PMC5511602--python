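import numpy as np
import pytest
from hypothesis import settings

from axonvar import synthetic_data as sd
from axonvar import tensor_fit as tf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


@pytest.fixture(scope="session")
def gtab32() -> tf.GradientTable:
    """1 b=0 volume plus 32 quasi-uniform b=1000 directions."""
    dirs = fibonacci_sphere(32)
    return tf.GradientTable(
        np.r_[0.0, np.full(32, 1000.0)], np.vstack([np.zeros(3), dirs])
    )


@pytest.fixture(scope="session")
def straight_phantom():
    spec = sd.PhantomSpec(grid_shape=(32, 32, 32), extent=28.0, bundle_radius=4.0)
    return sd.make_phantom(spec) + (spec,)


@pytest.fixture(scope="session")
def arc_phantom():
    spec = sd.PhantomSpec(
        bundle_kind="arc", radius=20.0, extent=30.0, grid_shape=(48, 48, 16), bundle_radius=3.0
    )
    return sd.make_phantom(spec) + (spec,)
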