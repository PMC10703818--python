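import numpy as np
import pytest

from felgrim.descriptors import build_default_registry
from felgrim.schema import build_default_schema
from felgrim.synthetic import GeneratorParams, generate_dataset


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def small_dataset():
    """120 synthetic faces under default study conditions."""
    return generate_dataset(120, GeneratorParams(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_similarity(rng):
    """A random rotation + uniform scale + translation (optionally reflected)."""
    theta = rng.uniform(-np.pi, np.pi)
    s = rng.uniform(0.3, 3.0)
    refl = -1.0 if rng.random() < 0.5 else 1.0
    c, sn = np.cos(theta), np.sin(theta)
    mat = s * np.array([[c, -sn], [sn, c]]) @ np.diag([refl, 1.0])
    t = rng.uniform(-200, 200, size=2)
    return mat, t
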