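import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from condylometry.phantoms import PhantomSpec, make_phantom, reference_landmarks

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ref_landmarks():
    return reference_landmarks()


@pytest.fixture(scope="session")
def default_phantom():
    """One default condyle phantom shared by read-only tests."""
    return make_phantom(PhantomSpec())


def rotation_matrix(axis: str, degrees: float) -> np.ndarray:
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    mats = {
        "x": [[1, 0, 0], [0, c, -s], [0, s, c]],
        "y": [[c, 0, s], [0, 1, 0], [-s, 0, c]],
        "z": [[c, -s, 0], [s, c, 0], [0, 0, 1]],
    }
    return np.asarray(mats[axis], dtype=float)
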