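import numpy as np
import pytest

from flock3d import ModelParams, SwarmState
from flock3d.experiments import desk_scale_params


@pytest.fixture
def params():
    """Production constants with a small agent count."""
    return ModelParams(N=20, L=50.0)


@pytest.fixture
def desk_params():
    """Scaled-down production preset: N=50 at the production density."""
    return desk_scale_params()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_state(params: ModelParams, rng, speed=None) -> SwarmState:
    """Uniform random positions (unconstrained) and random headings."""
    pos = rng.uniform(0, params.L, size=(params.N, 3))
    v = rng.standard_normal((params.N, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v *= params.v0 if speed is None else speed
    return SwarmState(0.0, pos, v)


def random_rotation(rng) -> np.ndarray:
    """Haar-random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
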