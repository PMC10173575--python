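import numpy as np
import pytest

from renalseg.phantoms import PhantomSpec, Sphere, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_phantom():
    """A (16, 64, 64) phantom with a tumor and a cyst, deterministic."""
    spec = PhantomSpec(
        shape=(16, 64, 64),
        kidney_axes=(5.0, 10.0, 8.0),
        kidney_centers=((8.0, 32.0, 18.0), (8.0, 32.0, 46.0)),
        tumor=Sphere((8.0, 28.0, 20.0), 4.0),
        cyst=Sphere((8.0, 36.0, 44.0), 3.0),
        noise_sigma=5.0,
        seed=7,
    )
    return generate_case(spec, case_id="case_fixture")


@pytest.fixture
def default_phantom():
    return generate_case(PhantomSpec(seed=3), case_id="case_default")


def numerical_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar-valued f at array x."""
    g = np.zeros_like(x, dtype=float)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
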