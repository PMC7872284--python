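import numpy as np
import pytest

from shmoo.geometry import AxisymShape, make_projection, make_sphere


@pytest.fixture(scope="session")
def sphere():
    return make_sphere(2.0, 0.1, 160)


@pytest.fixture(scope="session")
def projection():
    return make_projection(2.0, 0.5, 2.0, 0.1, 240)


@pytest.fixture
def open_cylinder():
    """Open cylindrical generating curve (radius a, theta = pi/2).

    Not a physical cell outline (no apex); used to exercise the kinematic
    relations where closed forms exist.
    """
    a, L, n = 1.0, 4.0, 80
    s = np.linspace(0.0, L, n)
    return AxisymShape(
        s=s, r=np.full(n, a), z=-s.copy(), theta=np.full(n, np.pi / 2),
        kappa_s=np.zeros(n), kappa_phi=np.full(n, 1.0 / a),
        h=np.full(n, 0.1))
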