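import numpy as np
import pytest

from beltsim import TorsoParams, TrunkSurface, belt_b, synthetic_trunk

CYL_RADIUS = 0.15


def make_cylinder(radius=CYL_RADIUS, n_theta=360, n_z=80, length=0.4):
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    z = np.linspace(0.0, length, n_z)
    return TrunkSurface(theta, z, np.full((n_theta, n_z), radius))


def make_ellipse(p=0.17, q=0.12, n_theta=360, n_z=20, length=0.4):
    """Elliptic cylinder with semi-axes p (lateral, x) and q (AP, y)."""
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    r = (np.cos(theta) ** 2 / p**2 + np.sin(theta) ** 2 / q**2) ** -0.5
    z = np.linspace(0.0, length, n_z)
    return TrunkSurface(theta, z, np.repeat(r[:, None], n_z, axis=1))


@pytest.fixture(scope="session")
def cylinder():
    return make_cylinder()


@pytest.fixture(scope="session")
def ellipse():
    return make_ellipse()


@pytest.fixture(scope="session")
def default_trunk():
    return synthetic_trunk(TorsoParams())


@pytest.fixture(scope="session")
def belt():
    return belt_b()
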