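import numpy as np
import pytest

from fffkit.examples import ATOM_TYPING_RADII, triatomic_system
from fffkit.units import ANGSTROM_TO_BOHR


@pytest.fixture(scope="session")
def radii_bohr():
    return {e: r * ANGSTROM_TO_BOHR for e, r in ATOM_TYPING_RADII.items()}


@pytest.fixture(scope="session")
def water():
    return triatomic_system("H2O")


@pytest.fixture(scope="session")
def co2():
    return triatomic_system("CO2")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def fd_derivative(f, x, order=1, h=1e-5):
    if order == 1:
        return (f(x + h) - f(x - h)) / (2 * h)
    return (f(x + h) - 2 * f(x) + f(x - h)) / h**2
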