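import numpy as np
import pytest

from qsarkit.chem_io import Molecule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def water():
    # geometry only matters qualitatively; charges come from equalization
    return Molecule(
        id="water",
        elements=["O", "H", "H"],
        coords=np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
        radii=np.array([1.52, 1.20, 1.20]),
    )


@pytest.fixture
def rod():
    # four collinear-ish heavy atoms along x with a slight y spread
    coords = np.array(
        [[-3.0, 0.1, 0.0], [-1.0, -0.1, 0.0], [1.0, 0.1, 0.0], [3.0, -0.1, 0.0]]
    )
    return Molecule(
        id="rod",
        elements=["C", "C", "C", "C"],
        coords=coords,
        radii=np.full(4, 1.7),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture
def rotator():
    return random_rotation
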