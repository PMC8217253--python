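import numpy as np
import pytest

from pellifilm import materials as mat
from pellifilm import reflectometry as refl
from pellifilm import synthetic as syn


@pytest.fixture(scope="session")
def contrasts():
    return mat.standard_contrasts()


@pytest.fixture(scope="session")
def capb_truth():
    return syn.scenario("capb")


@pytest.fixture(scope="session")
def c12e5_truth():
    return syn.scenario("c12e5")


@pytest.fixture(scope="session")
def pellicle_model():
    """A representative pre-treatment two-layer pellicle model."""
    return refl.PellicleTwoLayerModel(
        inner=refl.PellicleLayer(46.0, 0.557, roughness=5.0),
        outer=refl.PellicleLayer(325.0, 0.975, roughness=10.0),
    )


@pytest.fixture(scope="session")
def q_grid():
    return np.logspace(np.log10(0.01), np.log10(0.3), 120)


def parratt_reflectivity(stack, q):
    """Independent Parratt-recursion oracle for the Abelès implementation.

    Bottom-up recursion of reflectance amplitudes with Névot–Croce roughness
    factors; coded separately from the transfer-matrix path it checks.
    """
    q = np.atleast_1d(np.asarray(q, float))
    sld = np.array([s.sld for s in stack]) * 1e-6
    d = np.array([s.thickness for s in stack])
    sig = np.array([s.roughness for s in stack])
    k = np.sqrt(((q[:, None] / 2.0) ** 2 - 4 * np.pi * (sld[None, :] - sld[0])).astype(complex))
    n = len(stack)
    r_next = np.zeros(q.size, dtype=complex)
    for j in range(n - 2, -1, -1):
        f = (k[:, j] - k[:, j + 1]) / (k[:, j] + k[:, j + 1]) * np.exp(
            -2.0 * k[:, j] * k[:, j + 1] * sig[j + 1] ** 2
        )
        phase = np.exp(2j * k[:, j + 1] * d[j + 1]) if j + 1 < n - 1 else 0.0
        r_next = (f + r_next * phase) / (1.0 + f * r_next * phase)
    return np.minimum(np.abs(r_next) ** 2, 1.0)
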