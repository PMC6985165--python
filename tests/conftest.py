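import numpy as np
import pytest

from crypsis.receptor import receptor_noise
from crypsis.spectra import CANONICAL_GRID, Spectrum
from crypsis.synthetic import make_illuminant
from crypsis.visual import build_fish_system, irradiance_at_depth


@pytest.fixture(scope="session")
def grid():
    return CANONICAL_GRID


@pytest.fixture(scope="session")
def fish():
    return build_fish_system()


@pytest.fixture(scope="session")
def fish_noise(fish):
    return receptor_noise(fish)


@pytest.fixture(scope="session")
def illuminant():
    return make_illuminant()


@pytest.fixture(scope="session")
def irradiance_1m(illuminant):
    return irradiance_at_depth(illuminant, 1.0)


@pytest.fixture
def flat_spectrum(grid):
    def _make(value=1.0, kind="reflectance", label="flat"):
        return Spectrum(grid.wavelengths, np.full(len(grid), value), kind=kind, label=label)

    return _make


def rnl_matrix_oracle(df, e):
    """Independent matrix-form evaluation of the receptor-noise quadratic form.

    dS^2 = df' (D^-1 - D^-1 1 1' D^-1 / (1' D^-1 1)) df with D = diag(e^2):
    the generalised-least-squares projection of the receptor signals onto the
    subspace orthogonal to the achromatic direction.
    """
    df = np.asarray(df, dtype=float)
    e = np.asarray(e, dtype=float)
    dinv = 1.0 / e**2
    q = np.sum(df**2 * dinv) - np.sum(df * dinv) ** 2 / np.sum(dinv)
    return float(np.sqrt(max(q, 0.0)))
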