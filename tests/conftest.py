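"""Shared fixtures: the printed design, synthetic pure spectra and mixtures."""

import numpy as np
import pytest

from specresolve import (
    ANALYTES,
    SpectraSet,
    default_pure_spectra,
    simulate_spectra,
    table1_design,
)
from specresolve.preprocessing import select_window

NOISE_SD = 0.002
SEED = 3


@pytest.fixture(scope="session")
def design():
    return table1_design()


@pytest.fixture(scope="session")
def pure():
    return default_pure_spectra()


@pytest.fixture(scope="session")
def pure_windowed(pure):
    """True unit spectra restricted to the 220–300 nm working window (wl × 4)."""
    ss = SpectraSet(pure.wavelengths_nm, pure.unit_absorptivity, list(ANALYTES))
    return select_window(ss, 220.0, 300.0).absorbance.T


@pytest.fixture(scope="session")
def noiseless(design, pure):
    """Windowed noise-free spectra of all 30 design mixtures."""
    return select_window(simulate_spectra(design, pure, noise_sd=0.0), 220.0, 300.0)


@pytest.fixture(scope="session")
def noisy(design, pure):
    """Windowed spectra at the default 0.002 AU photometric noise."""
    return select_window(
        simulate_spectra(design, pure, noise_sd=NOISE_SD, seed=SEED), 220.0, 300.0
    )


@pytest.fixture(scope="session")
def cal_idx(design):
    return np.nonzero(design.role == "calibration")[0]


@pytest.fixture(scope="session")
def val_idx(design):
    return np.nonzero(design.role == "validation")[0]


@pytest.fixture(scope="session")
def Ycal(design):
    return design.calibration.nominal


@pytest.fixture(scope="session")
def Yval(design):
    return design.validation.nominal
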