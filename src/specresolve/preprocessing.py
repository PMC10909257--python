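"""Spectral window selection and mean-centering.

The working window is 220.0–300.0 nm (81 points at 1 nm): wavelengths below
220 nm carry mostly solvent/noise structure and those above 300 nm little
analyte information. Mean-centering is applied to the X-block (and Y-block)
for the factor-regression models; curve resolution and the linear network
consume raw absorbances within the window, since non-negativity constraints
are meaningless on centered data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import SpectraSet

__all__ = ["CenteredBlock", "select_window", "mean_center"]

DEFAULT_WINDOW = (220.0, 300.0)


@dataclass
class CenteredBlock:
    """A column-centered absorbance block and the means needed to undo it."""

    X_centered: np.ndarray
    x_means: np.ndarray
    window: tuple[float, float]
    wavelengths_nm: np.ndarray
    sample_ids: list[str]
    y_means: np.ndarray | None = None

    def restore(self) -> np.ndarray:
        """Add the column means back (inverse of centering)."""
        return self.X_centered + self.x_means


def select_window(spectra: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Inclusive wavelength slice ``[low_nm, high_nm]``; bounds must lie on the grid."""
    wl = spectra.wavelengths_nm
    if low_nm > high_nm:
        raise ValueError("low_nm must be <= high_nm")
    for bound in (low_nm, high_nm):
        if not np.any(np.isclose(wl, bound, atol=1e-9)):
            raise ValueError(f"window bound {bound} nm is not on the wavelength grid")
    mask = (wl >= low_nm - 1e-9) & (wl <= high_nm + 1e-9)
    return SpectraSet(wl[mask], spectra.absorbance[:, mask], list(spectra.sample_ids))


def mean_center(
    spectra: SpectraSet,
    reference_means: np.ndarray | None = None,
    Y: np.ndarray | None = None,
) -> CenteredBlock:
    """Subtract per-wavelength column means from the absorbance block.

    In calibration mode (``reference_means`` omitted) the means are computed
    from the block itself and stored for later use; in prediction mode the
    supplied calibration means are subtracted instead. If ``Y`` is given its
    column means are recorded as ``y_means`` (the Y-block itself is centered
    by the calibration engines).
    """
    X = spectra.absorbance
    if reference_means is None:
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples to estimate column means")
        x_means = X.mean(axis=0)
    else:
        x_means = np.asarray(reference_means, dtype=float)
        if x_means.shape != (X.shape[1],):
            raise ValueError("reference_means length must match wavelength count")
    window = (float(spectra.wavelengths_nm[0]), float(spectra.wavelengths_nm[-1]))
    y_means = None if Y is None else np.asarray(Y, dtype=float).mean(axis=0)
    return CenteredBlock(
        X - x_means, x_means, window, spectra.wavelengths_nm, list(spectra.sample_ids), y_means
    )
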