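"""Species absorption bands on the probe wavelength grid."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralBand", "make_species_spectrum", "WAVELENGTH_RANGE"]

# physical probe range within which band centers must lie, nm
WAVELENGTH_RANGE = (300.0, 1300.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralBand:
    """A single absorption band.

    center : peak wavelength, nm (within 300-1300 nm).
    fwhm : full width at half maximum, nm.
    amplitude : peak optical density at the reference dose (extinction scale).
    shape : 'gaussian' or 'lognormal' (log-wavelength Gaussian; mildly
        red-skewed, as solvated-electron bands are in practice).
    """

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if not (WAVELENGTH_RANGE[0] <= self.center <= WAVELENGTH_RANGE[1]):
            raise ValueError(f"band center {self.center} nm outside {WAVELENGTH_RANGE}")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown band shape {self.shape!r}")


def make_species_spectrum(band: SpectralBand, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate a band on a wavelength grid.

    The grid must be strictly ascending and lie within 300-1300 nm. Returns a
    non-negative vector whose maximum falls within one grid step of the band
    center whenever the center is inside the grid.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    if wl[0] < WAVELENGTH_RANGE[0] or wl[-1] > WAVELENGTH_RANGE[1]:
        raise ValueError(f"grid must lie within {WAVELENGTH_RANGE} nm")
    if band.shape == "gaussian":
        sigma = band.fwhm * _FWHM_TO_SIGMA
        y = np.exp(-0.5 * ((wl - band.center) / sigma) ** 2)
    else:  # lognormal: Gaussian in ln(wavelength), FWHM matched at the center
        sigma_x = np.arcsinh(band.fwhm / (2.0 * band.center)) / np.sqrt(2.0 * np.log(2.0))
        y = np.exp(-0.5 * (np.log(wl / band.center) / sigma_x) ** 2)
    return band.amplitude * y
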