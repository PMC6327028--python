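"""Time-wavelength transient-absorption matrix container.

The central data object of the package: absorbance (optical density) on a
wavelengths x delays grid, with a per-wavelength detector mask (blocked rows,
e.g. around the 780 nm notch filter), and the experiment metadata needed by
the downstream analyses (solute concentration, dose per pulse, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TAMatrix", "GridError"]


class GridError(ValueError):
    """A wavelength or delay grid is empty, non-monotone or mismatched."""


@dataclass
class TAMatrix:
    """Transient absorbance on a (wavelength, delay) grid.

    Parameters
    ----------
    wavelengths : array, nm, strictly ascending.
    delays : array, ps, strictly ascending.
    absorbance : array, shape (n_wavelengths, n_delays), optical density.
        Masked rows carry NaN as a sentinel.
    mask : boolean array per wavelength; True marks a detector-blocked row.
    concentration : solute concentration, mol/L.
    dose : dose per electron pulse, Gy.
    seed : seed used to generate the matrix, if synthetic.
    meta : free-form metadata (kinetic scheme parameters, mode, ...).
    """

    wavelengths: np.ndarray
    delays: np.ndarray
    absorbance: np.ndarray
    mask: np.ndarray | None = None
    concentration: float = 0.0
    dose: float = 25.3
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise GridError("wavelength grid must be a non-empty 1-D array")
        if self.delays.ndim != 1 or self.delays.size == 0:
            raise GridError("delay grid must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise GridError("wavelength grid must be strictly ascending")
        if np.any(np.diff(self.delays) <= 0):
            raise GridError("delay grid must be strictly ascending")
        if self.absorbance.shape != (self.wavelengths.size, self.delays.size):
            raise GridError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"grids ({self.wavelengths.size}, {self.delays.size})"
            )
        if self.mask is None:
            self.mask = np.zeros(self.wavelengths.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.wavelengths.shape:
                raise GridError("mask length must match wavelength grid")
        if not np.all(np.isfinite(self.absorbance[~self.mask])):
            raise ValueError("absorbance must be finite on all unmasked rows")
        self.concentration = float(self.concentration)
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    @property
    def n_delays(self) -> int:
        return self.delays.size

    def unmasked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (wavelengths, absorbance) restricted to unmasked rows."""
        keep = ~self.mask
        return self.wavelengths[keep], self.absorbance[keep]

    def window_rows(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of unmasked rows with wavelength inside ``window`` (inclusive)."""
        lo, hi = min(window), max(window)
        inside = (self.wavelengths >= lo) & (self.wavelengths <= hi) & ~self.mask
        return np.flatnonzero(inside)

    def band_integral(self, window: tuple[float, float]) -> np.ndarray:
        """Trapezoidal band integral over a wavelength window, one value per delay."""
        rows = self.window_rows(window)
        if rows.size == 0:
            raise GridError(f"no unmasked wavelengths inside window {window}")
        if rows.size == 1:
            return self.absorbance[rows[0]].copy()
        return np.trapezoid(self.absorbance[rows], self.wavelengths[rows], axis=0)

    def trace(self, wavelength: float) -> np.ndarray:
        """Kinetic trace at the unmasked grid point closest to ``wavelength``."""
        keep = np.flatnonzero(~self.mask)
        if keep.size == 0:
            raise GridError("matrix is fully masked")
        idx = keep[np.argmin(np.abs(self.wavelengths[keep] - wavelength))]
        return self.absorbance[idx].copy()

    def same_grids(self, other: "TAMatrix") -> bool:
        return (
            self.wavelengths.size == other.wavelengths.size
            and self.delays.size == other.delays.size
            and np.allclose(self.wavelengths, other.wavelengths)
            and np.allclose(self.delays, other.delays)
        )
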