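"""Electron-scavenging (C37) competition analysis of a concentration series.

Within the electron pulse, quasi-free electrons either relax toward solvation
or attach to the solute; the surviving (relaxing) fraction follows the
exponential scavenging law

    A(C) = A0 exp(-C / C37),

where A is the initial near-IR pre-solvated-electron absorbance, C the solute
concentration and C37 the scavenging capacity — the concentration at which the
unscavenged fraction drops to 1/e. The captured fraction is 1 - exp(-C/C37).
The pre-solvated-electron scavenging time at concentration C is 1/(k C) for a
rate constant k.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import TAMatrix

__all__ = [
    "ScavengingModel",
    "YieldCurve",
    "fit_scavenging",
    "capture_fraction",
    "capture_from_ratios",
    "scavenging_time",
    "initial_ir_absorbance",
    "normalized_kinetics_compare",
    "amplitude_linearity",
]

IR_WINDOW_NM = (900.0, 1000.0)


@dataclass(frozen=True)
class ScavengingModel:
    """Exponential scavenging law A(C) = a0 exp(-C/c37).

    c37 : mol/L, scavenging capacity; a0 : OD, zero-concentration absorbance;
    k_pre : L mol^-1 s^-1, pre-solvated-electron scavenging rate constant
    (an input constant, not fitted from the series).
    """

    c37: float
    a0: float
    k_pre: float = 5.0e12
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.c37 <= 0:
            raise ValueError("c37 must be positive")
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if self.k_pre <= 0:
            raise ValueError("k_pre must be positive")

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.a0 * np.exp(-c / self.c37)


@dataclass
class YieldCurve:
    """Relative electron yield and capture fraction across concentrations."""

    concentrations: np.ndarray
    relative_yield: np.ndarray
    capture_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.relative_yield = np.asarray(self.relative_yield, dtype=float)
        self.capture_fraction = np.asarray(self.capture_fraction, dtype=float)
        if not (
            self.concentrations.shape
            == self.relative_yield.shape
            == self.capture_fraction.shape
        ):
            raise ValueError("yield-curve arrays must share one length")
        if np.any(np.abs(self.relative_yield + self.capture_fraction - 1.0) > 1e-12):
            raise ValueError("relative_yield + capture_fraction must equal 1")

    @classmethod
    def from_model(cls, model: ScavengingModel, concentrations) -> "YieldCurve":
        c = np.asarray(concentrations, dtype=float)
        surviving = np.exp(-c / model.c37)
        return cls(c, surviving, 1.0 - surviving)


def fit_scavenging(concentrations, initial_absorbances) -> ScavengingModel:
    """Fit the exponential scavenging law to initial IR absorbances.

    The fit is linear in ln A vs C, weighted by absorbance (so the
    back-transformed residuals are approximately homoscedastic). Requires at
    least three distinct concentrations including one near zero.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(initial_absorbances, dtype=float)
    if c.shape != a.shape or c.size < 3:
        raise ValueError("need >= 3 paired (concentration, absorbance) points")
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if np.any(a <= 0):
        raise ValueError("absorbances must be positive")
    if c.min() > 0.2 * c.max():
        raise ValueError("series must include a concentration near zero")
    w = a / a.max()
    ln_a = np.log(a)
    # weighted least squares on ln A = ln a0 - C/c37
    W = np.diag(w)
    X = np.column_stack([np.ones_like(c), c])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ln_a)
    intercept, slope = beta
    if slope >= 0:
        raise ValueError("absorbance does not decrease with concentration")
    pred = X @ beta
    ss_res = float(np.sum(w * (ln_a - pred) ** 2))
    mean_w = float(np.sum(w * ln_a) / np.sum(w))
    ss_tot = float(np.sum(w * (ln_a - mean_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ScavengingModel(c37=float(-1.0 / slope), a0=float(np.exp(intercept)),
                           r_squared=float(r2))


def capture_fraction(model: ScavengingModel, concentration: float) -> float:
    """Fraction of electrons captured within the pulse, 1 - exp(-C/C37)."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return 1.0 - float(np.exp(-concentration / model.c37))


def capture_from_ratios(concentrations, initial_absorbances) -> np.ndarray:
    """Model-free capture fractions 1 - A(C)/A(0) from direct amplitude ratios.

    The zero-concentration amplitude is the absorbance at the smallest
    concentration in the series (which must be 0 for an unbiased estimate).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(initial_absorbances, dtype=float)
    a0 = a[np.argmin(c)]
    return 1.0 - a / a0


def scavenging_time(k: float, concentration: float) -> float:
    """Pseudo-first-order scavenging time 1/(k C), seconds."""
    if k <= 0 or concentration <= 0:
        raise ValueError("rate constant and concentration must be positive")
    return 1.0 / (k * concentration)


def initial_ir_absorbance(
    matrix: TAMatrix,
    window: tuple[float, float] = IR_WINDOW_NM,
    irf_fwhm: float = 7.0,
    n_delays: int = 3,
) -> float:
    """Initial pre-solvated-electron absorbance of one matrix.

    Mean absorbance over the electron-only near-IR window and the first
    ``n_delays`` delays after t0 + IRF fwhm (so the reading sits past the
    rising edge of the pulse).
    """
    rows = matrix.window_rows(window)
    if rows.size == 0:
        raise ValueError(f"no unmasked wavelengths in window {window}")
    cols = np.flatnonzero(matrix.delays > irf_fwhm)[:n_delays]
    if cols.size == 0:
        raise ValueError("no delays after the instrument response")
    return float(np.mean(matrix.absorbance[np.ix_(rows, cols)]))


def normalized_kinetics_compare(matrices, window: tuple[float, float] = (720.0, 1000.0)
                                ) -> float:
    """Maximum pairwise RMS difference between self-normalized band kinetics.

    Each matrix is band-integrated over ``window`` and normalized to its own
    maximum; returns the largest RMS difference over all pairs. Near-zero
    values mean the scavenger changes only the amplitude, not the shape, of
    the electron relaxation.
    """
    mats = list(matrices)
    if len(mats) < 2:
        raise ValueError("need at least two matrices to compare")
    first = mats[0]
    traces = []
    for m in mats:
        if not m.same_grids(first):
            raise ValueError("matrices must share wavelength and delay grids")
        tr = m.band_integral(window)
        peak = np.max(np.abs(tr))
        if peak <= 0:
            raise ValueError("flat band integral; cannot normalize")
        traces.append(tr / peak)
    worst = 0.0
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            worst = max(worst, float(np.sqrt(np.mean((traces[i] - traces[j]) ** 2))))
    return worst


def amplitude_linearity(initial_amplitudes, capture_fractions):
    """OLS of the new-species initial amplitude against electrons captured.

    Returns (slope, intercept, r_squared, intercept_stderr). A proportional
    relation (intercept ~ 0, r^2 ~ 1) means the early signal amplitude simply
    counts the electrons captured within the pulse.
    """
    y = np.asarray(initial_amplitudes, dtype=float)
    x = np.asarray(capture_fractions, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate constant abscissa")
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.intercept_stderr),
    )
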