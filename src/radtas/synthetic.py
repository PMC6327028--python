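"""Synthetic pulse-radiolysis transient-absorption matrices with known truth.

Emulates the structure of picosecond pulse-radiolysis data of an electron
scavenger (a nucleoside) in a viscous glycol: a near-IR pre-solvated-electron
band decaying with tau1, a visible band relaxing (blue-shifting ~750 -> 630 nm)
with tau2 toward the solvated-electron band, a UV-vis excited-anion band
decaying in a few hundred ps, within-pulse scavenging following the
exponential C37 law, a ~7 ps Gaussian instrument response, additive Gaussian
noise, and a detector-blocked region around the 780 nm notch filter.

Two construction modes:

* ``bilinear`` — absorbance is a strict sum of static species spectra times
  kinetic profiles (the factorization MCR-ALS assumes); the blue shift is
  discretized into the hot-visible and solvated species.
* ``shifting`` — the visible band center actually moves,
  lambda(t) = lambda_final + (lambda_initial - lambda_final) exp(-t/tau2),
  which violates bilinearity the way the real relaxing band does.

Every matrix is reproducible from its seed.
"""
from __future__ import annotations

import numpy as np

from .bands import SpectralBand, make_species_spectrum
from .kinetics import (
    SPECIES,
    InstrumentResponse,
    KineticScheme,
    irf_convolve,
    simulate_populations,
)
from .matrix import TAMatrix

__all__ = [
    "DEFAULT_BANDS",
    "REFERENCE_DOSE_GY",
    "SolventSpec",
    "default_wavelengths",
    "default_delays_ps",
    "microsecond_delays",
    "simulate_ta_matrix",
    "neat_solvent_matrix",
    "solution_matrix",
    "microsecond_matrix",
    "concentration_series",
]

REFERENCE_DOSE_GY = 25.3
MASK_WINDOW_NM = (770.0, 790.0)
DEFAULT_NOISE_SD = 5.0e-4


class SolventSpec:
    """Bulk solvent metadata (not used in any equation)."""

    def __init__(self, name: str, dielectric_constant: float, viscosity: float):
        if dielectric_constant <= 1:
            raise ValueError("dielectric_constant must exceed 1")
        if viscosity <= 0:
            raise ValueError("viscosity must be positive")
        self.name = name
        self.dielectric_constant = dielectric_constant
        self.viscosity = viscosity


#: diethylene glycol at 25 C
DEG = SolventSpec("diethylene glycol", 31.69, 35.7)

# Default species bands. Centers of the solvated electron (630 nm) and the
# initial visible band (750 nm) are the observed positions; the near-IR band
# sits above 900 nm with only its blue tail probed; anion band centers/widths
# are package defaults chosen to be spectrally distinguishable. Amplitudes are
# peak OD at the reference dose, on the scale typical of a ~25 Gy pulse
# (G(e-)*dose*epsilon ~ a few 0.01 OD).
DEFAULT_BANDS: dict[str, SpectralBand] = {
    "e_ir": SpectralBand(center=1080.0, fwhm=220.0, amplitude=0.080),
    "e_vis_hot": SpectralBand(center=750.0, fwhm=210.0, amplitude=0.070),
    "e_sol": SpectralBand(center=630.0, fwhm=230.0, amplitude=0.060),
    "tni_excited": SpectralBand(center=400.0, fwhm=150.0, amplitude=0.050),
    "tni_ground": SpectralBand(center=520.0, fwhm=140.0, amplitude=0.040),
}


def default_wavelengths() -> np.ndarray:
    """Probe grid 370-1100 nm, 5 nm step."""
    return np.arange(370.0, 1100.0 + 1e-9, 5.0)


def default_delays_ps() -> np.ndarray:
    """Picosecond window -20 to 500 ps, 2 ps step."""
    return np.arange(-20.0, 500.0 + 1e-9, 2.0)


def microsecond_delays(n: int = 200) -> np.ndarray:
    """Long-time window, log-spaced 10 ps to 20 us (in ps)."""
    return np.geomspace(10.0, 2.0e7, n)


def _detector_mask(wavelengths: np.ndarray,
                   window: tuple[float, float] | None) -> np.ndarray:
    mask = np.zeros(wavelengths.size, dtype=bool)
    if window is not None:
        lo, hi = min(window), max(window)
        mask |= (wavelengths >= lo) & (wavelengths <= hi)
    return mask


def _shift_center(scheme: KineticScheme, t: np.ndarray) -> np.ndarray:
    span = scheme.lambda_initial - scheme.lambda_final
    return scheme.lambda_final + span * np.exp(
        -np.clip(t, 0.0, None) / scheme.tau2
    )


def simulate_ta_matrix(
    scheme: KineticScheme,
    bands: dict[str, SpectralBand] | None = None,
    irf: InstrumentResponse | None = InstrumentResponse(),
    wavelengths: np.ndarray | None = None,
    delays: np.ndarray | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    mode: str = "bilinear",
    seed: int | None = None,
    dose: float = REFERENCE_DOSE_GY,
    mask_window: tuple[float, float] | None = MASK_WINDOW_NM,
) -> TAMatrix:
    """Simulate a transient-absorption matrix.

    ``bands`` maps each species of :data:`radtas.kinetics.SPECIES` to its
    absorption band. In shifting mode the solvated-electron band template is
    reused for the moving visible band (its center follows the tau2
    exponential) and the static hot-visible band is not used.
    Amplitudes scale linearly with ``dose`` relative to the reference dose.
    """
    if mode not in ("bilinear", "shifting"):
        raise ValueError(f"unknown mode {mode!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    missing = set(SPECIES) - set(bands)
    if missing:
        raise ValueError(f"missing bands for species: {sorted(missing)}")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    t = default_delays_ps() if delays is None else np.asarray(delays, float)

    # The populations turn on sharply at t = 0; to convolve with the IRF
    # accurately the signal is built on a supersampled time grid and decimated
    # back after the convolution.
    oversample = 1
    t_fine = t
    if irf is not None:
        steps = np.diff(t)
        if steps.size and np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            oversample = max(1, int(np.ceil(steps[0] / (irf.sigma / 8.0))))
            if oversample > 1:
                t_fine = np.linspace(
                    t[0], t[-1], (t.size - 1) * oversample + 1
                )

    pops = simulate_populations(scheme, t_fine)

    if mode == "bilinear":
        spectra = np.column_stack(
            [make_species_spectrum(bands[s], wl) for s in SPECIES]
        )
        signal = spectra @ pops
    else:
        by_species = dict(zip(SPECIES, pops))
        signal = np.zeros((wl.size, t_fine.size))
        for name in ("e_ir", "tni_excited", "tni_ground"):
            signal += np.outer(make_species_spectrum(bands[name], wl), by_species[name])
        # moving visible band carries the whole visible electron channel
        template = bands["e_sol"]
        centers = _shift_center(scheme, t_fine)
        n_vis = by_species["e_vis_hot"] + by_species["e_sol"]
        if template.shape == "gaussian":
            sigma_nm = template.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            gauss = np.exp(-0.5 * ((wl[:, None] - centers[None, :]) / sigma_nm) ** 2)
            signal += template.amplitude * gauss * n_vis[None, :]
        else:
            for j in range(t_fine.size):
                band_j = SpectralBand(
                    center=float(centers[j]),
                    fwhm=template.fwhm,
                    amplitude=template.amplitude,
                    shape=template.shape,
                )
                signal[:, j] += make_species_spectrum(band_j, wl) * n_vis[j]

    if irf is not None:
        signal = np.apply_along_axis(irf_convolve, 1, signal, t_fine, irf)
        if oversample > 1:
            signal = signal[:, ::oversample]

    signal *= dose / REFERENCE_DOSE_GY

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)

    mask = _detector_mask(wl, mask_window)
    signal[mask, :] = np.nan

    meta = {
        "mode": mode,
        "noise_sd": noise_sd,
        "irf_fwhm": None if irf is None else irf.fwhm,
        "scheme": {
            "tau1": scheme.tau1,
            "tau2": scheme.tau2,
            "tau_tni": scheme.tau_tni,
            "tau_esol": scheme.tau_esol,
            "k_esol_attach": scheme.k_esol_attach,
            "lambda_initial": scheme.lambda_initial,
            "lambda_final": scheme.lambda_final,
            "c37": scheme.c37,
            "concentration": scheme.concentration,
        },
    }
    return TAMatrix(
        wavelengths=wl,
        delays=t,
        absorbance=signal,
        mask=mask,
        concentration=scheme.concentration,
        dose=dose,
        seed=seed,
        meta=meta,
    )


# --------------------------------------------------------------------------
# Named experiment presets mirroring the study conditions
# --------------------------------------------------------------------------

def neat_solvent_matrix(seed: int | None = 0, mode: str = "bilinear",
                        noise_sd: float = DEFAULT_NOISE_SD) -> TAMatrix:
    """Neat-solvent picosecond matrix (no solute): the solvation experiment."""
    return simulate_ta_matrix(
        KineticScheme(concentration=0.0), mode=mode, seed=seed, noise_sd=noise_sd
    )


def solution_matrix(concentration: float, seed: int | None = 0,
                    noise_sd: float = DEFAULT_NOISE_SD) -> TAMatrix:
    """Solute solution on the picosecond window (bilinear mode)."""
    return simulate_ta_matrix(
        KineticScheme(concentration=concentration), seed=seed, noise_sd=noise_sd
    )


def microsecond_matrix(concentration: float = 0.0, seed: int | None = 0,
                       noise_sd: float = DEFAULT_NOISE_SD) -> TAMatrix:
    """Long-time (to 20 us) matrix on a log-spaced grid; IRF negligible there."""
    return simulate_ta_matrix(
        KineticScheme(concentration=concentration),
        irf=None,
        delays=microsecond_delays(),
        seed=seed,
        noise_sd=noise_sd,
    )


def concentration_series(
    concentrations=(0.0, 0.05, 0.1, 0.2, 0.3, 0.5),
    seed: int | None = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[TAMatrix]:
    """Picosecond matrices across a solute concentration series.

    Each matrix gets an independent noise stream derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(tuple(concentrations)))
    out = []
    for conc, child in zip(concentrations, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(solution_matrix(conc, seed=child_seed, noise_sd=noise_sd))
    return out
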