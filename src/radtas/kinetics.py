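"""Kinetic scheme of electron relaxation and attachment, and the pulse IRF.

The model is a linear cascade with a within-pulse branching at the top.
Dose-deposited electrons start either as pre-solvated electrons or — with
probability 1 - exp(-C/C37) set by quasi-free-electron scavenging within the
pulse — as the excited solute anion (TNI*):

    e_ir (p-like, near-IR)  --tau1-->  e_vis_hot (hot visible, ~750 nm)
    e_vis_hot               --tau2-->  e_sol (solvated electron, 630 nm)
    e_sol  --[1/tau_esol + k_attach*C]-->  (decay | ground anion)
    tni_excited (TNI*)      --tau_tni-->  non-absorbing fragments
    tni_ground              stable on the simulated window

The continuous blue shift of the relaxing visible band (~750 -> 630 nm with
time constant tau2) is represented in two ways: as the two-state hot/solvated
discretization above (bilinear mode, the factorization MCR-ALS assumes), or
as an actually moving band center (shifting mode, see `synthetic`).

All delays are picoseconds internally; tau_esol is stored in microseconds and
k_esol_attach in L mol^-1 s^-1, converted at evaluation time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticScheme",
    "InstrumentResponse",
    "SPECIES",
    "simulate_populations",
    "irf_convolve",
    "capture_fraction_at",
]

#: fixed species order of the population matrix
SPECIES = ("e_ir", "e_vis_hot", "e_sol", "tni_excited", "tni_ground")

PS_PER_US = 1.0e6
PS_PER_S = 1.0e12


@dataclass(frozen=True)
class KineticScheme:
    """Rate parameters of the relaxation/attachment cascade.

    tau1, tau2 : ps — IR->visible transfer and visible relaxation (blue shift).
    tau_tni : ps — excited-anion (TNI*) decay.
    tau_esol : microseconds — intrinsic solvated-electron lifetime.
    k_esol_attach : L mol^-1 s^-1 — slow e_sol + solute attachment step.
    lambda_initial, lambda_final : nm — visible-band shift endpoints.
    c37 : mol/L — scavenging capacity (1/e concentration of the exponential
        within-pulse capture law).
    concentration : mol/L — solute concentration of this experiment.
    """

    tau1: float = 45.0
    tau2: float = 80.0
    tau_tni: float = 350.0
    tau_esol: float = 5.0
    k_esol_attach: float = 5.0e8
    lambda_initial: float = 750.0
    lambda_final: float = 630.0
    c37: float = 0.37
    concentration: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "tau_tni", "tau_esol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c37 <= 0:
            raise ValueError("c37 must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.lambda_initial <= self.lambda_final:
            raise ValueError("lambda_initial must exceed lambda_final")
        if self.k_esol_attach < 0:
            raise ValueError("k_esol_attach must be non-negative")

    @property
    def relaxed_fraction(self) -> float:
        """exp(-C/C37): electrons that escape within-pulse capture."""
        return float(np.exp(-self.concentration / self.c37))

    @property
    def captured_fraction(self) -> float:
        """1 - exp(-C/C37): electrons captured as TNI* within the pulse."""
        return 1.0 - self.relaxed_fraction

    @property
    def k_esol_total_per_ps(self) -> float:
        """Combined e_sol decay rate 1/tau_esol + k_attach*C, in ps^-1."""
        return (
            1.0 / (self.tau_esol * PS_PER_US)
            + self.k_esol_attach * self.concentration / PS_PER_S
        )

    @property
    def attach_branching(self) -> float:
        """Fraction of e_sol decay that forms the ground-state anion."""
        k_att = self.k_esol_attach * self.concentration / PS_PER_S
        total = self.k_esol_total_per_ps
        return k_att / total if total > 0 else 0.0


def capture_fraction_at(concentration: float, c37: float) -> float:
    """Within-pulse capture fraction 1 - exp(-C/C37)."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if c37 <= 0:
        raise ValueError("c37 must be positive")
    return 1.0 - float(np.exp(-concentration / c37))


@dataclass(frozen=True)
class InstrumentResponse:
    """Gaussian instrument response (the temporal width of the electron pulse).

    fwhm : ps; t0 : center of the response on the delay axis, ps.
    """

    fwhm: float = 7.0
    shape: str = "gaussian"
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.shape != "gaussian":
            raise ValueError(f"unsupported IRF shape {self.shape!r}")

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _exp_decay(t: np.ndarray, rate: float) -> np.ndarray:
    """H(t) exp(-rate*t), safe for large negative exponents."""
    out = np.zeros_like(t)
    pos = t >= 0
    out[pos] = np.exp(-np.minimum(rate * t[pos], 700.0))
    return out


def _bateman3(t: np.ndarray, k1: float, k2: float, k3: float) -> np.ndarray:
    """Population of the third member of a k1 -> k2 -> k3 linear chain,
    unit initial population in the first member. The degenerate k1 = k2 case
    (catastrophic cancellation in the general formula) uses its own closed
    form; other near-degeneracies are split by a small relative jitter."""
    if abs(k1 - k2) < 1e-6 * max(k1, k2):
        k = 0.5 * (k1 + k2)
        tp = np.where(t >= 0, t, 0.0)
        out = (k / (k - k3)) ** 2 * (
            _exp_decay(t, k3) - _exp_decay(t, k) * (1.0 + (k - k3) * tp)
        )
        return np.clip(out, 0.0, None)
    ks = [k1, k2, k3]
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(ks[i] - ks[j]) < 1e-9 * max(ks[i], ks[j], 1e-30):
                ks[j] *= 1.0 + 1e-6
    k1, k2, k3 = ks
    out = k1 * k2 * (
        _exp_decay(t, k1) / ((k2 - k1) * (k3 - k1))
        + _exp_decay(t, k2) / ((k1 - k2) * (k3 - k2))
        + _exp_decay(t, k3) / ((k1 - k3) * (k2 - k3))
    )
    return np.clip(out, 0.0, None)


def simulate_populations(scheme: KineticScheme, delays: np.ndarray) -> np.ndarray:
    """Closed-form populations of the cascade, species x delays.

    Species order is :data:`SPECIES`. Populations are zero for t < 0 (the
    instrument response is applied separately, see :func:`irf_convolve`).
    At t = 0+ the electron channel holds exp(-C/C37) and the excited anion
    1 - exp(-C/C37).
    """
    t = np.asarray(delays, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("delay grid must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("delay grid must be strictly ascending")

    f = scheme.relaxed_fraction
    g = scheme.captured_fraction
    k1 = 1.0 / scheme.tau1
    k2 = 1.0 / scheme.tau2
    kv = scheme.k_esol_total_per_ps

    e_ir = f * _exp_decay(t, k1)
    if abs(k1 - k2) < 1e-6 * max(k1, k2):
        e_hot = f * k1 * np.where(t >= 0, t, 0.0) * _exp_decay(t, k1)
    else:
        e_hot = f * (k1 / (k2 - k1)) * (_exp_decay(t, k1) - _exp_decay(t, k2))
    e_sol = f * _bateman3(t, k1, k2, kv)
    tni_exc = g * _exp_decay(t, 1.0 / scheme.tau_tni)
    # every electron lost from the chain decays from e_sol, a fixed fraction
    # of which forms the ground-state anion
    electrons = e_ir + e_hot + e_sol
    lost = np.clip(f * (t >= 0) - electrons, 0.0, None)
    tni_gnd = scheme.attach_branching * lost

    pops = np.vstack([e_ir, e_hot, e_sol, tni_exc, tni_gnd])
    return np.clip(pops, 0.0, None)


def irf_convolve(profile: np.ndarray, delays: np.ndarray,
                 irf: InstrumentResponse) -> np.ndarray:
    """Convolve a time profile with the unit-area Gaussian instrument response.

    Requires a uniform delay grid with step <= the IRF fwhm. Edges are
    replicated so that a constant profile is returned unchanged; output length
    equals input length and the integral of profiles fully inside the window
    is preserved.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(profile, dtype=float)
    if y.shape != t.shape:
        raise ValueError("profile and delay grid must have the same length")
    steps = np.diff(t)
    if steps.size == 0:
        raise ValueError("need at least two time points")
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("irf_convolve requires a uniform time grid")
    if irf.fwhm < dt:
        raise ValueError("IRF fwhm must be at least the time step")
    sigma = irf.sigma
    half = int(np.ceil((4.0 * sigma + abs(irf.t0)) / dt))
    offsets = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * ((offsets - irf.t0) / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.concatenate([np.full(half, y[0]), y, np.full(half, y[-1])])
    # valid-mode convolution reverses the kernel, restoring out[i] = sum_j
    # kernel(j) * y[i-j]: a delta at t lands a Gaussian centered at t + t0
    return np.convolve(padded, kernel, mode="valid")
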