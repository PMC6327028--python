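"""Global lifetime analysis and band-shift tracking of electron relaxation.

The workhorse is :func:`global_fit`, a variable-projection multi-exponential
fit: a small number of time constants shared across all wavelengths, with the
per-wavelength amplitudes (decay-associated spectra, DAS) and an optional
non-decaying offset solved by linear least squares conditional on the taus.
Exponentials are convolved analytically with the Gaussian instrument response,

    (exp(-t/tau) * IRF)(t) = 1/2 exp(s^2/(2 tau^2) - (t-t0)/tau)
                             erfc((s/tau - (t-t0)/s) / sqrt(2)),

evaluated through erfcx for numerical stability.

:func:`track_peak` follows the visible band maximum through time (local
quadratic on log-absorbance, exact for a Gaussian band) and fits the
exponential relaxation lambda(t) = lambda_inf + shift * exp(-t/tau_shift).
:func:`estimate_lifetime_loglinear` is the simple single-trace estimator:
ordinary least squares on ln(signal) vs t.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .kinetics import InstrumentResponse
from .matrix import TAMatrix

__all__ = [
    "GlobalFitResult",
    "PeakTrajectory",
    "LifetimeEstimate",
    "exp_conv_gaussian",
    "global_fit",
    "track_peak",
    "estimate_lifetime_loglinear",
    "positive_fit_window",
]

logger = logging.getLogger(__name__)

_LOG_TAU_BOUNDS = (-1.0, 7.0)  # tau in [0.1 ps, 1e7 ps]


def exp_conv_gaussian(t: np.ndarray, tau: float,
                      irf: InstrumentResponse | None) -> np.ndarray:
    """H(t) exp(-t/tau) convolved with a unit-area Gaussian IRF (closed form)."""
    t = np.asarray(t, dtype=float)
    if irf is None:
        out = np.zeros_like(t)
        pos = t >= 0
        out[pos] = np.exp(-t[pos] / tau)
        return out
    sigma = irf.sigma
    u = (t - irf.t0) / sigma
    a = sigma / tau
    z = (a - u) / np.sqrt(2.0)
    # 0.5 exp(a^2/2 - a u) erfc(z) == 0.5 erfcx(z) exp(-u^2/2) for z > 0
    out = np.empty_like(t)
    hi = z > 0
    out[hi] = 0.5 * special.erfcx(z[hi]) * np.exp(-0.5 * u[hi] ** 2)
    out[~hi] = 0.5 * np.exp(0.5 * a * a - a * u[~hi]) * special.erfc(z[~hi])
    return out


@dataclass
class GlobalFitResult:
    """Shared time constants with decay-associated spectra.

    time_constants are sorted ascending; ``das`` columns follow that order and
    are defined on the full wavelength grid (NaN at masked rows). ``offset``
    is the per-wavelength non-decaying amplitude (zeros when not fitted).
    """

    time_constants: np.ndarray
    das: np.ndarray
    offset: np.ndarray
    residual_rms: float
    covariance: np.ndarray | None
    tau_stderr: np.ndarray | None
    converged: bool
    n_iterations: int
    message: str = ""
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.argsort(self.time_constants)
        self.time_constants = np.asarray(self.time_constants)[order]
        self.das = np.asarray(self.das)[:, order]
        if self.tau_stderr is not None:
            self.tau_stderr = np.asarray(self.tau_stderr)[order]


def _design_matrix(t: np.ndarray, taus: np.ndarray,
                   irf: InstrumentResponse | None, fit_offset: bool) -> np.ndarray:
    cols = [exp_conv_gaussian(t, tau, irf) for tau in taus]
    if fit_offset:
        if irf is None:
            step = (t >= 0).astype(float)
        else:
            step = 0.5 * special.erfc(-(t - irf.t0) / (irf.sigma * np.sqrt(2.0)))
        cols.append(step)
    return np.column_stack(cols)


def global_fit(
    matrix: TAMatrix,
    n_components: int,
    irf: InstrumentResponse | None = InstrumentResponse(),
    init_taus: np.ndarray | None = None,
    fit_offset: bool = True,
    max_iter: int = 500,
) -> GlobalFitResult:
    """Fit shared exponential time constants to every unmasked trace.

    Model per wavelength: offset_l + sum_i DAS_i(l) exp(-t/tau_i), convolved
    with the IRF. The taus are optimized on a log10 scale (bounds 0.1 ps to
    1e7 ps) by trust-region least squares; the linear amplitudes are projected
    out at every step (variable projection). Negative-going DAS (rise
    components) are allowed.
    """
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    if matrix.n_delays < n_components + 1:
        raise ValueError("need more delays than components")
    keep = ~matrix.mask
    if keep.sum() < n_components:
        raise ValueError("fewer unmasked wavelengths than components")
    data = matrix.absorbance[keep]  # (nw_u, nt)
    t = matrix.delays

    if init_taus is None:
        t_pos = t[t > 0]
        span_lo = max(t_pos[0] if t_pos.size else 1.0, 1.0)
        init_taus = np.geomspace(span_lo, max(t[-1], 2 * span_lo), n_components + 2)[1:-1]
    init_taus = np.asarray(init_taus, dtype=float)
    if init_taus.size != n_components:
        raise ValueError("init_taus length must equal n_components")

    def solve_linear(log_taus: np.ndarray):
        B = _design_matrix(t, 10.0 ** log_taus, irf, fit_offset)
        coef, *_ = np.linalg.lstsq(B, data.T, rcond=None)
        return B, coef  # coef: (n_basis, nw_u)

    def residuals(log_taus: np.ndarray) -> np.ndarray:
        B, coef = solve_linear(log_taus)
        return (B @ coef - data.T).ravel()

    x0 = np.clip(np.log10(init_taus), *_LOG_TAU_BOUNDS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = optimize.least_squares(
            residuals,
            x0,
            bounds=_LOG_TAU_BOUNDS,
            xtol=1e-10,
            ftol=1e-10,
            max_nfev=max_iter * max(n_components, 1),
            diff_step=1e-4,
        )
    converged = bool(sol.success)
    if not converged:
        logger.warning("global fit did not converge: %s", sol.message)

    taus = 10.0 ** sol.x
    B, coef = solve_linear(sol.x)
    resid = B @ coef - data.T
    residual_rms = float(np.sqrt(np.mean(resid**2)))

    # covariance of log10(tau) from the Gauss-Newton approximation
    covariance = None
    tau_stderr = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(resid.size - sol.x.size - coef.size, 1)
        s2 = float(np.sum(resid**2)) / dof
        cov_log = s2 * np.linalg.inv(jtj)
        covariance = cov_log
        tau_stderr = np.sqrt(np.diag(cov_log)) * np.log(10.0) * taus
    except np.linalg.LinAlgError:  # singular Jacobian near a degenerate fit
        pass

    das_full = np.full((matrix.n_wavelengths, n_components), np.nan)
    offset_full = np.zeros(matrix.n_wavelengths)
    das_full[keep] = coef[:n_components].T
    if fit_offset:
        offset_full[keep] = coef[n_components]
        offset_full[~keep] = np.nan

    return GlobalFitResult(
        time_constants=taus,
        das=das_full,
        offset=offset_full,
        residual_rms=residual_rms,
        covariance=covariance,
        tau_stderr=tau_stderr,
        converged=converged,
        n_iterations=int(sol.nfev),
        message=str(sol.message),
        wavelengths=matrix.wavelengths.copy(),
    )


@dataclass
class PeakTrajectory:
    """Band-maximum position vs delay, with the fitted exponential shift."""

    delays: np.ndarray
    peak_positions: np.ndarray
    total_shift: float  # nm, signed: final minus initial
    shift_time_constant: float  # ps (NaN when the shift fit is degenerate)
    lambda_infinity: float = float("nan")
    fit_ok: bool = True
    skipped_delays: list = field(default_factory=list)


def _parabola_peak(x: np.ndarray, y: np.ndarray) -> float:
    """Vertex abscissa of the least-squares parabola through the points."""
    c2, c1, _ = np.polyfit(x - x.mean(), y, 2)
    if c2 >= 0:
        return float(x[np.argmax(y)])
    return float(x.mean() - c1 / (2.0 * c2))


def track_peak(
    matrix: TAMatrix,
    window: tuple[float, float] = (550.0, 900.0),
    t_range: tuple[float, float] | None = None,
    stencil: int = 8,
) -> PeakTrajectory:
    """Track the absorption-band maximum inside a wavelength window.

    Per delay, the peak is the vertex of a least-squares quadratic on
    log-absorbance over ``2*stencil + 1`` grid points around the discrete
    argmax (exact for a Gaussian band at any stencil width). Delays whose
    window is all-masked, non-positive, or whose maximum cannot be bracketed
    away from the window edge are omitted with a warning. The relaxation lambda(t) = lambda_inf + shift exp(-t/tau) is
    then fit to the positions; ``total_shift`` is lambda_inf minus the fitted
    position at t = 0 (i.e. -shift).
    """
    rows = matrix.window_rows(window)
    if rows.size < 7:
        raise ValueError("window must contain at least 7 unmasked grid points")
    wl = matrix.wavelengths[rows]
    if t_range is None:
        t_range = (matrix.delays[0], matrix.delays[-1])
    t_sel = np.flatnonzero(
        (matrix.delays >= t_range[0]) & (matrix.delays <= t_range[1])
    )

    delays_out, positions, skipped = [], [], []
    for j in t_sel:
        col = matrix.absorbance[rows, j]
        if not np.all(np.isfinite(col)) or np.max(col) <= 0:
            skipped.append(float(matrix.delays[j]))
            continue
        i = int(np.argmax(col))
        if i < max(stencil, 1) or i > col.size - 1 - max(stencil, 1):
            # maximum at or near the window edge cannot be bracketed: another
            # band's tail dominates this delay — omit it
            skipped.append(float(matrix.delays[j]))
            continue
        # quadratic on log-absorbance around the argmax (exact for a Gaussian
        # band); the stencil widens with the available points to average noise
        h = min(stencil, i, col.size - 1 - i)
        xs = wl[i - h : i + h + 1]
        ys = col[i - h : i + h + 1]
        pos = _parabola_peak(xs, np.log(ys) if np.all(ys > 0) else ys)
        if not (xs[0] <= pos <= xs[-1]):
            # vertex extrapolated beyond its stencil: curvature lost in noise
            skipped.append(float(matrix.delays[j]))
            continue
        delays_out.append(float(matrix.delays[j]))
        positions.append(pos)
    if skipped:
        logger.warning("track_peak omitted %d delays (masked/non-positive window)",
                       len(skipped))
    delays_out = np.asarray(delays_out)
    positions = np.asarray(positions)
    if delays_out.size < 5:
        raise ValueError("fewer than 5 usable delays for peak tracking")

    p_first, p_last = positions[0], positions[-1]
    try:
        span_t = delays_out[-1] - delays_out[0]

        def model_resid(p):
            lam_inf, shift, log_tau = p
            return lam_inf + shift * np.exp(-delays_out / 10.0**log_tau) - positions

        # soft-L1 loss: individual mistracked delays (band overlap at early
        # times) must not steer the relaxation fit. A tau below the sampling
        # resolution leaves the amplitude unconstrained, so fits are started
        # from several initial taus and such minima are rejected.
        dt_min = float(np.min(np.diff(delays_out)))
        sol = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for tau0 in np.geomspace(max(span_t / 50.0, 2 * dt_min), span_t, 4):
                cand = optimize.least_squares(
                    model_resid,
                    x0=[p_last, p_first - p_last, np.log10(tau0)],
                    loss="soft_l1",
                    f_scale=2.0,
                    max_nfev=5000,
                )
                if not cand.success or 10.0 ** cand.x[2] < 2 * dt_min:
                    continue
                if sol is None or cand.cost < sol.cost:
                    sol = cand
        if sol is None:
            raise RuntimeError("shift fit did not converge")
        lam_inf, shift, log_tau = sol.x
        tau_shift = 10.0**log_tau
        span = positions.max() - positions.min()
        if abs(shift) > 5 * max(span, 1.0):
            raise RuntimeError("degenerate shift fit")
        return PeakTrajectory(delays_out, positions, float(-shift),
                              float(tau_shift), float(lam_inf), True)
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        # static band: report the raw end-to-end difference
        return PeakTrajectory(delays_out, positions, float(p_last - p_first),
                              float("nan"), float(p_last), False)


@dataclass
class LifetimeEstimate:
    """Single-exponential lifetime from a log-linear fit."""

    tau: float  # ps
    half_life: float  # ps, tau * ln 2
    fit_window: tuple[float, float]
    r_squared: float
    n_points: int = 0
    amplitude: float = float("nan")


def positive_fit_window(
    delays: np.ndarray,
    trace: np.ndarray,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Shrink a fit window to end before the trace first becomes non-positive.

    Kinetic profiles recovered under a non-negativity constraint truncate at
    exact zero once the component amplitude falls below the noise floor; the
    log-linear estimator needs a strictly positive stretch.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(trace, dtype=float)
    bad = np.flatnonzero((t >= window[0]) & (t <= window[1]) & (y <= 0))
    if bad.size == 0:
        return (float(window[0]), float(window[1]))
    return (float(window[0]), float(t[bad[0]] - 1e-9))


def estimate_lifetime_loglinear(
    delays: np.ndarray,
    trace: np.ndarray,
    fit_window: tuple[float, float],
) -> LifetimeEstimate:
    """Lifetime by ordinary least squares of ln(signal) against time.

    The trace must be strictly positive inside the window (non-positive
    values signal an offset mis-specification and raise).
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(trace, dtype=float)
    if t.shape != y.shape:
        raise ValueError("trace and delays must have equal length")
    sel = (t >= fit_window[0]) & (t <= fit_window[1])
    if sel.sum() < 5:
        raise ValueError("need at least 5 points inside the fit window")
    t_w, y_w = t[sel], y[sel]
    if np.any(y_w <= 0):
        raise ValueError(
            "non-positive trace values inside the fit window "
            "(check baseline/offset subtraction)"
        )
    ln_y = np.log(y_w)
    slope, intercept = np.polyfit(t_w, ln_y, 1)
    if slope >= 0:
        raise ValueError("trace does not decay inside the fit window")
    pred = slope * t_w + intercept
    ss_res = float(np.sum((ln_y - pred) ** 2))
    ss_tot = float(np.sum((ln_y - ln_y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    tau = -1.0 / slope
    return LifetimeEstimate(
        tau=float(tau),
        half_life=float(tau * np.log(2.0)),
        fit_window=(float(fit_window[0]), float(fit_window[1])),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=int(sel.sum()),
        amplitude=float(np.exp(intercept)),
    )
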