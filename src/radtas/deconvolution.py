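"""Species deconvolution: rank estimation, MCR-ALS, and reference subtraction.

MCR-ALS (multivariate curve resolution by alternating least squares)
factorizes the absorbance matrix D (wavelengths x delays) into non-negative
species spectra S and kinetic profiles C, D ~ S C, alternating two
constrained linear problems: S given C, then C given S, each solved by
non-negative least squares per column. Lack of fit,

    LOF% = 100 sqrt( sum(residual^2) / sum(data^2) ),

is tracked per iteration and must never increase. The scale ambiguity is
fixed by normalizing each spectrum to unit maximum after every iteration
(profiles compensated); the permutation ambiguity is resolved against a
reference with :func:`match_components`.

:func:`subtract_reference` implements the complementary route: the
neat-solvent matrix, scaled per delay on the electron-only near-IR window,
is subtracted from the solution matrix to isolate the solute-derived signal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import linalg, optimize

from .matrix import GridError, TAMatrix

__all__ = [
    "RankEstimate",
    "MCRResult",
    "SubtractionResult",
    "estimate_rank",
    "initialize_purest_variables",
    "mcr_als",
    "electron_reference_spectra",
    "subtract_reference",
    "match_components",
]

logger = logging.getLogger(__name__)


@dataclass
class RankEstimate:
    """Chemical rank from the singular-value spectrum."""

    rank: int
    singular_values: np.ndarray
    noise_floor: float


def estimate_rank(matrix: TAMatrix, floor_factor: float = 5.0) -> RankEstimate:
    """Estimate the number of absorbing species by SVD of the unmasked rows.

    The noise floor is the median of the trailing half of the singular-value
    spectrum; singular values above ``floor_factor`` times the floor count as
    signal. At least one component is always reported.
    """
    _, data = matrix.unmasked()
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 unmasked wavelengths and 2 delays")
    if not np.any(data):
        raise ValueError("degenerate all-zero matrix")
    sv = linalg.svdvals(data)
    tail = sv[sv.size // 2 :]
    # floor never drops below numerical rank resolution (noiseless data)
    floor = max(float(np.median(tail)), 1e-12 * float(sv[0]))
    rank = int(np.sum(sv > floor_factor * floor))
    return RankEstimate(rank=max(rank, 1), singular_values=sv, noise_floor=floor)


def initialize_purest_variables(matrix: TAMatrix, rank: int,
                                alpha_frac: float = 0.05) -> np.ndarray:
    """Initial kinetic-profile estimates from the purest wavelength rows.

    SIMPLISMA selection: the first pick maximizes the purity SD/(mean +
    alpha) with alpha = ``alpha_frac`` of the largest row mean (the noise
    correction that keeps near-empty rows from winning); subsequent picks
    weight the purity by a determinant-based independence term so that each
    new row is as orthogonal as possible to those already chosen. Returns a
    (rank x n_delays) array of unit-maximum profiles.
    """
    keep = np.flatnonzero(~matrix.mask)
    data = matrix.absorbance[keep]
    n_rows = data.shape[0]
    if rank < 1 or rank > min(data.shape):
        raise ValueError("rank exceeds matrix dimensions")
    mu = data.mean(axis=1)
    sd = data.std(axis=1)
    alpha = alpha_frac * float(mu.max())
    purity = sd / (np.abs(mu) + alpha)

    norms = np.sqrt(np.sum(data**2, axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    unit = data / safe[:, None]

    selected: list[int] = []
    for _ in range(rank):
        best_i, best_score = -1, -np.inf
        for i in range(n_rows):
            if i in selected:
                continue
            if selected:
                block = unit[selected + [i]]
                weight = float(np.linalg.det(block @ block.T))
            else:
                weight = 1.0
            score = purity[i] * max(weight, 0.0)
            if score > best_score:
                best_score, best_i = score, i
        selected.append(best_i)

    profiles = np.clip(data[selected], 0.0, None)
    peaks = profiles.max(axis=1)
    profiles = profiles / np.where(peaks > 0, peaks, 1.0)[:, None]
    return profiles


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A X - B|| with X >= 0 column by column; ridge fallback."""
    n = A.shape[1]
    X = np.empty((n, B.shape[1]))
    for j in range(B.shape[1]):
        try:
            X[:, j], _ = optimize.nnls(A, B[:, j])
        except (RuntimeError, np.linalg.LinAlgError):
            lam = 1e-10 * np.trace(A.T @ A)
            logger.warning("nnls failed on column %d; ridge fallback", j)
            sol = np.linalg.solve(A.T @ A + lam * np.eye(n), A.T @ B[:, j])
            X[:, j] = np.clip(sol, 0.0, None)
    return X


def _unimodal_project(row: np.ndarray) -> np.ndarray:
    """L2 projection of a profile onto the unimodal cone, mode at the argmax.

    Non-decreasing up to the mode and non-increasing after it, each side by
    isotonic regression. Physical kinetic profiles of a linear cascade
    (decays, rise-decays, rise-plateaus) are all unimodal, so the constraint
    removes rotated solutions whose profiles pick up a second extremum.
    """
    m = int(np.argmax(row))
    out = row.copy()
    if m > 0:
        out[: m + 1] = optimize.isotonic_regression(row[: m + 1], increasing=True).x
    if m < row.size - 1:
        out[m:] = optimize.isotonic_regression(row[m:], increasing=False).x
    return out


@dataclass
class MCRResult:
    """MCR-ALS factorization of a transient-absorption matrix.

    ``spectra`` is (n_wavelengths x rank) with NaN at masked rows, each
    column normalized to unit maximum; ``profiles`` is (rank x n_delays) on
    the compensating scale so that spectra @ profiles reconstructs the data.
    """

    spectra: np.ndarray
    profiles: np.ndarray
    lack_of_fit_trace: np.ndarray
    iterations: int
    converged: bool
    wavelengths: np.ndarray
    delays: np.ndarray

    @property
    def lack_of_fit(self) -> float:
        return float(self.lack_of_fit_trace[-1])


def mcr_als(
    matrix: TAMatrix,
    rank: int,
    init: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-3,
    nonneg_spectra: bool = True,
    nonneg_profiles: bool = True,
    unimodal_profiles: bool = False,
    frozen_spectra: dict[int, np.ndarray] | None = None,
) -> MCRResult:
    """Alternating-least-squares curve resolution under non-negativity.

    ``init`` is a (rank x n_delays) initial profile estimate (defaults to
    :func:`initialize_purest_variables`). ``frozen_spectra`` optionally pins
    given spectrum columns (values on the unmasked wavelength grid) during
    the spectral update — the fixed-species variant. Iterations stop when the
    lack of fit changes by less than ``tol`` percentage points; hitting
    ``max_iter`` flags the result as not converged instead of raising.
    """
    keep = np.flatnonzero(~matrix.mask)
    D = matrix.absorbance[keep]
    if rank < 1 or rank > min(D.shape):
        raise ValueError("rank exceeds matrix dimensions")
    if init is None:
        C = initialize_purest_variables(matrix, rank)
    else:
        C = np.asarray(init, dtype=float)
        if C.shape != (rank, D.shape[1]):
            raise ValueError(
                f"init must have shape {(rank, D.shape[1])}, got {C.shape}"
            )
        C = np.clip(C, 0.0, None) if nonneg_profiles else C.copy()

    denom = float(np.sum(D**2))
    frozen = {} if frozen_spectra is None else {
        int(k): np.asarray(v, dtype=float) for k, v in frozen_spectra.items()
    }
    for k, v in frozen.items():
        if v.shape != (D.shape[0],):
            raise ValueError("frozen spectrum length must match unmasked rows")

    lof_trace: list[float] = []
    converged = False
    S = np.zeros((D.shape[0], rank))
    for it in range(max_iter):
        # spectra given profiles: rows of D against rows of C
        if nonneg_spectra:
            S = _nnls_columns(C.T, D.T).T
        else:
            S = np.linalg.lstsq(C.T, D.T, rcond=None)[0].T
        for k, v in frozen.items():
            S[:, k] = v
        # guard against an all-zero component killing the next step
        dead = ~np.any(S > 0, axis=0)
        if np.any(dead):
            S[:, dead] = 1e-12

        # profiles given spectra: columns of D against S
        if nonneg_profiles:
            C = _nnls_columns(S, D)
        else:
            C = np.linalg.lstsq(S, D, rcond=None)[0]
        if unimodal_profiles:
            C = np.apply_along_axis(_unimodal_project, 1, C)

        resid = D - S @ C
        lof = 100.0 * np.sqrt(float(np.sum(resid**2)) / denom)
        lof_trace.append(lof)
        if it > 0 and abs(lof_trace[-2] - lof) < tol:
            converged = True
            break

        # fix the scale ambiguity: unit-maximum spectra, compensated profiles
        peaks = S.max(axis=0)
        scale = np.where(peaks > 0, peaks, 1.0)
        S = S / scale
        C = C * scale[:, None]

    if not converged:
        logger.warning("MCR-ALS reached max_iter=%d without converging", max_iter)

    peaks = S.max(axis=0)
    scale = np.where(peaks > 0, peaks, 1.0)
    S = S / scale
    C = C * scale[:, None]

    spectra_full = np.full((matrix.n_wavelengths, rank), np.nan)
    spectra_full[keep] = S
    return MCRResult(
        spectra=spectra_full,
        profiles=C,
        lack_of_fit_trace=np.asarray(lof_trace),
        iterations=len(lof_trace),
        converged=converged,
        wavelengths=matrix.wavelengths.copy(),
        delays=matrix.delays.copy(),
    )


def electron_reference_spectra(
    neat: TAMatrix,
    snap_times: tuple[float, ...] = (8.0, 60.0, 450.0),
    n_average: int = 3,
    rank: int = 3,
) -> list[np.ndarray]:
    """Non-negative basis of the electron spectral subspace from neat data.

    Every delay column of the neat-solvent matrix is a non-negative mixture
    of the electron-species spectra, so a few rank-truncated (denoised)
    snapshot columns — early, intermediate and late in the relaxation — span
    the electron subspace while staying physically non-negative. Freezing
    these columns during MCR-ALS of a solution matrix (see
    :func:`mcr_als` ``frozen_spectra``) pins the electron contribution and
    leaves the solute-derived species in the free components, removing the
    rotational ambiguity that otherwise mixes electron kinetics into them.
    Returns unit-maximum spectra on the unmasked wavelength grid.
    """
    keep = np.flatnonzero(~neat.mask)
    D = neat.absorbance[keep]
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    r = min(rank, s.size)
    denoised = U[:, :r] @ np.diag(s[:r]) @ Vt[:r]
    basis = []
    for ts in snap_times:
        j = int(np.argmin(np.abs(neat.delays - ts)))
        lo, hi = max(j - n_average, 0), min(j + n_average + 1, neat.delays.size)
        col = np.clip(denoised[:, lo:hi].mean(axis=1), 0.0, None)
        peak = col.max()
        if peak <= 0:
            raise ValueError(f"no signal near delay {ts} ps in the reference")
        basis.append(col / peak)
    return basis


@dataclass
class SubtractionResult:
    """Solution matrix minus the per-delay-scaled neat-solvent reference."""

    isolated: TAMatrix
    scale_factors: np.ndarray
    ir_window: tuple[float, float]


def subtract_reference(
    solution: TAMatrix,
    neat: TAMatrix,
    ir_window: tuple[float, float] = (900.0, 1000.0),
) -> SubtractionResult:
    """Isolate the solute-derived signal by scaled neat-solvent subtraction.

    For each delay the scale factor is the least-squares scalar matching the
    neat matrix to the solution over the electron-only near-IR window
    (clipped at zero); the scaled neat matrix is then subtracted everywhere.
    The isolated matrix keeps the solution's mask.
    """
    if not solution.same_grids(neat):
        raise GridError("solution and neat matrices must share both grids")
    rows = solution.window_rows(ir_window)
    rows = rows[~neat.mask[rows]]
    if rows.size == 0:
        raise GridError("IR window is empty after masking")

    s_win = solution.absorbance[rows]
    n_win = neat.absorbance[rows]
    denom = np.sum(n_win * n_win, axis=0)
    numer = np.sum(n_win * s_win, axis=0)
    # Per-delay least squares, shrunk toward the global scale once the
    # reference signal in the window decays into the noise (where the
    # per-delay scalar is ill-conditioned).
    total_denom = float(denom.sum())
    global_scale = float(numer.sum()) / total_denom if total_denom > 0 else 0.0
    lam = 0.1 * float(denom.max()) if denom.size else 0.0
    scale = (numer + lam * global_scale) / (denom + lam) if (denom + lam).all() \
        else np.zeros_like(denom)
    scale = np.clip(scale, 0.0, None)

    isolated_values = solution.absorbance - scale[None, :] * neat.absorbance
    combined_mask = solution.mask | neat.mask
    isolated_values[combined_mask, :] = np.nan
    isolated = TAMatrix(
        wavelengths=solution.wavelengths.copy(),
        delays=solution.delays.copy(),
        absorbance=isolated_values,
        mask=combined_mask,
        concentration=solution.concentration,
        dose=solution.dose,
        seed=solution.seed,
        meta={"derived": "reference_subtraction", "ir_window": list(ir_window)},
    )
    return SubtractionResult(isolated=isolated, scale_factors=scale,
                             ir_window=(float(ir_window[0]), float(ir_window[1])))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def match_components(recovered: np.ndarray, truth: np.ndarray
                     ) -> tuple[tuple[int, ...], np.ndarray]:
    """Resolve the permutation ambiguity against a reference set.

    Both arguments are (k x n) arrays of component profiles (or transposed
    spectra). Returns the permutation ``perm`` such that recovered[perm[i]]
    corresponds to truth[i], maximizing the summed Pearson correlation by
    brute force (k <= 6), together with the matched correlations.
    """
    rec = np.atleast_2d(np.asarray(recovered, dtype=float))
    tru = np.atleast_2d(np.asarray(truth, dtype=float))
    if rec.shape != tru.shape:
        raise ValueError("recovered and truth must have matching shapes")
    k = rec.shape[0]
    if k > 6:
        raise ValueError("brute-force matching limited to 6 components")
    corr = np.array([[_pearson(rec[i], tru[j]) for j in range(k)] for i in range(k)])
    best_perm, best_total = None, -np.inf
    for perm in permutations(range(k)):
        total = sum(corr[perm[j], j] for j in range(k))
        if total > best_total:
            best_total, best_perm = total, perm
    scores = np.array([corr[best_perm[j], j] for j in range(k)])
    return best_perm, scores
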