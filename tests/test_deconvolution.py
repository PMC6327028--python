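"""Rank estimation, MCR-ALS factorization and reference subtraction."""
from itertools import combinations

import numpy as np
import pytest

from radtas import (
    InstrumentResponse,
    KineticScheme,
    SpectralBand,
    TAMatrix,
    electron_reference_spectra,
    estimate_lifetime_loglinear,
    estimate_rank,
    initialize_purest_variables,
    irf_convolve,
    match_components,
    mcr_als,
    simulate_populations,
    simulate_ta_matrix,
    subtract_reference,
)
from radtas.deconvolution import _nnls_columns
from radtas.solvation import positive_fit_window


def _convolved_populations(scheme, delays):
    pops = simulate_populations(scheme, delays)
    irf = InstrumentResponse()
    return np.vstack([irf_convolve(p, delays, irf) for p in pops])


class TestRank:
    def test_noiseless_three_species_rank(self, neat_noiseless):
        assert estimate_rank(neat_noiseless).rank == 3

    def test_early_time_high_concentration_rank_two(self):
        """Before visible states grow in, only the near-IR electron and the
        excited anion absorb above the noise floor."""
        m = simulate_ta_matrix(
            KineticScheme(concentration=0.8),
            delays=np.arange(-20.0, 100.0 + 1e-9, 2.0),
            seed=21,
        )
        assert estimate_rank(m).rank == 2

    def test_pure_noise_rank_at_most_one(self):
        wl = np.arange(370.0, 1101.0, 5.0)
        t = np.arange(-20.0, 501.0, 2.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = TAMatrix(wl, t, rng.normal(0, 5e-4, (wl.size, t.size)))
            hits += estimate_rank(m).rank <= 1
        assert hits >= 95

    def test_all_zero_matrix_rejected(self):
        m = TAMatrix(np.array([400.0, 500.0]), np.array([0.0, 1.0]),
                     np.zeros((2, 2)))
        with pytest.raises(ValueError):
            estimate_rank(m)


class TestPurestVariables:
    def test_non_overlapping_bands_selected_within_supports(self):
        wl = np.arange(370.0, 1101.0, 5.0)
        t = np.arange(0.0, 200.0, 2.0)
        s1 = np.exp(-0.5 * ((wl - 450) / 30.0) ** 2)
        s2 = np.exp(-0.5 * ((wl - 900) / 30.0) ** 2)
        data = np.outer(s1, np.exp(-t / 50.0)) + np.outer(s2, 1 - np.exp(-t / 50.0))
        m = TAMatrix(wl, t, data)
        profiles = initialize_purest_variables(m, 2)
        # each initial profile must reproduce one of the pure kinetics
        pure = np.vstack([np.exp(-t / 50.0), 1 - np.exp(-t / 50.0)])
        _, scores = match_components(profiles, pure)
        assert np.all(scores > 0.99)

    def test_rank_one_picks_maximum_purity_row(self, solution_03):
        keep = ~solution_03.mask
        data = solution_03.absorbance[keep]
        mu, sd = data.mean(axis=1), data.std(axis=1)
        alpha = 0.05 * mu.max()
        best = int(np.argmax(sd / (np.abs(mu) + alpha)))
        profile = initialize_purest_variables(solution_03, 1)
        expected = np.clip(data[best], 0, None)
        np.testing.assert_allclose(profile[0], expected / expected.max())

    def test_initial_estimates_correlate_with_truth(self, solution_03):
        """Purest-variable profiles resemble the true kinetics (r >= 0.7)."""
        init = initialize_purest_variables(solution_03, 4)
        truth = _convolved_populations(KineticScheme(concentration=0.3),
                                       solution_03.delays)
        _, scores = match_components(init, truth[[0, 1, 2, 3]])
        assert np.all(scores >= 0.7)

    def test_rank_exceeding_dimensions_rejected(self, solution_03):
        with pytest.raises(ValueError):
            initialize_purest_variables(solution_03, 10**4)


def brute_force_nnls(A, b):
    """Exhaustive active-set search for min ||Ax - b||, x >= 0."""
    n = A.shape[1]
    best_x, best_r = np.zeros(n), np.linalg.norm(b)
    for k in range(1, n + 1):
        for free in combinations(range(n), k):
            sol, *_ = np.linalg.lstsq(A[:, free], b, rcond=None)
            if np.any(sol < 0):
                continue
            x = np.zeros(n)
            x[list(free)] = sol
            r = np.linalg.norm(A @ x - b)
            if r < best_r - 1e-12:
                best_r, best_x = r, x
    return best_x


class TestMCR:
    def test_half_step_equals_brute_force_nnls(self):
        """Each constrained ALS half-step solves the exact non-negative
        least-squares problem (checked against active-set enumeration)."""
        rng = np.random.default_rng(5)
        A = np.abs(rng.normal(size=(6, 2)))
        B = rng.normal(size=(6, 6))  # mixed-sign targets exercise the constraint
        X = _nnls_columns(A, B)
        for j in range(6):
            np.testing.assert_allclose(X[:, j], brute_force_nnls(A, B[:, j]),
                                       atol=1e-10)

    def test_noiseless_bilinear_exact_recovery(self):
        """With true profiles as init, the noiseless factorization is exact."""
        m = simulate_ta_matrix(KineticScheme(), noise_sd=0.0, irf=None)
        truth = simulate_populations(KineticScheme(), m.delays)[:3]
        init = truth / truth.max(axis=1, keepdims=True)
        res = mcr_als(m, 3, init=init, tol=1e-8)
        assert res.lack_of_fit < 0.1
        _, scores = match_components(res.profiles, truth)
        assert np.all(scores >= 0.999)

    def test_lack_of_fit_monotone(self, solution_03):
        res = mcr_als(solution_03, 4, tol=1e-6, max_iter=100)
        assert np.all(np.diff(res.lack_of_fit_trace) <= 1e-9)

    def test_recovered_solvated_electron_band_peaks_at_630(self, solution_03):
        """The matched solvated-electron spectrum peaks at 630 +- 10 nm."""
        rank = estimate_rank(solution_03).rank
        res = mcr_als(solution_03, rank)
        truth = _convolved_populations(KineticScheme(concentration=0.3),
                                       solution_03.delays)
        perm, _ = match_components(res.profiles, truth[[2, 3, 0, 1]][:rank])
        keep = ~solution_03.mask
        spec = res.spectra[keep, perm[0]]
        peak = solution_03.wavelengths[keep][np.argmax(spec)]
        assert peak == pytest.approx(630.0, abs=10.0)

    def test_three_species_benchmark_matches_truth(self, neat_matrix):
        """Neat-solvent three-species run: mean matched correlation >= 0.95."""
        res = mcr_als(neat_matrix, 3, tol=1e-4)
        truth = _convolved_populations(KineticScheme(), neat_matrix.delays)[:3]
        _, scores = match_components(res.profiles, truth)
        assert scores.mean() >= 0.95

    def test_excited_anion_decay_not_forming_ground_anion(self):
        """The ground-anion formation rate anticorrelates with the excited
        anion: TNI* decays to fragments, the anion grows from e_sol."""
        scheme = KineticScheme(concentration=0.3, k_esol_attach=5e9 * 2)
        sol = simulate_ta_matrix(scheme, seed=19)
        neat = simulate_ta_matrix(KineticScheme(), seed=919)
        basis = electron_reference_spectra(neat)
        res = mcr_als(sol, 5, tol=1e-4, frozen_spectra=dict(enumerate(basis)))
        truth = _convolved_populations(scheme, sol.delays)
        perm, _ = match_components(res.profiles[3:], truth[[3, 4]])
        tni = res.profiles[3:][perm[0]]
        gnd = res.profiles[3:][perm[1]]
        w = np.ones(21) / 21
        sm = lambda y: np.convolve(np.pad(y, 10, mode="edge"), w, mode="valid")
        sel = sol.delays >= 10
        d_gnd = np.gradient(sm(gnd)[sel], sol.delays[sel])
        a, b = d_gnd - d_gnd.mean(), sm(tni)[sel] - sm(tni)[sel].mean()
        corr = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert corr <= 0.0

    def test_nonconvergence_flagged_not_raised(self, solution_03):
        res = mcr_als(solution_03, 4, max_iter=3, tol=1e-12)
        assert not res.converged

    def test_bad_init_shape_rejected(self, solution_03):
        with pytest.raises(ValueError):
            mcr_als(solution_03, 3, init=np.ones((2, 5)))


class TestSubtraction:
    def test_self_subtraction_vanishes(self, neat_matrix):
        """Neat against an independent neat realization leaves only noise."""
        other = simulate_ta_matrix(KineticScheme(), seed=7007)
        res = subtract_reference(neat_matrix, other)
        vals = res.isolated.absorbance[~res.isolated.mask]
        # independent noise adds in quadrature; the per-delay scale estimate
        # contributes a further few percent
        assert np.sqrt(np.mean(vals**2)) <= 5e-4 * np.sqrt(2.0) * 1.1

    def test_scale_factor_equals_relaxed_fraction(self, solution_03,
                                                  neat_reference):
        """Early-time scale factor ~ exp(-C/C37) = 0.444 at 0.3 M."""
        res = subtract_reference(solution_03, neat_reference)
        early = (solution_03.delays > 7.0) & (solution_03.delays < 30.0)
        expected = KineticScheme(concentration=0.3).relaxed_fraction
        assert np.mean(res.scale_factors[early]) == pytest.approx(expected,
                                                                  rel=0.02)

    def test_isolated_kinetics_recover_excited_anion_lifetime(
            self, solution_03, neat_reference):
        """Band-integrated isolated signal decays with tau_tni within 15%."""
        res = subtract_reference(solution_03, neat_reference)
        band = res.isolated.band_integral((370.0, 600.0))
        est = estimate_lifetime_loglinear(solution_03.delays, band,
                                          (20.0, 500.0))
        assert est.tau == pytest.approx(350.0, rel=0.15)

    def test_ir_window_residual_averages_to_zero(self, solution_03,
                                                 neat_reference):
        res = subtract_reference(solution_03, neat_reference)
        rows = res.isolated.window_rows((900.0, 1000.0))
        resid = res.isolated.absorbance[rows]
        assert abs(np.mean(resid)) < 5e-5

    def test_grid_mismatch_rejected(self, solution_03):
        other = simulate_ta_matrix(KineticScheme(),
                                   delays=np.arange(0.0, 100.0, 2.0), seed=1)
        with pytest.raises(Exception):
            subtract_reference(solution_03, other)

    def test_routes_agree_on_excited_anion_lifetime(self, solution_03,
                                                    neat_reference):
        """Subtraction and frozen-spectra MCR lifetimes differ by <= 20%."""
        sub = subtract_reference(solution_03, neat_reference)
        band = sub.isolated.band_integral((370.0, 600.0))
        tau_sub = estimate_lifetime_loglinear(solution_03.delays, band,
                                              (20.0, 500.0)).tau
        basis = electron_reference_spectra(neat_reference)
        res = mcr_als(solution_03, 4, tol=1e-4,
                      frozen_spectra=dict(enumerate(basis)))
        prof = res.profiles[3]
        win = positive_fit_window(solution_03.delays, prof, (20.0, 500.0))
        tau_mcr = estimate_lifetime_loglinear(solution_03.delays, prof, win).tau
        assert abs(tau_mcr - tau_sub) / tau_sub <= 0.20


class TestMatchComponents:
    def test_identity(self):
        a = np.random.default_rng(1).normal(size=(3, 40))
        perm, scores = match_components(a, a)
        assert perm == (0, 1, 2)
        np.testing.assert_allclose(scores, 1.0)

    def test_transposition_recovered(self):
        a = np.random.default_rng(2).normal(size=(3, 40))
        perm, _ = match_components(a[[1, 0, 2]], a)
        assert perm == (1, 0, 2)

    def test_rank_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_components(np.ones((2, 10)), np.ones((3, 10)))
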