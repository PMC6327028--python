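"""Exponential electron-scavenging (C37) analysis."""
import numpy as np
import pytest
from scipy import optimize

from radtas import (
    KineticScheme,
    ScavengingModel,
    YieldCurve,
    amplitude_linearity,
    capture_fraction,
    capture_from_ratios,
    concentration_series,
    fit_scavenging,
    initial_ir_absorbance,
    normalized_kinetics_compare,
    scavenging_time,
    simulate_ta_matrix,
)

CONCS = (0.0, 0.05, 0.1, 0.2, 0.3, 0.5)


@pytest.fixture(scope="module")
def series():
    return concentration_series(CONCS, seed=13)


@pytest.fixture(scope="module")
def fitted_model(series):
    amps = [initial_ir_absorbance(m) for m in series]
    return fit_scavenging(CONCS, amps)


class TestFit:
    def test_exact_series_recovers_c37(self):
        c = np.array(CONCS)
        a = 0.02 * np.exp(-c / 0.37)
        model = fit_scavenging(c, a)
        assert model.c37 == pytest.approx(0.37, rel=1e-3)
        assert model.a0 == pytest.approx(0.02, rel=1e-3)

    def test_capture_fractions_reproduce_printed_percentages(self, fitted_model):
        """12% captured at 0.05 M and 75% at 0.5 M, within 2 points."""
        assert 100 * capture_fraction(fitted_model, 0.05) == pytest.approx(12.0, abs=2.0)
        assert 100 * capture_fraction(fitted_model, 0.5) == pytest.approx(75.0, abs=2.0)

    def test_single_anchor_c37_root(self):
        """1 - exp(-0.05/c37) = 0.12 has the root c37 = 0.391 mol/L."""
        root = optimize.brentq(lambda c: 1 - np.exp(-0.05 / c) - 0.12, 0.1, 2.0)
        assert root == pytest.approx(0.391, rel=5e-3)
        root75 = optimize.brentq(lambda c: 1 - np.exp(-0.5 / c) - 0.75, 0.1, 2.0)
        assert root75 == pytest.approx(0.361, rel=5e-3)

    def test_direct_ratio_route_agrees_with_fit(self, series, fitted_model):
        amps = [initial_ir_absorbance(m) for m in series]
        ratios = capture_from_ratios(CONCS, amps)
        fitted = [capture_fraction(fitted_model, c) for c in CONCS]
        np.testing.assert_allclose(ratios[1:], fitted[1:], atol=0.03)

    def test_scale_equivariance(self, series):
        """Scaling all absorbances by gamma scales a0 and leaves c37 alone."""
        amps = np.array([initial_ir_absorbance(m) for m in series])
        base = fit_scavenging(CONCS, amps)
        scaled = fit_scavenging(CONCS, 3.7 * amps)
        assert scaled.c37 == pytest.approx(base.c37, rel=1e-9)
        assert scaled.a0 == pytest.approx(3.7 * base.a0, rel=1e-9)

    def test_contract_violations_rejected(self):
        with pytest.raises(ValueError):
            fit_scavenging([0.1, 0.1, 0.1], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_scavenging([0.0, 0.1, 0.2], [1.0, -0.5, 0.2])
        with pytest.raises(ValueError):
            fit_scavenging([0.4, 0.45, 0.5], [1.0, 0.9, 0.8])


class TestCaptureFraction:
    model = ScavengingModel(c37=0.391, a0=1.0)

    def test_zero_concentration(self):
        assert capture_fraction(self.model, 0.0) == 0.0

    def test_printed_anchor_points(self):
        assert capture_fraction(self.model, 0.05) == pytest.approx(0.120, abs=1e-3)
        assert capture_fraction(ScavengingModel(c37=0.361, a0=1.0), 0.5) == \
            pytest.approx(0.750, abs=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            capture_fraction(self.model, -0.1)

    def test_yield_curve_sums_to_one(self):
        curve = YieldCurve.from_model(self.model, [0.0, 0.1, 0.5, 1.0])
        np.testing.assert_allclose(
            curve.relative_yield + curve.capture_fraction, 1.0, atol=1e-15)
        with pytest.raises(ValueError):
            YieldCurve(np.array([0.1]), np.array([0.5]), np.array([0.6]))


class TestScavengingTime:
    def test_printed_arithmetic_400fs(self):
        """1/(kC) with k = 5e12 /M/s at 0.5 M is 400 fs."""
        assert scavenging_time(5e12, 0.5) == pytest.approx(4.0e-13, rel=1e-12)

    def test_reciprocal_in_concentration(self):
        assert scavenging_time(5e12, 1.0) == scavenging_time(5e12, 0.5) / 2

    def test_low_concentration_4ps(self):
        assert scavenging_time(5e12, 0.05) == pytest.approx(4.0e-12, rel=1e-12)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            scavenging_time(0.0, 0.5)
        with pytest.raises(ValueError):
            scavenging_time(5e12, 0.0)


class TestNormalizedKinetics:
    def test_identical_matrices_deviate_zero(self, series):
        assert normalized_kinetics_compare([series[0], series[0]]) == 0.0

    def test_concentration_series_shape_invariant(self, series):
        """Scavenging rescales the IR kinetics without changing their shape,
        so normalized traces stay within the noise-propagated bound."""
        dev = normalized_kinetics_compare(series, (720.0, 1000.0))
        m = series[-1]  # smallest amplitude: dominates the noise bound
        rows = m.window_rows((720.0, 1000.0))
        step = np.diff(m.wavelengths[rows]).mean()
        sigma_band = 5e-4 * step * np.sqrt(rows.size)
        peak = np.max(m.band_integral((720.0, 1000.0)))
        bound = np.sqrt(2.0) * sigma_band / peak
        assert dev <= 2.0 * bound

    def test_concentration_dependent_relaxation_detected(self):
        """Positive control: a relaxation time that grows 50% with the solute
        breaks the shape invariance in >= 95 of 100 seeds."""
        null_devs, alt_devs = [], []
        for k in range(100):
            base = simulate_ta_matrix(KineticScheme(concentration=0.0),
                                      seed=6000 + k)
            null = simulate_ta_matrix(KineticScheme(concentration=0.5),
                                      seed=7000 + k)
            skewed = simulate_ta_matrix(
                KineticScheme(concentration=0.5, tau1=45.0 * 1.5),
                seed=7000 + k)
            null_devs.append(normalized_kinetics_compare([base, null]))
            alt_devs.append(normalized_kinetics_compare([base, skewed]))
        threshold = np.quantile(null_devs, 0.95)
        detections = sum(d > threshold for d in alt_devs)
        assert detections >= 95


class TestAmplitudeLinearity:
    def test_generator_series_linear_through_origin(self, series, fitted_model):
        """New-species initial amplitude is proportional to electrons captured."""
        fracs = np.array([capture_fraction(fitted_model, c) for c in CONCS])
        amps = np.array([
            np.mean(m.absorbance[m.window_rows((380.0, 420.0))][:, (m.delays > 7)][:, :3])
            for m in series
        ])
        slope, intercept, r2, se = amplitude_linearity(amps, fracs)
        assert r2 >= 0.99
        assert abs(intercept) <= 2 * se

    def test_proportional_inputs(self):
        x = np.array([0.0, 0.2, 0.5, 0.8])
        slope, intercept, r2, _ = amplitude_linearity(3.0 * x, x)
        assert r2 == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_permutation_destroys_linearity(self, series, fitted_model):
        fracs = np.array([capture_fraction(fitted_model, c) for c in CONCS])
        amps = np.array([
            np.mean(m.absorbance[m.window_rows((380.0, 420.0))][:, (m.delays > 7)][:, :3])
            for m in series
        ])
        rng = np.random.default_rng(8)
        drops = 0
        n = 0
        while n < 100:
            perm = rng.permutation(len(amps))
            if np.array_equal(perm, np.arange(len(amps))):
                continue
            n += 1
            _, _, r2, _ = amplitude_linearity(amps[perm], fracs)
            drops += r2 < 0.5
        # with six exchangeable points ~8% of permutations keep r^2 >= 0.5
        # (e.g. a single adjacent swap); the computed null rate is ~91%
        assert drops >= 88

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            amplitude_linearity([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
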