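"""Burgers constitutive model: moduli, crossover, and fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from condense_rheo.viscoelastic import (BurgersParameters, ComplexModuliDataset,
                                        complex_moduli, crossover_frequency,
                                        fit_burgers, moduli_from_model,
                                        relaxation_modulus,
                                        zero_shear_viscosity)


class TestBurgersParameters:
    def test_canonical_ordering_swaps_components(self):
        p = BurgersParameters(eta0=1.0, tau0=2.0, eta1=3.0, tau1=0.5)
        assert (p.eta0, p.tau0, p.eta1, p.tau1) == (3.0, 0.5, 1.0, 2.0)

    def test_newtonian_fast_branch(self):
        assert BurgersParameters(1.0, 0.0, 1.0, 1.0).is_fast_newtonian

    @pytest.mark.parametrize("bad", [(-1, 0, 1, 1), (1, -1, 1, 1), (1, 0, 1, 0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            BurgersParameters(*bad)


class TestRelaxationModulus:
    def test_single_maxwell_at_t_equals_tau(self):
        p = BurgersParameters(0.0, 0.0, 1.0, 1.0)
        assert relaxation_modulus(p, 1.0) == pytest.approx(1.0 / math.e, rel=1e-12)

    def test_instantaneous_modulus(self):
        p = BurgersParameters(1.0, 0.5, 1.0, 1.0)
        assert relaxation_modulus(p, 1e-12) == pytest.approx(3.0, rel=1e-9)

    def test_two_exponential_sum_vs_high_precision_oracle(self):
        # frozen from a 30-digit symbolic evaluation of
        # (0.1/0.005) e^{-9} + (0.2/0.045) e^{-1} at t = 0.045 s
        p = BurgersParameters(0.1, 0.005, 0.2, 0.045)
        assert relaxation_modulus(p, 0.045) == pytest.approx(
            1.63748793462147724, rel=1e-14)

    def test_nonpositive_time_is_domain_error(self):
        p = BurgersParameters(0.1, 0.005, 0.2, 0.045)
        for t in (0.0, -1.0):
            with pytest.raises(ValueError):
                relaxation_modulus(p, t)

    def test_monotone_decreasing(self, ph_burgers):
        t = np.logspace(-4, 1, 200)
        g = relaxation_modulus(ph_burgers, t)
        assert np.all(np.diff(g) < 0)


class TestComplexModuli:
    def test_maxwell_equal_moduli_at_unit_omega_tau(self):
        gp, gpp = complex_moduli(BurgersParameters(0, 0, 1, 1), 1.0)
        assert gp == pytest.approx(0.5) and gpp == pytest.approx(0.5)

    def test_zero_frequency_gives_zero_moduli(self, ph_burgers):
        assert complex_moduli(ph_burgers, 0.0) == (0.0, 0.0)

    def test_negative_omega_rejected(self, ph_burgers):
        with pytest.raises(ValueError):
            complex_moduli(ph_burgers, -1.0)

    def test_fourier_transform_consistency(self, rng):
        """G*(w) = i w * one-sided Fourier transform of G(t), by quadrature."""
        for _ in range(20):
            eta0, eta1 = rng.uniform(0.05, 5, 2)
            tau1 = rng.uniform(0.02, 0.5)
            tau0 = tau1 * rng.uniform(0.02, 0.9)
            p = BurgersParameters(eta0, tau0, eta1, tau1)
            w = rng.uniform(0.5, 50.0)
            re, _ = quad(lambda t: relaxation_modulus(p, t) * math.cos(w * t),
                         1e-12, np.inf, limit=400)
            im, _ = quad(lambda t: relaxation_modulus(p, t) * math.sin(w * t),
                         1e-12, np.inf, limit=400)
            # i w (re - i im) = w im + i w re
            gp, gpp = complex_moduli(p, w)
            assert gp == pytest.approx(w * im, rel=1e-6)
            assert gpp == pytest.approx(w * re, rel=1e-6)

    def test_moduli_nonnegative_and_gprime_monotone(self, presets):
        w = np.logspace(-3, 4, 300)
        for preset in presets:
            gp, gpp = complex_moduli(preset.burgers, w)
            assert np.all(gp >= 0) and np.all(gpp >= 0)
            assert np.all(np.diff(gp) >= -1e-12 * gp.max())


class TestZeroShearViscosity:
    @pytest.mark.parametrize("eta0,eta1", [(0.1, 0.2), (0.0, 0.53)])
    def test_sum_of_component_viscosities(self, eta0, eta1):
        p = BurgersParameters(eta0, 0.001, eta1, 0.1)
        assert zero_shear_viscosity(p) == pytest.approx(eta0 + eta1, rel=1e-15)

    def test_low_frequency_limit_of_loss_modulus(self, ph_burgers):
        w = 1e-6
        _, gpp = complex_moduli(ph_burgers, w)
        assert gpp / w == pytest.approx(zero_shear_viscosity(ph_burgers), rel=1e-9)


def _crossover_oracle(params, n=10**6):
    """Dense log-grid scan for the first G' = G'' sign change."""
    w = np.logspace(-6 + math.log10(1 / params.tau1),
                    6 - math.log10(max(params.tau0, params.tau1 * 1e-6)), n)
    gp, gpp = complex_moduli(params, w)
    d = gp - gpp
    idx = np.nonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    # linear interpolation inside the bracketing interval
    return w[i] + (w[i + 1] - w[i]) * (-d[i]) / (d[i + 1] - d[i])


class TestCrossoverFrequency:
    def test_maxwell_crossover_is_inverse_tau(self, rng):
        for tau1 in rng.uniform(1e-3, 10.0, 50):
            p = BurgersParameters(0.0, 0.0, 1.0, float(tau1))
            assert crossover_frequency(p) == pytest.approx(1.0 / tau1, rel=1e-12)

    def test_burgers_crossover_matches_grid_scan_oracle(self):
        p = BurgersParameters(0.1, 0.005, 1.0, 0.1)
        oracle = _crossover_oracle(p)
        assert crossover_frequency(p) == pytest.approx(oracle, rel=1e-5)

    def test_dominant_newtonian_component_has_no_crossover(self):
        p = BurgersParameters(10.0, 0.0, 1.0, 1.0)
        assert _crossover_oracle(p) is None
        assert crossover_frequency(p) is None

    def test_inverse_crossover_transitions_from_tau1_to_tau0(self):
        """With tau0/tau1 = 0.1 fixed, 1/w_x tracks tau1 at small eta0/eta1
        (9% away at ratio 0.05) and migrates toward tau0 as eta0/eta1 grows,
        monotonically; by ratio 0.5 it sits closer to tau0 than to tau1."""
        tau1, tau0 = 0.1, 0.01
        ratios = [0.05, 0.1, 0.2, 0.35, 0.5, 1.0, 2.0]
        inv_wx = [1.0 / crossover_frequency(BurgersParameters(r, tau0, 1.0, tau1))
                  for r in ratios]
        assert np.all(np.diff(inv_wx) < 0)
        assert abs(inv_wx[0] - tau1) / tau1 < 0.10
        i2, i5 = ratios.index(0.2), ratios.index(0.5)
        assert abs(inv_wx[i2] - tau1) < abs(inv_wx[i2] - tau0)
        assert abs(inv_wx[i5] - tau0) < abs(inv_wx[i5] - tau1)


class TestModuliDataset:
    def test_validation_rejects_nonpositive_loss_modulus(self):
        with pytest.raises(ValueError):
            ComplexModuliDataset(np.array([1.0, 2.0]), np.array([0.1, 0.2]),
                                 np.array([0.3, 0.0]))

    def test_negative_storage_rows_flagged_not_rejected(self):
        d = ComplexModuliDataset(np.array([1.0, 2.0]), np.array([-0.1, 0.2]),
                                 np.array([0.3, 0.5]))
        assert list(d.flagged_rows()) == [True, False]
        assert len(d.without_flagged()) == 1

    def test_csv_round_trip(self, ph_burgers, tmp_path):
        data = moduli_from_model(ph_burgers,
                                 2 * np.pi * np.array([0.5, 1, 2, 5, 10, 20, 40.0]),
                                 sem_frac=0.02)
        path = tmp_path / "moduli.csv"
        data.to_csv(path)
        back = ComplexModuliDataset.from_csv(path)
        np.testing.assert_allclose(back.omega, data.omega, rtol=1e-12)
        np.testing.assert_allclose(back.g_prime, data.g_prime, rtol=1e-12)
        np.testing.assert_allclose(back.sem_g_dprime, data.sem_g_dprime, rtol=1e-12)


class TestFitBurgers:
    GRID = np.logspace(np.log10(np.pi), np.log10(80 * np.pi), 10)

    def test_exact_round_trip(self):
        truth = BurgersParameters(0.1, 0.01, 0.43, 0.125)
        fit = fit_burgers(moduli_from_model(truth, self.GRID), weights="relative")
        for name in ("eta0", "tau0", "eta1", "tau1"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=1e-6)
        assert fit.eta == fit.params.eta0 + fit.params.eta1
        assert fit.converged

    def test_crossover_consistency_of_fit(self):
        truth = BurgersParameters(0.1, 0.01, 0.43, 0.125)
        fit = fit_burgers(moduli_from_model(truth, self.GRID), weights="relative")
        wx = fit.omega_x
        gp, gpp = complex_moduli(fit.params, wx)
        assert abs(gp - gpp) / gpp < 1e-9

    def test_noisy_monte_carlo_recovers_viscosity(self):
        """2% multiplicative noise, 200 repeats: median eta within 5% of 0.53."""
        truth = BurgersParameters(0.1, 0.01, 0.43, 0.125)
        base = moduli_from_model(truth, self.GRID)
        rng = np.random.default_rng(7)
        etas = []
        for _ in range(200):
            gp = base.g_prime * (1 + 0.02 * rng.standard_normal(len(base)))
            gpp = base.g_dprime * (1 + 0.02 * rng.standard_normal(len(base)))
            noisy = ComplexModuliDataset(base.omega, gp, np.abs(gpp))
            etas.append(fit_burgers(noisy, weights="relative").eta)
        assert abs(np.median(etas) - 0.53) / 0.53 < 0.05

    def test_newtonian_dataset(self):
        w = self.GRID
        data = ComplexModuliDataset(w, np.zeros_like(w), 0.3 * w)
        fit = fit_burgers(data, weights="relative")
        assert fit.eta == pytest.approx(0.3, rel=1e-6)
        assert fit.params.tau0 == 0.0
        assert fit.params.tau1 < 1e-4 / w[-1] or fit.params.tau1 < 1e-6

    def test_scale_equivariance(self, ph_burgers):
        base = moduli_from_model(ph_burgers, self.GRID)
        c = 7.3
        scaled = ComplexModuliDataset(base.omega, c * base.g_prime, c * base.g_dprime)
        f0 = fit_burgers(base, weights="relative")
        f1 = fit_burgers(scaled, weights="relative")
        assert f1.params.eta0 == pytest.approx(c * f0.params.eta0, rel=1e-6)
        assert f1.params.eta1 == pytest.approx(c * f0.params.eta1, rel=1e-6)
        assert f1.params.tau1 == pytest.approx(f0.params.tau1, rel=1e-6)

    def test_too_few_rows_rejected(self, ph_burgers):
        data = moduli_from_model(ph_burgers, np.array([1.0, 2.0, 4.0]))
        with pytest.raises(ValueError):
            fit_burgers(data)
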