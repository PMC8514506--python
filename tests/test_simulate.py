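"""Synthetic-data generators: spectra, traces, ramps, fusion datasets."""

import math
from dataclasses import replace

import numpy as np
import pytest

from condense_rheo.presets import S_P
from condense_rheo.simulate import (DRIVE_BAND, SimulationConfig,
                                    default_drive_config, driven_response,
                                    medium_response, passive_psd,
                                    simulate_driven_trace,
                                    simulate_fusion_dataset,
                                    simulate_passive_trace,
                                    simulate_rupture_trace,
                                    simulate_stretch_experiment)
from condense_rheo.tension import series_spring, spring_from_tension
from condense_rheo.viscoelastic import BurgersParameters, complex_moduli


class TestMediumResponse:
    def test_newtonian_drag_only(self, water):
        newt = BurgersParameters(0.3, 0.0, 1e-15, 1e-9)
        km, xm = medium_response(newt, 1.0, 2 * math.pi)
        assert km == pytest.approx(0.0, abs=1e-10)
        assert xm == pytest.approx(6 * math.pi * 0.3, rel=1e-6)

    def test_maxwell_at_unit_omega_tau(self):
        p = BurgersParameters(0.0, 0.0, 1.0, 1.0)
        km, xm = medium_response(p, 1.0, 1.0)
        assert km == pytest.approx(6 * math.pi * 0.5, rel=1e-12)
        assert xm == pytest.approx(6 * math.pi * 0.5, rel=1e-12)

    def test_cross_module_identity(self, pkh_burgers):
        w = 2 * math.pi
        km, xm = medium_response(pkh_burgers, 1.0, w)
        gp, gpp = complex_moduli(pkh_burgers, w)
        assert km == pytest.approx(6 * math.pi * gp, rel=1e-12)
        assert xm * w == pytest.approx(6 * math.pi * gpp, rel=1e-12)

    def test_zero_frequency_limit(self, pkh_burgers):
        km, xm = medium_response(pkh_burgers, 1.0, 0.0)
        assert km == 0.0
        assert xm == pytest.approx(6 * math.pi * 0.3, rel=1e-12)


class TestPassivePsd:
    def test_newtonian_lorentzian_reduction(self):
        newt = BurgersParameters(0.3, 0.0, 1e-15, 1e-9)
        cfg = SimulationConfig(trap_stiffness=310.0)
        wc = 310.0 / (6 * math.pi * 0.3)
        p0 = 2 * cfg.kBT / (310.0 * wc)
        w = np.logspace(-2, 3, 50)
        np.testing.assert_allclose(passive_psd(newt, cfg, w),
                                   p0 / ((w / wc) ** 2 + 1), rtol=1e-6)

    def test_high_frequency_asymptote(self, pkh_burgers):
        cfg = SimulationConfig(trap_stiffness=310.0)
        w = 1e5 / pkh_burgers.tau0
        p = pkh_burgers
        kminf = 6 * math.pi * (p.eta0 / p.tau0 + p.eta1 / p.tau1)
        xi = 6 * math.pi * (p.eta0 / (w**2 * p.tau0**2)
                            + p.eta1 / (w**2 * p.tau1**2))
        approx = 2 * cfg.kBT * xi / (310.0 + kminf) ** 2
        assert passive_psd(p, cfg, w) == pytest.approx(approx, rel=1e-3)


class TestPassiveTrace:
    def test_seed_determinism_bit_identical(self, ph_burgers):
        cfg = SimulationConfig(trap_stiffness=310.0, duration=2.0, seed=11)
        a = simulate_passive_trace(ph_burgers, cfg)
        b = simulate_passive_trace(ph_burgers, cfg)
        assert np.array_equal(a.values, b.values)

    def test_seed_required(self, ph_burgers):
        cfg = SimulationConfig(trap_stiffness=310.0, duration=2.0)
        with pytest.raises(ValueError):
            simulate_passive_trace(ph_burgers, cfg)

    def test_equipartition_variance(self):
        """Sample variance matches kBT/kappa_t for a medium with a Newtonian
        component (S:P), averaging over seeds against the Monte-Carlo SE."""
        cfg = SimulationConfig(trap_stiffness=310.0, sampling_rate=1000.0,
                               duration=100.0)
        variances = [simulate_passive_trace(S_P.burgers,
                                            replace(cfg, seed=s)).values.var()
                     for s in range(12)]
        mean = np.mean(variances)
        se = np.std(variances, ddof=1) / math.sqrt(len(variances))
        assert abs(mean - cfg.kBT / 310.0) < 3 * se

    def test_periodogram_matches_lorentzian(self, water):
        """Seed-averaged periodogram of a water trace tracks the closed-form
        Lorentzian bin by bin within 5 SE."""
        from condense_rheo.calibration import periodogram
        cfg = SimulationConfig(trap_stiffness=307.0, sampling_rate=50000.0,
                               duration=0.5)
        specs = []
        for s in range(50):
            tr = simulate_passive_trace(water, replace(cfg, seed=s))
            ps = periodogram(tr, n_segments=25)
            specs.append(ps.density)
        specs = np.asarray(specs)
        mean = specs.mean(axis=0)
        se = specs.std(axis=0, ddof=1) / math.sqrt(len(specs))
        # exclude the Nyquist bin, whose one-sided scaling convention differs
        target = passive_psd(water, cfg, ps.omega)[:-1]
        assert np.all(np.abs(mean[:-1] - target) < 5 * se[:-1] + 1e-30)

    @pytest.mark.parametrize("duration", [5.0, 20.0, 80.0])
    def test_spectral_synthesis_preserves_total_power(self, ph_burgers, duration):
        """Seed-averaged sample variance matches the band integral
        (1/pi) * int P dw at every record length, within 3 SE."""
        cfg = SimulationConfig(trap_stiffness=310.0, sampling_rate=1000.0,
                               duration=duration)
        w = np.logspace(-4, math.log10(math.pi * 1000.0), 4000)
        band = np.trapezoid(passive_psd(ph_burgers, cfg, w), w) / math.pi
        vs = [simulate_passive_trace(ph_burgers, replace(cfg, seed=s)).values.var()
              for s in range(10)]
        se = np.std(vs, ddof=1) / math.sqrt(len(vs))
        assert abs(np.mean(vs) - band) < 3 * se


class TestDrivenTrace:
    def test_newtonian_closed_form(self):
        """kappa_t=310, eta=0.3 Pa s, 1 Hz: F_t0/X_t0 and Delta by hand."""
        newt = BurgersParameters(0.3, 0.0, 1e-15, 1e-9)
        cfg = SimulationConfig(trap_stiffness=310.0)
        w = 2 * math.pi
        xi = 6 * math.pi * 0.3
        ratio, delta = driven_response(newt, cfg, w)
        assert ratio == pytest.approx(
            310.0 * w * xi / math.sqrt(310.0**2 + (w * xi) ** 2), rel=1e-9)
        assert delta == pytest.approx(math.pi / 2 - math.atan(w * xi / 310.0),
                                      rel=1e-9)
        assert ratio == pytest.approx(35.3, abs=0.05)
        assert delta == pytest.approx(1.457, abs=0.001)

    def test_noise_free_is_deterministic_without_seed(self, ph_burgers):
        cfg = SimulationConfig(trap_stiffness=310.0, duration=2.0)  # no seed
        trap, force = simulate_driven_trace(ph_burgers, cfg, 2 * math.pi,
                                            thermal_noise=False)
        assert trap.meta["seed"] is None
        t = trap.times()
        np.testing.assert_allclose(trap.values, np.cos(2 * math.pi * t),
                                   rtol=0, atol=1e-12)

    def test_out_of_band_frequency_rejected(self, ph_burgers):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError):
            simulate_driven_trace(ph_burgers, cfg, DRIVE_BAND[1] * 1.5)

    def test_ground_truth_meta_consistent(self, presets):
        """Recorded (X_t0, F_t0, Delta) reproduce the medium's moduli exactly
        through the oscillation inversion, at every standard frequency."""
        from condense_rheo.rheology import OscillationFit, moduli_from_oscillation
        for preset in presets:
            kt = preset.kappa_t_oscillation
            for f_hz in (0.5, 1, 2, 5, 10, 20, 40):
                w = 2 * math.pi * f_hz
                cfg = SimulationConfig(trap_stiffness=kt, duration=2.0)
                trap, force = simulate_driven_trace(preset.burgers, cfg, w,
                                                    thermal_noise=False)
                fit = OscillationFit(omega=w, x_t0=trap.meta["X_t0_um"], phi=0.0,
                                     b1=0.0, f_t0=force.meta["F_t0_pn"],
                                     delta=force.meta["Delta_rad"], b2=0.0)
                gp, gpp = moduli_from_oscillation(fit, kt, 1.0)
                egp, egpp = complex_moduli(preset.burgers, w)
                assert gp == pytest.approx(egp, rel=1e-9, abs=1e-12)
                assert gpp == pytest.approx(egpp, rel=1e-9)


class TestStretchSimulator:
    def test_rigid_traps_slope_difference(self):
        gamma, R, a, v = 57.1, 5.0, 1.0, 0.05
        cfg = SimulationConfig(sampling_rate=100.0, seed=0)
        _, f1, f2 = simulate_stretch_experiment(gamma, R, a, 1e12, 1e12, v, cfg)
        chi0 = spring_from_tension(gamma, R, a)
        t = f1.times()
        slope_diff = np.polyfit(t, f2.values - f1.values, 1)[0]
        assert slope_diff == pytest.approx(2 * v * chi0, rel=1e-9)

    def test_chi0_hand_value(self):
        # gamma=57.1, R=5, a=1: chi0 = (pi/2) gamma / (-0.5 ln 0.25 + 0.34)
        expected = 0.5 * math.pi * 57.1 / (-0.5 * math.log(0.25) + 0.34)
        assert spring_from_tension(57.1, 5.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_theta0_domain_enforced(self):
        cfg = SimulationConfig(sampling_rate=100.0)
        with pytest.raises(ValueError):
            simulate_stretch_experiment(57.1, 2.5, 1.0, 600, 600, 0.05, cfg)

    def test_ground_truth_in_meta(self):
        cfg = SimulationConfig(sampling_rate=100.0)
        _, f1, _ = simulate_stretch_experiment(57.1, 5.0, 1.0, 600, 600, 0.05, cfg)
        chi0 = spring_from_tension(57.1, 5.0, 1.0)
        assert f1.meta["chi_sys0_pn_per_um"] == pytest.approx(
            series_spring(chi0, 600, 600), rel=1e-12)


class TestRuptureSimulator:
    def test_unit_peak(self):
        cfg = SimulationConfig(sampling_rate=100.0, duration=30.0, seed=2)
        tr = simulate_rupture_trace(1.0 / (2 * math.pi), 1.0, 1.0, 0.1, cfg)
        assert tr.values.max() == pytest.approx(1.0, rel=1e-12)

    def test_paper_like_peak(self):
        cfg = SimulationConfig(sampling_rate=100.0, duration=30.0, seed=2)
        tr = simulate_rupture_trace(57.1, 1.0, 1.1, 0.1, cfg)
        assert tr.values.max() == pytest.approx(2 * math.pi * 1.1 * 57.1, rel=1e-12)
        assert tr.values.max() == pytest.approx(394.65, abs=0.05)

    def test_peak_location_randomised_by_seed(self):
        cfg = SimulationConfig(sampling_rate=100.0, duration=30.0, seed=2)
        t1 = simulate_rupture_trace(57.1, 1.0, 1.1, 0.1, cfg)
        t2 = simulate_rupture_trace(57.1, 1.0, 1.1, 0.1, replace(cfg, seed=3))
        assert t1.meta["t_peak_s"] != t2.meta["t_peak_s"]


class TestFusionSimulator:
    def test_noise_free_proportionality(self):
        data = simulate_fusion_dataset(10.1, [3.0])
        assert data.tau_fu_ms[0] == pytest.approx(30.3, rel=1e-12)

    def test_previous_study_slope(self):
        data = simulate_fusion_dataset(6.7, [3.0])
        assert data.tau_fu_ms[0] == pytest.approx(20.1, rel=1e-12)

    def test_radii_range_enforced(self):
        with pytest.raises(ValueError):
            simulate_fusion_dataset(10.1, [0.5])

    def test_noisy_generation_positive_and_seeded(self):
        radii = np.linspace(0.8, 8.0, 17)
        d1 = simulate_fusion_dataset(10.1, radii, noise_sd=5.0, seed=4)
        d2 = simulate_fusion_dataset(10.1, radii, noise_sd=5.0, seed=4)
        assert np.array_equal(d1.tau_fu_ms, d2.tau_fu_ms)
        assert np.all(d1.tau_fu_ms > 0)


def test_default_drive_config_period_coverage():
    cfg = SimulationConfig(seed=0)
    for f in (0.5, 1, 2, 5, 10, 20, 40):
        c = default_drive_config(cfg, f)
        assert c.duration * f >= 5  # at least 5 periods everywhere
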