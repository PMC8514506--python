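"""End-to-end synthetic-experiment pipelines.

These functions chain the generators and the analysis stages exactly the
way a measurement campaign would: simulate driven trace pairs -> cosine
fits -> moduli -> replicate aggregation -> Burgers fit (rheology); simulate
stretching ramps -> slope fits -> series-spring inversion -> tension; and
the umbrella :func:`run_pipeline` that produces a full materials-and-fusion
report for every condensate preset from a single top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import fusion, presets, rheology, tension
from .calibration import (active_passive_calibrate, fit_stretched_lorentzian,
                          log_bin, periodogram)
from .simulate import (KBT_ROOM, SimulationConfig, default_drive_config,
                       simulate_driven_trace, simulate_fusion_dataset,
                       simulate_passive_trace, simulate_rupture_trace,
                       simulate_stretch_experiment)
from .viscoelastic import BurgersFit, BurgersParameters, fit_burgers

logger = logging.getLogger("condense_rheo")


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds (< 2^31) derived from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def measure_moduli(
    params: BurgersParameters,
    kappa_t: float,
    seed: int,
    freqs_hz=presets.STANDARD_FREQS_HZ,
    n_replicates: int = 3,
    amplitude: float = 1.0,
    bead_radius: float = 1.0,
    thermal_noise: bool = True,
):
    """Synthetic oscillatory-rheology campaign -> aggregated moduli dataset.

    Simulates trap/force trace pairs for each frequency and replicate,
    cosine-fits both channels, converts to moduli, and aggregates replicates
    into a mean +/- SEM dataset.
    """
    seeds = iter(child_seeds(seed, n_replicates * len(freqs_hz)))
    reps = []
    for _ in range(n_replicates):
        pairs = []
        for f_hz in freqs_hz:
            omega = 2 * np.pi * f_hz
            cfg = default_drive_config(
                SimulationConfig(trap_stiffness=kappa_t, bead_radius=bead_radius,
                                 seed=next(seeds)),
                f_hz,
            )
            trap, force = simulate_driven_trace(
                params, cfg, omega, amplitude=amplitude,
                thermal_noise=thermal_noise)
            pairs.append((trap, force, omega))
        reps.append(rheology.moduli_dataset_from_pairs(pairs, kappa_t, bead_radius))
    if n_replicates == 1:
        return reps[0]
    return rheology.aggregate_replicates(reps)


def recover_viscosity(
    params: BurgersParameters,
    kappa_t: float,
    seed: int,
    freqs_hz=presets.STANDARD_FREQS_HZ,
    n_replicates: int = 3,
) -> BurgersFit:
    """Full rheology pipeline: driven traces -> moduli -> Burgers fit."""
    data = measure_moduli(params, kappa_t, seed, freqs_hz, n_replicates)
    weights = "sem" if n_replicates > 1 else "relative"
    return fit_burgers(data, weights=weights)


def recover_tension_stretch(
    gamma: float,
    seed: int,
    R: float = 5.0,
    a: float = 1.0,
    kappa_t1: float = 600.0,
    kappa_t2: float = 600.0,
    v: float = 0.05,
    noise_frac: float = 0.01,
    sampling_rate: float = 100.0,
) -> tension.TensionResult:
    """Stretch a synthetic droplet and analyse it back to a tension.

    ``noise_frac`` scales additive force noise to the final ramp force
    (v * pull_time * chi_sys0), mimicking a stated percentage force noise.
    """
    from .tension import series_spring, spring_from_tension

    chi_sys0 = series_spring(spring_from_tension(gamma, R, a), kappa_t1, kappa_t2)
    noise_sd = noise_frac * 0.5 * chi_sys0  # pull distance is 0.5 um
    cfg = SimulationConfig(trap_stiffness=kappa_t1, sampling_rate=sampling_rate,
                           duration=0.5 / v, seed=seed)
    _, f1, f2 = simulate_stretch_experiment(
        gamma, R, a, kappa_t1, kappa_t2, v, cfg, noise_sd=noise_sd)
    exp = tension.StretchExperiment(kappa_t1=kappa_t1, kappa_t2=kappa_t2, v=v,
                                    force1=f1, force2=f2, R=R, a=a)
    return tension.analyze_stretch(exp)


def recover_tension_rupture(
    gamma: float,
    seed: int,
    a: float = 1.0,
    f: float = tension.DEFAULT_RUPTURE_GEOMETRY_FACTOR,
    v: float = 0.1,
    noise_sd: float = 0.5,
    duration: float = 30.0,
    sampling_rate: float = 100.0,
) -> tension.TensionResult:
    """Rupture a synthetic droplet surface and read the tension back."""
    cfg = SimulationConfig(sampling_rate=sampling_rate, duration=duration, seed=seed)
    trace = simulate_rupture_trace(gamma, a, f, v, cfg, noise_sd=noise_sd)
    return tension.tension_from_rupture(trace, a, f)


def calibrate_synthetic(
    params: BurgersParameters,
    kappa_t: float,
    epsilon: float,
    seed: int,
    drive_freq_hz: float = 0.2,
    duration: float = 200.0,
    sampling_rate: float = 500.0,
    n_segments: int = 10,
    bead_radius: float = 1.0,
    band_limit_hz: float | None = 10.0,
    drive_duration: float = 100.0,
):
    """Active-passive calibration round trip on volt-unit synthetic traces.

    Generates a passive volt trace and a low-frequency driven pair with the
    detector conversion ``epsilon`` (um/V) hidden, then recovers both
    kappa_t and epsilon from the volt data alone.  ``band_limit_hz``
    restricts the stretched-Lorentzian fit to the band the model can
    represent (droplet spectra have sub-10-Hz corners); pass None to fit the
    whole sampled band, as appropriate for Newtonian media whose spectrum is
    exactly Lorentzian.
    """
    from .calibration import PowerSpectrum

    s_passive, s_drive = child_seeds(seed, 2)
    cfg = SimulationConfig(trap_stiffness=kappa_t, bead_radius=bead_radius,
                           sampling_rate=sampling_rate, duration=duration,
                           seed=s_passive, volt_per_um=1.0 / epsilon)
    passive_v = simulate_passive_trace(params, cfg)
    ps_v = periodogram(passive_v, n_segments=n_segments)
    if band_limit_hz is not None:
        keep = ps_v.omega <= 2 * np.pi * band_limit_hz
        ps_v = PowerSpectrum(ps_v.omega[keep], ps_v.density[keep],
                             ps_v.unit, ps_v.n_averages)
    ps_v = log_bin(ps_v)
    fit = fit_stretched_lorentzian(ps_v)

    omega = 2 * np.pi * drive_freq_hz
    cfg_d = replace(cfg, seed=s_drive, duration=drive_duration)
    trap, force_v = simulate_driven_trace(params, cfg_d, omega, amplitude=1.0,
                                          thermal_noise=True)
    drive = rheology.fit_oscillation(trap, force_v, omega)
    return active_passive_calibrate(ps_v, fit, drive, cfg.kBT)


def fusion_summary(
    preset: presets.CondensatePreset,
    eta: float,
    gamma: float,
    tau1_ms: float,
    seed: int,
    n_droplets: int = 17,
    noise_sd_ms: float | None = None,
    R_ref: float = 3.0,
) -> fusion.CondensateSummary:
    """Simulate a fusion campaign for a preset and summarise it against the
    viscocapillary prediction using the supplied material properties."""
    rng = np.random.default_rng(seed)
    radii = rng.uniform(0.8, 8.0, n_droplets)
    if noise_sd_ms is None:
        noise_sd_ms = 0.1 * preset.inverse_fusion_speed * 3.0
    data = simulate_fusion_dataset(preset.inverse_fusion_speed, radii,
                                   noise_sd=noise_sd_ms, seed=seed)
    slope, se = fusion.fit_fusion_speed(data)
    return fusion.derived_metrics(preset.name, eta, gamma, tau1_ms, slope, se,
                                  R_ref=R_ref)


def run_pipeline(seed: int, out_dir, quick: bool = False) -> dict:
    """Full synthetic campaign over all four condensate presets.

    For each preset: oscillatory rheology (eta, tau1), droplet stretching
    and rupture (gamma), fusion-speed fitting, and the viscocapillary
    comparison; writes moduli CSVs, fit JSONs, and the final summary table
    under ``out_dir``.  Everything derives from the single ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_rep = 2 if quick else 3
    summaries = []
    records = {}
    for preset, s in zip(presets.ALL_PRESETS, child_seeds(seed, len(presets.ALL_PRESETS))):
        s_rheo, s_stretch, s_rupture, s_fusion = child_seeds(s, 4)
        logger.info("[%s] rheology: %d replicates at %s Hz, kappa_t=%g pN/um",
                    preset.name, n_rep, list(presets.STANDARD_FREQS_HZ),
                    preset.kappa_t_oscillation)
        data = measure_moduli(preset.burgers, preset.kappa_t_oscillation,
                              s_rheo, n_replicates=n_rep)
        fit = fit_burgers(data, weights="sem")
        tag = preset.name.replace(":", "_")
        data.to_csv(out / f"moduli_{tag}.csv")
        (out / f"burgers_fit_{tag}.json").write_text(fit.to_json())

        logger.info("[%s] tension: stretch + rupture", preset.name)
        t_stretch = recover_tension_stretch(preset.gamma, s_stretch)
        t_rupture = recover_tension_rupture(preset.gamma, s_rupture)

        summary = fusion_summary(preset, eta=fit.eta, gamma=t_stretch.gamma,
                                 tau1_ms=fit.params.tau1 * 1e3, seed=s_fusion)
        summaries.append(summary)
        records[preset.name] = {
            "eta_pa_s": fit.eta,
            "tau1_ms": fit.params.tau1 * 1e3,
            "gamma_stretch_pn_per_um": t_stretch.gamma,
            "gamma_rupture_pn_per_um": t_rupture.gamma,
            **summary.as_record(),
        }
    text, df = fusion.table_report(summaries)
    df.to_csv(out / "summary_table.csv", index=False)
    report = {"seed": seed, "condensates": records}
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("summary:\n%s", text)
    return report
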