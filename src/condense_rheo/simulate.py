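"""Synthetic optical-tweezer experiments with known ground truth.

Every input the analysis pipeline consumes can be generated here from a
Burgers-medium description and a trap configuration, with seeded randomness:

* passive thermal bead-position traces (stationary Gaussian process whose
  one-sided power spectrum is the overdamped trapped-bead spectrum),
* sinusoidally driven trap/force trace pairs at 0.5-40 Hz,
* linear-ramp two-trap droplet-stretching force traces,
* bead-rupture force ramps,
* (radius, fusion time) datasets with tau_fu proportional to R.

Physics conventions: inertia is neglected throughout (the inertial corner of
a 1-um bead in media of >= 0.3 Pa s lies far above the experimental band),
and drag uses the unbounded-medium Stokes coefficient 6*pi*eta*a (beads sit
several diameters from any boundary).  Passive traces are synthesised in the
frequency domain - independent complex Gaussian Fourier coefficients with
variance proportional to the target spectrum, Hermitian symmetry, inverse
FFT - which realises the target spectrum exactly, with no time-stepping
discretisation bias.  Thermal noise on driven force traces is kappa_t times
the passive bead-position process, i.e. it has the same thermal origin as
the passive fluctuations rather than being white.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .fusion import FusionDataset
from .tension import series_spring, spring_from_tension
from .trace import TimeTrace
from .viscoelastic import BurgersParameters, complex_moduli

#: thermal energy at 298.15 K, pN um
KBT_ROOM = 4.116e-3

#: admissible sinusoidal drive band, rad/s
DRIVE_BAND = (2 * math.pi * 0.1, 2 * math.pi * 100.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Bead/trap/sampling configuration shared by the generators.

    ``volt_per_um``, when set, makes position output channels volt-valued
    (value_V = value_um * volt_per_um) and force channels raw detector
    volts (F_V = F_pN * volt_per_um / kappa_t), emulating an uncalibrated
    quadrant photodiode with conversion factor epsilon = 1/volt_per_um.
    """

    trap_stiffness: float = 310.0   # pN/um
    bead_radius: float = 1.0        # um
    kBT: float = KBT_ROOM           # pN um
    sampling_rate: float = 1000.0   # Hz
    duration: float = 10.0          # s
    seed: int | None = None
    volt_per_um: float | None = None

    def __post_init__(self) -> None:
        if min(self.trap_stiffness, self.bead_radius, self.kBT,
               self.sampling_rate, self.duration) <= 0:
            raise ValueError("all physical configuration values must be > 0")
        if self.volt_per_um is not None and self.volt_per_um <= 0:
            raise ValueError("volt_per_um must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")
        return np.random.default_rng(self.seed)


def medium_response(
    params: BurgersParameters, a: float, omega: float
) -> tuple[float, float]:
    """Medium spring constant and friction coefficient seen by a bead.

    6*pi*a*G*(omega) = kappa_m + i*omega*xi_m, so kappa_m = 6*pi*a*G'(omega)
    (pN/um) and xi_m = 6*pi*a*G''(omega)/omega (pN s/um).  At omega = 0 the
    analytic limit (0, 6*pi*a*(eta0+eta1)) is returned.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    pref = 6.0 * math.pi * a
    if omega == 0.0:
        return 0.0, pref * (params.eta0 + params.eta1)
    gp, gpp = complex_moduli(params, omega)
    return pref * gp, pref * gpp / omega


def passive_psd(params: BurgersParameters, cfg: SimulationConfig, omega):
    """One-sided position power spectrum of the trapped bead, um^2 s.

    P_x(omega) = 2 kBT xi_m(omega) / |kappa_t + kappa_m(omega)
    + i omega xi_m(omega)|^2, with bead inertia dropped (overdamped limit).
    Normalisation: C_x(0) = (1/pi) * integral_0^inf P_x(omega) d omega.
    """
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    pref = 6.0 * math.pi * cfg.bead_radius
    gp, gpp = complex_moduli(params, w)
    kappa_m = pref * np.asarray(gp)
    omega_xi = pref * np.asarray(gpp)          # omega * xi_m
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.where(w > 0, omega_xi / w, np.nan)
    denom = (cfg.trap_stiffness + kappa_m) ** 2 + omega_xi**2
    p = 2.0 * cfg.kBT * xi / denom
    # analytic omega -> 0 limit for convenience on grids that include 0
    zero = w == 0
    if np.any(zero):
        xi0 = pref * (params.eta0 + params.eta1)
        p = np.where(zero, 2.0 * cfg.kBT * xi0 / cfg.trap_stiffness**2, p)
    return p if np.asarray(omega).ndim else float(p[0])


def _synthesize_gaussian(psd_omega, cfg: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean Gaussian samples whose one-sided PSD (in the
    C_x(0) = (1/pi) int P domega convention) is ``psd_omega``."""
    n = cfg.n_samples
    dt = cfg.dt
    freqs = np.fft.rfftfreq(n, dt)              # Hz
    # per-Hz one-sided density S(f) = 2 P_x(2 pi f)
    s_f = 2.0 * psd_omega(2.0 * math.pi * np.maximum(freqs, 1e-300))
    coeffs = np.zeros(freqs.size, dtype=complex)
    interior = slice(1, -1 if n % 2 == 0 else None)
    n_int = freqs[interior].size
    sigma = np.sqrt(n * s_f[interior] / (4.0 * dt))
    coeffs[interior] = sigma * (rng.standard_normal(n_int)
                                + 1j * rng.standard_normal(n_int))
    if n % 2 == 0:
        coeffs[-1] = math.sqrt(n * s_f[-1] / (2.0 * dt)) * rng.standard_normal()
    coeffs[0] = 0.0  # zero mean
    return np.fft.irfft(coeffs, n=n)


def simulate_passive_trace(
    params: BurgersParameters, cfg: SimulationConfig
) -> TimeTrace:
    """Thermal bead-position trace of a trapped bead in a Burgers medium.

    Frequency-domain synthesis against :func:`passive_psd`; bit-identical
    for identical (parameters, seed).  Requires >= 1024 samples.
    """
    if cfg.n_samples < 2**10:
        raise ValueError("need duration * sampling_rate >= 1024 samples")
    rng = cfg.rng()
    x_um = _synthesize_gaussian(lambda w: passive_psd(params, cfg, w), cfg, rng)
    meta = {
        "generator": "simulate_passive_trace",
        "seed": cfg.seed,
        "burgers": [params.eta0, params.tau0, params.eta1, params.tau1],
        "kappa_t_pn_per_um": cfg.trap_stiffness,
        "kBT_pn_um": cfg.kBT,
        "bead_radius_um": cfg.bead_radius,
    }
    if cfg.volt_per_um is None:
        return TimeTrace(0.0, cfg.dt, x_um, "bead_position_um", meta)
    meta["volt_per_um"] = cfg.volt_per_um
    return TimeTrace(0.0, cfg.dt, x_um * cfg.volt_per_um, "bead_position_v", meta)


def driven_response(
    params: BurgersParameters, cfg: SimulationConfig, omega: float
) -> tuple[float, float]:
    """Steady-state force response to a unit-amplitude sinusoidal trap drive.

    Returns (F_t0/X_t0 in pN/um, Delta in rad) solving the overdamped force
    balance: with Z = kappa_m + i omega xi_m, the trapping-force phasor is
    kappa_t * Z / (kappa_t + Z) times the trap-position phasor.
    """
    kappa_m, xi_m = medium_response(params, cfg.bead_radius, omega)
    z = kappa_m + 1j * omega * xi_m
    h = cfg.trap_stiffness * z / (cfg.trap_stiffness + z)
    return abs(h), math.atan2(h.imag, h.real)


def simulate_driven_trace(
    params: BurgersParameters,
    cfg: SimulationConfig,
    omega: float,
    amplitude: float = 1.0,
    phase: float = 0.0,
    thermal_noise: bool = True,
) -> tuple[TimeTrace, TimeTrace]:
    """Trap-position and trapping-force traces for a sinusoidally driven trap.

    The deterministic branch is the exact steady-state solution (the initial
    transient is never emitted), so with ``thermal_noise=False`` the output
    involves no stochastic calls at all.  With noise, the force trace gains
    -kappa_t times a passive thermal position trace.
    """
    if not DRIVE_BAND[0] <= omega <= DRIVE_BAND[1]:
        raise ValueError("drive frequency outside the 0.1-100 Hz band")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    ratio, delta_phase = driven_response(params, cfg, omega)
    f_t0 = ratio * amplitude
    t = np.arange(cfg.n_samples) * cfg.dt
    trap = amplitude * np.cos(omega * t + phase)
    force = f_t0 * np.cos(omega * t + phase + delta_phase)
    if thermal_noise:
        rng = cfg.rng()
        x_th = _synthesize_gaussian(lambda w: passive_psd(params, cfg, w), cfg, rng)
        force = force - cfg.trap_stiffness * x_th
    meta = {
        "generator": "simulate_driven_trace",
        "seed": cfg.seed if thermal_noise else None,
        "burgers": [params.eta0, params.tau0, params.eta1, params.tau1],
        "kappa_t_pn_per_um": cfg.trap_stiffness,
        "omega_rad_s": omega,
        "X_t0_um": amplitude,
        "F_t0_pn": f_t0,
        "Delta_rad": delta_phase,
        "phi_rad": phase,
    }
    if cfg.volt_per_um is None:
        trap_tr = TimeTrace(0.0, cfg.dt, trap, "trap_position_um", meta)
        force_tr = TimeTrace(0.0, cfg.dt, force, "force_pn", meta)
    else:
        meta = {**meta, "volt_per_um": cfg.volt_per_um}
        # trap position is commanded in um by the instrument; the raw force
        # channel is the bead-trap displacement read in volts
        trap_tr = TimeTrace(0.0, cfg.dt, trap, "trap_position_um", meta)
        force_v = force * cfg.volt_per_um / cfg.trap_stiffness
        force_tr = TimeTrace(0.0, cfg.dt, force_v, "force_v", meta)
    return trap_tr, force_tr


def default_drive_config(cfg: SimulationConfig, freq_hz: float) -> SimulationConfig:
    """Sampling policy for oscillation experiments: 10 s at 1 kHz for drives
    up to 10 Hz, 2 s at 4 kHz above (always >= 20 periods)."""
    if freq_hz <= 10.0:
        return replace(cfg, sampling_rate=1000.0, duration=10.0)
    return replace(cfg, sampling_rate=4000.0, duration=2.0)


def simulate_stretch_experiment(
    gamma: float,
    R: float,
    a: float,
    kappa_t1: float,
    kappa_t2: float,
    v: float,
    cfg: SimulationConfig,
    noise_sd: float = 0.0,
    pull_distance: float = 0.5,
) -> tuple[TimeTrace, TimeTrace, TimeTrace]:
    """Two-trap droplet-stretching traces: trap-1 position ramp plus the two
    force ramps with slopes -/+ v*chi_sys0 and additive Gaussian noise.

    chi0 follows from the tension and geometry; chi_sys0 composes the droplet
    and both traps as springs in series.  Ground truth lands in ``meta``.
    """
    if v <= 0:
        raise ValueError("pulling speed must be > 0")
    chi0 = spring_from_tension(gamma, R, a)  # validates theta0 <= 0.5
    chi_sys0 = series_spring(chi0, kappa_t1, kappa_t2)
    duration = pull_distance / v
    n = max(int(round(duration * cfg.sampling_rate)), 2)
    t = np.arange(n) * cfg.dt
    slope = v * chi_sys0
    pos1 = -v * t
    f1 = -slope * t
    f2 = slope * t
    if noise_sd > 0:
        rng = cfg.rng()
        f1 = f1 + rng.normal(0.0, noise_sd, n)
        f2 = f2 + rng.normal(0.0, noise_sd, n)
    meta = {
        "generator": "simulate_stretch_experiment",
        "seed": cfg.seed if noise_sd > 0 else None,
        "gamma_pn_per_um": gamma, "R_um": R, "a_um": a,
        "kappa_t1_pn_per_um": kappa_t1, "kappa_t2_pn_per_um": kappa_t2,
        "v_um_per_s": v, "chi0_pn_per_um": chi0,
        "chi_sys0_pn_per_um": chi_sys0, "noise_sd_pn": noise_sd,
    }
    return (
        TimeTrace(0.0, cfg.dt, pos1, "trap_position_um", meta),
        TimeTrace(0.0, cfg.dt, f1, "force_pn", meta),
        TimeTrace(0.0, cfg.dt, f2, "force_pn", meta),
    )


def simulate_rupture_trace(
    gamma: float,
    a: float,
    f: float,
    v: float,
    cfg: SimulationConfig,
    noise_sd: float = 0.0,
) -> TimeTrace:
    """Force ramp of a bead pulled through the droplet surface.

    The force climbs linearly to F_rup = 2*pi*a*f*gamma at a seed-randomised
    rupture time within the configured duration, then collapses to ~0.
    """
    if f <= 0 or gamma <= 0 or a <= 0 or v <= 0:
        raise ValueError("gamma, a, f, v must be positive")
    f_rup = 2.0 * math.pi * a * f * gamma
    n = cfg.n_samples
    t = np.arange(n) * cfg.dt
    rng = cfg.rng()
    t_peak = float(rng.uniform(0.6, 0.9)) * cfg.duration
    force = np.where(t <= t_peak, f_rup * t / t_peak, 0.0)
    # make the last pre-rupture sample hit the peak exactly
    i_peak = int(np.searchsorted(t, t_peak, side="right")) - 1
    force[i_peak] = f_rup
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, n)
    meta = {
        "generator": "simulate_rupture_trace", "seed": cfg.seed,
        "gamma_pn_per_um": gamma, "a_um": a, "f": f,
        "F_rup_pn": f_rup, "t_peak_s": t_peak, "noise_sd_pn": noise_sd,
    }
    return TimeTrace(0.0, cfg.dt, force, "force_pn", meta)


def simulate_fusion_dataset(
    inverse_speed: float,
    radii,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FusionDataset:
    """(radius, fusion time) dataset with tau_fu = inverse_speed * R plus
    Gaussian noise (ms), truncated to stay positive."""
    r = np.asarray(radii, dtype=float)
    if inverse_speed <= 0:
        raise ValueError("inverse fusion speed must be > 0")
    if np.any(r < 0.8) or np.any(r > 8.0):
        raise ValueError("radii outside the studied 0.8-8 um range")
    tau = inverse_speed * r
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is mandatory for noisy generation")
        rng = np.random.default_rng(seed)
        noisy = tau + rng.normal(0.0, noise_sd, r.size)
        # redraw any non-positive values (truncation of the noise law)
        for _ in range(1000):
            bad = noisy <= 0
            if not np.any(bad):
                break
            noisy[bad] = tau[bad] + rng.normal(0.0, noise_sd, int(bad.sum()))
        tau = np.maximum(noisy, 1e-9)
    meta = {"generator": "simulate_fusion_dataset", "seed": seed,
            "inverse_speed_ms_per_um": inverse_speed, "noise_sd_ms": noise_sd}
    return FusionDataset(r, tau, meta)
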