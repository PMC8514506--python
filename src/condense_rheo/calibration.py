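"""Trap-stiffness and detector calibration from passive and driven traces.

Passive route: the position power spectrum of a bead trapped in a Newtonian
medium is Lorentzian, P(w) = P(0)/((w/w_c)^2 + 1), with corner
w_c = kappa_t/(6 pi eta a); in a viscoelastic medium the spectrum flattens
differently and is fit by a "stretched" Lorentzian
P(w) = P(0)/((w/w_eff)^alpha + 1) with alpha in (1, 3].

Active-passive route (no second laser, no piezo stage): the detector reports
volts, so the spectrum P_V carries an unknown volt-to-um factor epsilon.
Equipartition applied to the fitted stretched Lorentzian gives the first
identity,

    kappa_t * epsilon^2 = alpha sin(pi/alpha) kBT / (w_eff P_V(0)),

and driving the trap sinusoidally while reading the raw force amplitude
F_V0 and phase lag Delta gives the second; combining them,

    epsilon = [(alpha/2) sin(pi/alpha) (w/w_eff) / ((w/w_eff)^alpha + 1)]
              * X_t0 / (F_V0 sin Delta).

Both kappa_t and epsilon then follow from volt-unit data alone.

Spectral-density convention throughout: one-sided in angular frequency with
C_x(0) = (1/pi) * integral_0^inf P(w) dw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .rheology import OscillationFit
from .trace import TimeTrace


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided spectral density on an angular-frequency grid (unit^2 s)."""

    omega: np.ndarray
    density: np.ndarray
    unit: str = "um"
    n_averages: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if w.shape != d.shape or w.ndim != 1:
            raise ValueError("omega and density must be 1-d and equal length")
        if np.any(w <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("omega must be positive and increasing")
        if np.any(d < 0):
            raise ValueError("spectral density must be non-negative")
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "density", d)

    def total_variance(self) -> float:
        """(1/pi) * integral P dw over the sampled band (trapezoid rule)."""
        return float(np.trapezoid(self.density, self.omega) / math.pi)


def periodogram(trace: TimeTrace, n_segments: int = 1) -> PowerSpectrum:
    """Welch-averaged one-sided spectrum of a trace.

    Segments use a boxcar window without overlap so that a pure sinusoid
    keeps its spectral mass in one bin; normalisation is such that
    (1/pi) * integral P dw equals the sample variance.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    nperseg = trace.n // n_segments
    if nperseg < 2:
        raise ValueError("trace too short for the requested number of segments")
    freqs, s_f = signal.welch(
        trace.values, fs=trace.sampling_rate, window="boxcar",
        nperseg=nperseg, noverlap=0, detrend="constant", scaling="density",
    )
    # S(f) df-normalised -> P(w) with variance = (1/pi) int P dw
    keep = freqs > 0
    unit = "V" if trace.channel.endswith("_v") else "um"
    return PowerSpectrum(2.0 * math.pi * freqs[keep], s_f[keep] / 2.0,
                         unit=unit, n_averages=n_segments)


def log_bin(ps: PowerSpectrum, bins_per_decade: int = 12) -> PowerSpectrum:
    """Octave-smooth a spectrum onto logarithmically spaced bins.

    Densities are averaged arithmetically per bin (periodogram noise is
    multiplicative, so downstream fits run on the log of these averages).
    """
    w = ps.omega
    edges = np.logspace(math.log10(w[0] * 0.999), math.log10(w[-1] * 1.001),
                        max(int(math.log10(w[-1] / w[0]) * bins_per_decade), 2) + 1)
    idx = np.digitize(w, edges) - 1
    wc, dc = [], []
    for b in range(edges.size - 1):
        m = idx == b
        if np.any(m):
            wc.append(np.exp(np.mean(np.log(w[m]))))
            dc.append(float(np.mean(ps.density[m])))
    return PowerSpectrum(np.array(wc), np.array(dc), ps.unit, ps.n_averages)


@dataclass(frozen=True)
class SpectrumFit:
    """Fitted (stretched-)Lorentzian spectrum parameters."""

    p0: float
    omega_eff: float
    alpha: float
    residual: float
    model: str  # "lorentzian" | "stretched"
    corner_in_band: bool = True

    def __post_init__(self) -> None:
        if self.p0 <= 0 or self.omega_eff <= 0:
            raise ValueError("p0 and omega_eff must be positive")
        if self.model == "lorentzian" and self.alpha != 2.0:
            raise ValueError("lorentzian model fixes alpha = 2")
        if self.model == "stretched" and not (1.0 < self.alpha <= 3.0):
            raise ValueError("stretched alpha must lie in (1, 3]")

    def density(self, omega) -> np.ndarray:
        w = np.asarray(omega, dtype=float)
        return self.p0 / ((w / self.omega_eff) ** self.alpha + 1.0)

    def integrated_variance(self) -> float:
        """(1/pi) * integral_0^inf of the fitted model, closed form:
        P(0) * w_eff / (alpha sin(pi/alpha))."""
        return self.p0 * self.omega_eff / (self.alpha * math.sin(math.pi / self.alpha))


def _fit_spectrum(ps: PowerSpectrum, alpha_free: bool) -> SpectrumFit:
    w = ps.omega
    d = np.maximum(ps.density, 1e-300)
    logd = np.log(d)
    p0_guess = float(np.exp(np.mean(logd[: max(w.size // 20, 3)])))
    # corner guess: where density first falls below half the plateau
    below = np.nonzero(d < 0.5 * p0_guess)[0]
    wc_guess = float(w[below[0]]) if below.size else float(w[w.size // 2])

    def resid(x):
        lp0, lwe = x[0], x[1]
        alpha = x[2] if alpha_free else 2.0
        model = lp0 - np.log((w / math.exp(lwe)) ** alpha + 1.0)
        return model - logd

    x0 = [math.log(p0_guess), math.log(wc_guess)]
    lb = [-300.0, math.log(w[0] * 1e-3)]
    ub = [300.0, math.log(w[-1] * 1e3)]
    if alpha_free:
        x0.append(2.0)
        lb.append(1.0 + 1e-9)
        ub.append(3.0)
    res = optimize.least_squares(resid, x0, bounds=(lb, ub),
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p0 = math.exp(res.x[0])
    omega_eff = math.exp(res.x[1])
    alpha = float(res.x[2]) if alpha_free else 2.0
    return SpectrumFit(
        p0=p0, omega_eff=omega_eff, alpha=alpha,
        residual=float(2.0 * res.cost),
        model="stretched" if alpha_free else "lorentzian",
        corner_in_band=bool(w[0] <= omega_eff <= w[-1]),
    )


def fit_lorentzian(ps: PowerSpectrum) -> SpectrumFit:
    """Least-squares Lorentzian fit in log-density space (alpha fixed at 2).

    ``corner_in_band=False`` flags a low-confidence fit whose corner fell
    outside the sampled band.
    """
    if ps.omega.size < 8:
        raise ValueError("need at least 8 frequency bins")
    return _fit_spectrum(ps, alpha_free=False)


def fit_stretched_lorentzian(ps: PowerSpectrum) -> SpectrumFit:
    """Joint (p0, omega_eff, alpha) fit in log-density space, alpha in (1, 3]."""
    if ps.omega.size < 8:
        raise ValueError("need at least 8 frequency bins")
    return _fit_spectrum(ps, alpha_free=True)


def stiffness_from_corner(omega_c: float, a: float, eta_medium: float) -> float:
    """kappa_t = omega_c * 6 pi eta a (pN/um), the Newtonian corner relation."""
    if min(omega_c, a, eta_medium) <= 0:
        raise ValueError("omega_c, a, eta must be positive")
    return omega_c * 6.0 * math.pi * eta_medium * a


@dataclass(frozen=True)
class TrapCalibration:
    """Trap stiffness and volt-to-um conversion with provenance."""

    kappa_t: float               # pN/um
    epsilon: float = 1.0         # um/V; 1.0 when traces are already in um
    method: str = "corner"       # "corner" | "active_passive"
    kBT: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa_t <= 0 or self.epsilon <= 0:
            raise ValueError("kappa_t and epsilon must be positive")

    def force_to_pn(self, force_v: np.ndarray) -> np.ndarray:
        """F_t = kappa_t * epsilon * F_V."""
        return self.kappa_t * self.epsilon * np.asarray(force_v, dtype=float)

    def position_to_um(self, x_v: np.ndarray) -> np.ndarray:
        return self.epsilon * np.asarray(x_v, dtype=float)


def active_passive_calibrate(
    ps_v: PowerSpectrum,
    fit: SpectrumFit,
    drive: OscillationFit,
    kBT: float,
) -> TrapCalibration:
    """Joint stiffness + detector calibration from volt-unit data.

    ``ps_v`` is the passive spectrum in V^2 s, ``fit`` its stretched-
    Lorentzian fit, and ``drive`` the cosine-fit of a low-frequency drive
    whose trap amplitude ``x_t0`` is known in um (commanded by the
    instrument) while the force amplitude ``f_t0`` is the raw F_V0 in volts.
    """
    if not (1.0 < fit.alpha <= 3.0):
        raise ValueError("alpha outside (1, 3]")
    sin_delta = math.sin(drive.delta)
    if sin_delta <= 0:
        raise ValueError("sin Delta <= 0: unphysical drive phase")
    alpha, w_eff = fit.alpha, fit.omega_eff
    w = drive.omega
    shape = (w / w_eff) / ((w / w_eff) ** alpha + 1.0)
    epsilon = (0.5 * alpha * math.sin(math.pi / alpha) * shape
               * drive.x_t0 / (drive.f_t0 * sin_delta))
    kappa_t = (alpha * math.sin(math.pi / alpha) * kBT
               / (w_eff * fit.p0 * epsilon**2))
    return TrapCalibration(
        kappa_t=kappa_t, epsilon=epsilon, method="active_passive", kBT=kBT,
        provenance={
            "alpha": alpha, "omega_eff_rad_s": w_eff, "p_v0": fit.p0,
            "drive_omega_rad_s": w, "x_t0_um": drive.x_t0,
            "f_v0_v": drive.f_t0, "delta_rad": drive.delta,
            "spectrum_n_averages": ps_v.n_averages,
        },
    )
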