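"""Oscillatory micro-rheology: cosine fits of driven traces to complex moduli.

An optically trapped bead driven sinusoidally inside a viscoelastic medium
reports the medium's complex modulus.  Both the trap-position and the
trapping-force traces are fit to cosine waves at the (known) drive frequency,

    X_t = X_t0 cos(w t + phi) + B1,
    F_t = F_t0 cos(w t + phi + Delta) + B2,

and the moduli follow from the amplitude ratio and phase lag with
Upsilon = F_t0/(kappa_t X_t0):

    G'(w)  = F_t0/(6 pi a X_t0) * (cos Delta - Upsilon) / ((cos Delta - Upsilon)^2 + sin^2 Delta)
    G''(w) = F_t0/(6 pi a X_t0) * sin Delta             / ((cos Delta - Upsilon)^2 + sin^2 Delta)

G'' > 0 whenever sin Delta > 0 (dissipation); noisy G' may come out
negative and is flagged rather than clipped.  Replicate per-droplet moduli
on a shared frequency grid aggregate into mean +/- SEM datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace import TimeTrace
from .viscoelastic import ComplexModuliDataset


def fit_cosine(trace: TimeTrace, omega: float) -> tuple[float, float, float]:
    """Linear least-squares cosine fit at a known drive frequency.

    Returns (amplitude, phase, offset) with amplitude >= 0 and phase in
    (-pi, pi].  The trace must span at least two full periods.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    period = 2.0 * math.pi / omega
    if trace.duration < 2.0 * period:
        raise ValueError("trace must span at least 2 full drive periods")
    t = trace.times()
    basis = np.column_stack([np.cos(omega * t), np.sin(omega * t), np.ones_like(t)])
    (a, b, c), *_ = np.linalg.lstsq(basis, trace.values, rcond=None)
    amplitude = math.hypot(a, b)
    phase = math.atan2(-b, a)  # a cos + b sin = A cos(wt + phi)
    return float(amplitude), float(phase), float(c)


def wrap_phase(phi: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    out = math.remainder(phi, 2.0 * math.pi)
    if out <= -math.pi:
        out += 2.0 * math.pi
    return out


def phase_difference(trap_fit: tuple[float, float, float],
                     force_fit: tuple[float, float, float]) -> float:
    """Delta = force phase - trap phase, wrapped to (-pi, pi].

    Physically meaningful values lie in (0, pi) (viscous dissipation needs
    sin Delta > 0); callers should treat other values as quality failures.
    """
    return wrap_phase(force_fit[1] - trap_fit[1])


@dataclass(frozen=True)
class OscillationFit:
    """Cosine-fit summary of one driven trap/force trace pair.

    ``f_t0`` is in pN when the force trace was calibrated and in raw volts
    when used inside the active-passive calibration (where it is F_V0).
    """

    omega: float
    x_t0: float
    phi: float
    b1: float
    f_t0: float
    delta: float     # force-minus-trap phase difference Delta, rad
    b2: float

    def __post_init__(self) -> None:
        if self.x_t0 <= 0 or self.f_t0 <= 0:
            raise ValueError("amplitudes must be positive")

    def upsilon(self, kappa_t: float) -> float:
        """Upsilon = F_t0 / (kappa_t X_t0), dimensionless in (0, 1)."""
        return self.f_t0 / (kappa_t * self.x_t0)

    def bead_response(self, kappa_t: float) -> tuple[float, float]:
        """Bead oscillation (X0, delta) from X0 e^{-i delta} =
        X_t0 - (F_t0/kappa_t) e^{i Delta}."""
        z = self.x_t0 - (self.f_t0 / kappa_t) * np.exp(1j * self.delta)
        return float(abs(z)), float(-np.angle(z))


def fit_oscillation(trap: TimeTrace, force: TimeTrace, omega: float) -> OscillationFit:
    """Fit both traces of a drive pair and assemble an :class:`OscillationFit`."""
    xt0, phi, b1 = fit_cosine(trap, omega)
    ft0, phi_f, b2 = fit_cosine(force, omega)
    delta = wrap_phase(phi_f - phi)
    if delta < 0:
        # a negative amplitude convention ambiguity cannot occur (amplitudes
        # are positive); delta < 0 means noise or an unphysical pair and is
        # surfaced downstream by moduli_from_oscillation
        pass
    return OscillationFit(omega=omega, x_t0=xt0, phi=phi, b1=b1,
                          f_t0=ft0, delta=delta, b2=b2)


def moduli_from_oscillation(
    fit: OscillationFit, kappa_t: float, a: float
) -> tuple[float, float]:
    """Elastic and viscous moduli (Pa) from one oscillation fit.

    Raises if Upsilon >= 1 (force amplitude exceeding what the trap can
    exert on the commanded stroke - an inconsistent calibration) or if
    sin Delta <= 0 (no dissipation - unphysical phase).
    """
    ups = fit.upsilon(kappa_t)
    if ups >= 1.0:
        raise ValueError("Upsilon >= 1: force amplitude inconsistent with trap stiffness")
    sd = math.sin(fit.delta)
    if sd <= 0.0:
        raise ValueError("sin Delta <= 0: unphysical phase difference")
    cd = math.cos(fit.delta)
    pref = fit.f_t0 / (6.0 * math.pi * a * fit.x_t0)
    denom = (cd - ups) ** 2 + sd**2
    return pref * (cd - ups) / denom, pref * sd / denom


def moduli_dataset_from_pairs(
    pairs: list[tuple[TimeTrace, TimeTrace, float]],
    kappa_t: float,
    a: float,
) -> ComplexModuliDataset:
    """One droplet's moduli dataset from (trap, force, omega) trace pairs."""
    rows = []
    for trap, force, omega in pairs:
        fit = fit_oscillation(trap, force, omega)
        gp, gpp = moduli_from_oscillation(fit, kappa_t, a)
        rows.append((omega, gp, gpp))
    rows.sort(key=lambda r: r[0])
    w, gp, gpp = (np.array(col) for col in zip(*rows))
    return ComplexModuliDataset(w, gp, gpp)


def aggregate_replicates(replicates: list[ComplexModuliDataset]) -> ComplexModuliDataset:
    """Mean +/- SEM moduli over replicate droplets on a shared frequency grid."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    w = replicates[0].omega
    for rep in replicates[1:]:
        if rep.omega.shape != w.shape or not np.allclose(rep.omega, w, rtol=1e-12):
            raise ValueError("replicates must share the same frequency grid")
    gp = np.stack([rep.g_prime for rep in replicates])
    gpp = np.stack([rep.g_dprime for rep in replicates])
    n = len(replicates)
    sem = lambda arr: np.std(arr, axis=0, ddof=1) / math.sqrt(n)
    return ComplexModuliDataset(
        w, gp.mean(axis=0), gpp.mean(axis=0),
        sem_g_prime=sem(gp), sem_g_dprime=sem(gpp),
        n_replicates=np.full(w.size, n),
    )
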