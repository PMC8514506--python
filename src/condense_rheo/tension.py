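"""Interfacial tension from droplet stretching and bead-rupture tensiometry.

Stretching route: a droplet suspended between two trapped beads at opposite
poles behaves, for small stretches, as a spring of static constant

    chi0 = (pi * alpha(theta0) / 2) * gamma,
    1/alpha(theta0) = -0.5 ln(theta0) + 0.34,     theta0 = a/(R - a) <= 0.5,

in series with the two traps: 1/chi_sys0 = 1/chi0 + 1/kt1 + 1/kt2.  Pulling
trap 1 at constant speed v produces force ramps of slopes -/+ v*chi_sys0 on
the two traps, so chi_sys0 = ((f2 - f1)/2)/v, and the tension follows from

    gamma = (1/pi) * [ln(R/a - 1) + 0.68] * chi0.

Rupture route: pulling a trapped bead through the droplet surface requires a
peak force F_rup = 2*pi*a*f*gamma, with a dimensionless constant f = 1.1
absorbing the adhesion of droplet components to the bead coating.

Units: pN, um, s; tensions in pN/um (= mN/m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trace import TimeTrace

DEFAULT_RUPTURE_GEOMETRY_FACTOR = 1.1
DEFAULT_SMOOTHING_WINDOW_S = 0.064

# bracket of Eq.-42-style formula vanishes when R/a - 1 = exp(-0.68)
_MIN_LOG_ARG = math.exp(-0.68)


def polar_angle(R: float, a: float) -> float:
    """Polar angle theta0 = a/(R-a) spanned by a bead at the droplet pole."""
    if not R > 2 * a:
        raise ValueError("droplet must enclose the beads: R > 2a required")
    return a / (R - a)


def geometry_factor(theta0: float) -> float:
    """alpha(theta0) with 1/alpha = -0.5 ln(theta0) + 0.34, valid to theta0 = 0.5."""
    if not 0 < theta0 <= 0.5:
        raise ValueError("theta0 = a/(R-a) must lie in (0, 0.5]")
    return 1.0 / (-0.5 * math.log(theta0) + 0.34)


def spring_from_tension(gamma: float, R: float, a: float) -> float:
    """Forward map: droplet static spring constant chi0 from tension (pN/um)."""
    alpha = geometry_factor(polar_angle(R, a))
    return 0.5 * math.pi * alpha * gamma


def tension_from_spring(chi0: float, R: float, a: float) -> float:
    """Interfacial tension gamma from the droplet spring constant chi0."""
    theta0 = polar_angle(R, a)
    if theta0 > 0.5:
        raise ValueError("theta0 > 0.5 is outside the geometry-factor validity domain")
    if R / a - 1 <= _MIN_LOG_ARG:
        raise ValueError("R/a too small: geometry bracket non-positive")
    if chi0 <= 0:
        raise ValueError("chi0 must be positive")
    return (math.log(R / a - 1.0) + 0.68) / math.pi * chi0


def series_spring(chi0: float, kappa_t1: float, kappa_t2: float) -> float:
    """System spring constant of droplet + two traps in series."""
    return 1.0 / (1.0 / chi0 + 1.0 / kappa_t1 + 1.0 / kappa_t2)


def droplet_spring_constant(chi_sys0: float, kappa_t1: float, kappa_t2: float) -> float:
    """Invert the three-springs-in-series relation for the droplet alone.

    Requires 1/chi_sys0 > 1/kt1 + 1/kt2 (the measured system cannot be softer
    than the traps alone).
    """
    inv = 1.0 / chi_sys0 - 1.0 / kappa_t1 - 1.0 / kappa_t2
    if inv <= 0:
        raise ValueError(
            "system spring softer than the traps in series: inconsistent input"
        )
    return 1.0 / inv


def moving_average(values: np.ndarray, window_s: float, dt: float) -> np.ndarray:
    """Centered moving average over a window of window_s seconds."""
    n = max(int(round(window_s / dt)), 1)
    if n <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(n) / n
    pad = n // 2
    # odd reflection preserves linear trends at the edges exactly
    padded = np.pad(np.asarray(values, dtype=float), pad,
                    mode="reflect", reflect_type="odd")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(values)]
    return out


@dataclass(frozen=True)
class StretchExperiment:
    """Two-trap droplet stretching measurement.

    force1/force2 are the trap-1 and trap-2 force x-components (pN) recorded
    while trap 1 is pulled at speed ``v``; trap 2 is fixed.  ``d0`` (the
    initial inter-bead distance) never enters the analysis — only slopes do —
    and is kept for provenance only.
    """

    kappa_t1: float
    kappa_t2: float
    v: float
    force1: TimeTrace
    force2: TimeTrace
    R: float
    a: float
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW_S
    d0: float | None = None

    def __post_init__(self) -> None:
        # v > 0 is a stretch, v < 0 a retraction (time-reversed pull)
        if self.v == 0:
            raise ValueError("pulling speed must be non-zero")
        if self.kappa_t1 <= 0 or self.kappa_t2 <= 0:
            raise ValueError("trap stiffnesses must be > 0")
        polar_angle(self.R, self.a)  # validates R > 2a
        if polar_angle(self.R, self.a) > 0.5:
            raise ValueError("theta0 = a/(R-a) must be <= 0.5")


@dataclass(frozen=True)
class TensionResult:
    """Tension estimate with the intermediate spring constants."""

    gamma: float
    method: str
    chi0: float | None = None
    chi_sys0: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _ramp_slope(trace: TimeTrace, window_s: float) -> tuple[float, float]:
    """Slope (pN/s) of a smoothed force ramp by OLS, plus fit RMS residual."""
    y = moving_average(trace.values, window_s, trace.dt)
    t = trace.times()
    A = np.column_stack([t, np.ones_like(t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    rms = math.sqrt(res[0] / len(y)) if len(res) else 0.0
    return float(coef[0]), rms


def stretch_spring_constant(exp: StretchExperiment) -> tuple[float, dict]:
    """System spring constant chi_sys0 = ((f2 - f1)/2)/v from the force ramps.

    Both force traces are smoothed with the configured moving-average window
    and fitted linearly in time.  Raises if the slopes show no restoring
    force (f2 <= f1).
    """
    f1, rms1 = _ramp_slope(exp.force1, exp.smoothing_window)
    f2, rms2 = _ramp_slope(exp.force2, exp.smoothing_window)
    chi_sys0 = 0.5 * (f2 - f1) / exp.v
    if chi_sys0 <= 0:
        raise ValueError("force slopes show no restoring tension")
    return chi_sys0, {"f1_pn_per_s": f1, "f2_pn_per_s": f2,
                      "rms1_pn": rms1, "rms2_pn": rms2}


def analyze_stretch(exp: StretchExperiment) -> TensionResult:
    """Full stretching analysis: slopes -> chi_sys0 -> chi0 -> gamma."""
    chi_sys0, diag = stretch_spring_constant(exp)
    chi0 = droplet_spring_constant(chi_sys0, exp.kappa_t1, exp.kappa_t2)
    gamma = tension_from_spring(chi0, exp.R, exp.a)
    return TensionResult(gamma=gamma, method="stretch", chi0=chi0,
                         chi_sys0=chi_sys0, diagnostics=diag)


def tension_from_rupture(
    force_trace: TimeTrace,
    a: float,
    f: float = DEFAULT_RUPTURE_GEOMETRY_FACTOR,
    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW_S,
    force_limit: float | None = None,
) -> TensionResult:
    """Tension from the peak force at surface rupture: gamma = F_rup/(2 pi a f).

    The trace must show a rupture signature: a maximum followed by a drop of
    at least 50%.  If ``force_limit`` is given and the peak reaches it, the
    result is flagged as a lower bound (instrument trapping power exceeded).
    """
    if f <= 0 or a <= 0:
        raise ValueError("a and f must be positive")
    y = moving_average(force_trace.values, smoothing_window, force_trace.dt)
    i_max = int(np.argmax(y))
    f_rup = float(y[i_max])
    if f_rup <= 0:
        raise ValueError("no positive force peak in trace")
    tail_min = float(np.min(y[i_max:]))
    if tail_min > 0.5 * f_rup:
        raise ValueError("no rupture signature: force never drops 50% below its peak")
    gamma = f_rup / (2.0 * math.pi * a * f)
    diag = {"f_rup_pn": f_rup, "f": f, "lower_bound": False}
    if force_limit is not None and f_rup >= force_limit:
        diag["lower_bound"] = True
        diag["gamma_lower_bound_pn_per_um"] = force_limit / (2.0 * math.pi * a * f)
    return TensionResult(gamma=gamma, method="rupture", diagnostics=diag)
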