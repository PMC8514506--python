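"""Fusion-speed fitting and the viscocapillary-model comparison.

Condensate droplets fuse on a timescale proportional to their radius; the
inverse fusion speed is the slope s of the through-origin fit tau_fu = s*R.
For a Newtonian droplet the viscocapillary model predicts

    tau_fu^N = 1.97 * eta * R / gamma = 1.97 * tau_vc,

so comparing measured tau_fu against tau_fu^N at a common reference radius
diagnoses non-Newtonian behaviour during fusion: tau_fu > tau_fu^N means the
effective viscosity rose under deformation (shear thickening), tau_fu <
tau_fu^N means it fell (shear thinning).  The deformation rate during fusion
is of order 1/tau_fu* with tau_fu* = sqrt(tau_fu * tau_fu^N), so the ratio
tau1/tau_fu* of the shear-relaxation time to the fusion timescale locates
each condensate on the associative-polymer thinning/thickening curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: viscosity of water at 25 C, Pa s
ETA_WATER = 8.9e-4

#: relative tolerance on eta_eff/eta for calling a condensate Newtonian
REGIME_TOL = 0.05


@dataclass(frozen=True)
class FusionDataset:
    """Per-droplet (radius, fusion time) observations."""

    radius_um: np.ndarray
    tau_fu_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.radius_um, dtype=float)
        t = np.asarray(self.tau_fu_ms, dtype=float)
        if r.shape != t.shape or r.ndim != 1:
            raise ValueError("radius and tau_fu must be 1-d and equal length")
        if np.any(r <= 0) or np.any(t <= 0):
            raise ValueError("radii and fusion times must be positive")
        object.__setattr__(self, "radius_um", r)
        object.__setattr__(self, "tau_fu_ms", t)

    def __len__(self) -> int:
        return self.radius_um.size


def fit_fusion_speed(data: FusionDataset, through_origin: bool = True) -> tuple[float, float]:
    """Inverse fusion speed s (ms/um) and its standard error.

    Default is the proportional (through-origin) fit tau_fu = s*R; an
    intercept can be enabled but is off by default because fusion time
    vanishes with droplet size.
    """
    r, t = data.radius_um, data.tau_fu_ms
    if through_origin:
        s = float(np.sum(r * t) / np.sum(r * r))
        dof = len(data) - 1
        if dof <= 0:
            return s, float("nan")
        resid = t - s * r
        se = math.sqrt(float(np.sum(resid**2)) / dof / float(np.sum(r * r)))
        return s, se
    if len(data) < 2:
        raise ValueError("intercept fit needs at least 2 points")
    A = np.column_stack([r, np.ones_like(r)])
    coef, _, _, _ = np.linalg.lstsq(A, t, rcond=None)
    resid = t - A @ coef
    dof = len(data) - 2
    s2 = float(np.sum(resid**2)) / dof if dof > 0 else float("nan")
    cov = s2 * np.linalg.inv(A.T @ A)
    return float(coef[0]), math.sqrt(cov[0, 0])


def viscocapillary_time(eta: float, gamma: float, R: float) -> float:
    """tau_vc = eta*R/gamma in ms (eta in Pa s, gamma in pN/um, R in um)."""
    if eta <= 0 or gamma <= 0 or R <= 0:
        raise ValueError("eta, gamma, R must be positive")
    return 1e3 * eta * R / gamma


def predict_newtonian_fusion_time(eta: float, gamma: float, R: float) -> float:
    """Viscocapillary fusion-time prediction tau_fu^N = 1.97*eta*R/gamma, ms."""
    return 1.97 * viscocapillary_time(eta, gamma, R)


@dataclass(frozen=True)
class CondensateSummary:
    """One condensate's material properties and fusion-model comparison."""

    name: str
    eta: float                  # Pa s
    gamma: float                # pN/um
    tau1: float                 # ms
    inverse_fusion_speed: float  # ms/um
    inverse_fusion_speed_se: float = float("nan")
    R_ref: float = 3.0          # um
    eta_w: float = ETA_WATER

    @property
    def tau_fu(self) -> float:
        """Measured fusion time at the reference radius, ms."""
        return self.inverse_fusion_speed * self.R_ref

    @property
    def tau_vc(self) -> float:
        return viscocapillary_time(self.eta, self.gamma, self.R_ref)

    @property
    def tau_fu_newtonian(self) -> float:
        return predict_newtonian_fusion_time(self.eta, self.gamma, self.R_ref)

    @property
    def tau_fu_star(self) -> float:
        """Geometric-mean fusion timescale sqrt(tau_fu * tau_fu^N), ms."""
        return math.sqrt(self.tau_fu * self.tau_fu_newtonian)

    @property
    def ratio_tau1_star(self) -> float:
        return self.tau1 / self.tau_fu_star

    @property
    def eta_eff_ratio(self) -> float:
        """Effective-to-zero-shear viscosity ratio tau_fu / tau_fu^N."""
        return self.tau_fu / self.tau_fu_newtonian

    @property
    def pct_diff(self) -> float:
        """Percent deviation 200*|tau_fu - tau_fu^N|/(tau_fu + tau_fu^N)."""
        a, b = self.tau_fu, self.tau_fu_newtonian
        return 200.0 * abs(a - b) / (a + b)

    @property
    def relative_viscosity(self) -> float:
        return self.eta / self.eta_w

    @property
    def regime(self) -> str:
        r = self.eta_eff_ratio
        if r > 1.0 + REGIME_TOL:
            return "thickening"
        if r < 1.0 - REGIME_TOL:
            return "thinning"
        return "newtonian"

    def as_record(self) -> dict:
        return {
            "name": self.name,
            "eta_pa_s": self.eta,
            "gamma_pn_per_um": self.gamma,
            "tau1_ms": self.tau1,
            "tau_fu_ms": self.tau_fu,
            "tau_vc_ms": self.tau_vc,
            "tau_fu_newtonian_ms": self.tau_fu_newtonian,
            "tau_fu_star_ms": self.tau_fu_star,
            "tau1_over_tau_fu_star": self.ratio_tau1_star,
            "eta_eff_over_eta": self.eta_eff_ratio,
            "pct_diff": self.pct_diff,
            "relative_viscosity": self.relative_viscosity,
            "regime": self.regime,
        }


def derived_metrics(
    name: str,
    eta: float,
    gamma: float,
    tau1_ms: float,
    inverse_fusion_speed: float,
    inverse_fusion_speed_se: float = float("nan"),
    R_ref: float = 3.0,
    eta_w: float = ETA_WATER,
) -> CondensateSummary:
    """Assemble a :class:`CondensateSummary` from measured inputs."""
    if min(eta, gamma, tau1_ms, inverse_fusion_speed, R_ref) <= 0:
        raise ValueError("all summary inputs must be positive")
    return CondensateSummary(
        name=name, eta=eta, gamma=gamma, tau1=tau1_ms,
        inverse_fusion_speed=inverse_fusion_speed,
        inverse_fusion_speed_se=inverse_fusion_speed_se,
        R_ref=R_ref, eta_w=eta_w,
    )


def _sig(x: float, n: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def table_report(summaries: list[CondensateSummary]) -> tuple[str, pd.DataFrame]:
    """Materials-and-fusion summary table (formatted text + DataFrame).

    Rounds derived timescales to 3 significant figures and ratios/percent
    deviations to 2, matching conventional reporting.
    """
    if not summaries:
        raise ValueError("need at least one condensate summary")
    rows = []
    for s in summaries:
        rec = s.as_record()
        rec["tau_fu_star_ms"] = _sig(rec["tau_fu_star_ms"], 3)
        rec["tau_fu_newtonian_ms"] = _sig(rec["tau_fu_newtonian_ms"], 3)
        rec["tau1_over_tau_fu_star"] = _sig(rec["tau1_over_tau_fu_star"], 2)
        rec["eta_eff_over_eta"] = _sig(rec["eta_eff_over_eta"], 2)
        rec["pct_diff"] = _sig(rec["pct_diff"], 2)
        rec["relative_viscosity"] = _sig(rec["relative_viscosity"], 2)
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df.to_string(index=False), df


def report_json(summaries: list[CondensateSummary]) -> str:
    _, df = table_report(summaries)
    return json.dumps(df.to_dict(orient="records"), indent=2)
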