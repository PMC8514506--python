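"""Reference parameter sets for the four model condensates.

Each preset describes one oppositely charged binary condensate system
(polylysine:heparin "pK:H", proline-rich-motif:heparin "P:H",
SH3-pentamer:proline-rich-motif "S:P", SH3-pentamer:lysozyme "S:L") by its
measured material properties: a Burgers medium (zero-shear viscosity
eta0+eta1 and shear-relaxation times), interfacial tension, trap stiffness
used in its oscillation experiments, and the measured inverse fusion speed.

eta, tau1, gamma, the inverse fusion speeds and the trap stiffnesses are
the measured headline values; the split of eta into (eta0, tau0) components
is constrained qualitatively (tau0 is 5-35x shorter than tau1 except for
S:P, whose fast component is Newtonian with tau0 = 0; eta0/eta1 exceeds
0.26 for pK:H and S:L and exceeds 1 only for S:L) and fixed here so the
synthetic experiments have a definite ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .viscoelastic import BurgersParameters


@dataclass(frozen=True)
class CondensatePreset:
    name: str
    burgers: BurgersParameters        # ground-truth medium
    gamma: float                      # interfacial tension, pN/um
    kappa_t_oscillation: float        # trap stiffness in rheology runs, pN/um
    inverse_fusion_speed: float       # ms/um
    tau_fu_ms: float                  # measured fusion time at R = 3 um
    tau1_ms: float                    # reported shear-relaxation time, ms

    @property
    def eta(self) -> float:
        return self.burgers.eta


PK_H = CondensatePreset(
    name="pK:H",
    burgers=BurgersParameters(eta0=0.1, tau0=0.005, eta1=0.2, tau1=0.045),
    gamma=57.1,
    kappa_t_oscillation=310.0,
    inverse_fusion_speed=10.1,
    tau_fu_ms=30.3,
    tau1_ms=45.0,
)

P_H = CondensatePreset(
    name="P:H",
    burgers=BurgersParameters(eta0=0.1, tau0=0.01, eta1=0.43, tau1=0.125),
    gamma=67.0,
    kappa_t_oscillation=310.0,
    inverse_fusion_speed=39.3 / 3.0,
    tau_fu_ms=39.3,
    tau1_ms=125.0,
)

S_P = CondensatePreset(
    name="S:P",
    burgers=BurgersParameters(eta0=0.75, tau0=0.0, eta1=3.0, tau1=0.072),
    gamma=73.4,
    kappa_t_oscillation=310.0,
    inverse_fusion_speed=384.0 / 3.0,
    tau_fu_ms=384.0,
    tau1_ms=72.0,
)

S_L = CondensatePreset(
    name="S:L",
    burgers=BurgersParameters(eta0=5.6, tau0=0.04, eta1=4.5, tau1=0.396),
    gamma=106.0,
    kappa_t_oscillation=1850.0,
    inverse_fusion_speed=1774.0 / 3.0,
    tau_fu_ms=1774.0,
    tau1_ms=396.0,
)

ALL_PRESETS = (PK_H, P_H, S_P, S_L)

#: reported measured values used in the viscocapillary comparison
#: (eta Pa s, gamma pN/um, tau1 ms, tau_fu ms at R = 3 um)
MEASURED = {
    "pK:H": dict(eta=0.30, gamma=57.1, tau1_ms=45.0, tau_fu_ms=30.3),
    "P:H": dict(eta=0.53, gamma=67.0, tau1_ms=125.0, tau_fu_ms=39.3),
    "S:P": dict(eta=3.75, gamma=73.4, tau1_ms=72.0, tau_fu_ms=384.0),
    "S:L": dict(eta=10.1, gamma=106.0, tau1_ms=396.0, tau_fu_ms=1774.0),
}

#: standard oscillation frequency grid, Hz
STANDARD_FREQS_HZ = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)
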