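"""Burgers-model viscoelasticity: relaxation modulus, complex moduli, fitting.

The Burgers model is two Maxwell elements in parallel,

    G(t) = (eta0/tau0) exp(-t/tau0) + (eta1/tau1) exp(-t/tau1),   t > 0,

with viscosities ``eta0, eta1`` (Pa s) and relaxation times ``tau0, tau1``
(s).  Its one-sided Fourier transform gives the elastic (storage) and viscous
(loss) moduli

    G'(w)  = w^2 tau0 eta0 / (1 + (w tau0)^2) + w^2 tau1 eta1 / (1 + (w tau1)^2)
    G''(w) = w eta0 / (1 + (w tau0)^2)        + w eta1 / (1 + (w tau1)^2)

The limit tau0 = 0 is an explicit Newtonian sub-branch: the fast element
contributes nothing to G' and ``w*eta0`` to G''.  The zero-shear viscosity is
eta0 + eta1 in every case.

Units follow the pN/um/s system throughout the package, in which
1 Pa = 1 pN/um^2 and 1 Pa s = 1 pN s/um^2, so moduli computed from forces in
pN and lengths in um are numerically in Pa with no conversion factors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass(frozen=True)
class BurgersParameters:
    """Constitutive parameters (eta0, tau0, eta1, tau1) of a Burgers fluid.

    Components are stored in canonical order tau0 <= tau1 (swapped on
    construction if given the other way).  ``tau0 = 0`` denotes a Newtonian
    fast component.
    """

    eta0: float
    tau0: float
    eta1: float
    tau1: float

    def __post_init__(self) -> None:
        if self.eta0 < 0 or self.eta1 < 0:
            raise ValueError("viscosities must be non-negative")
        if self.tau0 < 0 or self.tau1 < 0:
            raise ValueError("relaxation times must be >= 0")
        if self.tau0 > self.tau1:
            # canonical ordering: fast component first
            eta0, tau0, eta1, tau1 = self.eta0, self.tau0, self.eta1, self.tau1
            object.__setattr__(self, "eta0", eta1)
            object.__setattr__(self, "tau0", tau1)
            object.__setattr__(self, "eta1", eta0)
            object.__setattr__(self, "tau1", tau0)
        if self.tau1 <= 0:
            raise ValueError("tau1 must be > 0")

    @property
    def is_fast_newtonian(self) -> bool:
        return self.tau0 == 0.0

    @property
    def eta(self) -> float:
        """Zero-shear viscosity eta0 + eta1 (Pa s)."""
        return self.eta0 + self.eta1


def relaxation_modulus(params: BurgersParameters, t) -> np.ndarray | float:
    """Shear relaxation modulus G(t) in Pa for t > 0.

    For tau0 = 0 the fast component is a Dirac delta (Newtonian) and only the
    slow exponential is returned as the pointwise value.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("relaxation modulus is defined pointwise only for t > 0")
    slow = (params.eta1 / params.tau1) * np.exp(-t_arr / params.tau1)
    if params.is_fast_newtonian:
        out = slow
    else:
        out = (params.eta0 / params.tau0) * np.exp(-t_arr / params.tau0) + slow
    return out if out.ndim else float(out)


def complex_moduli(params: BurgersParameters, omega):
    """Elastic and viscous moduli (G', G'') in Pa at angular frequency omega.

    Accepts scalars or arrays; omega must be >= 0 (both moduli vanish at 0).
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("angular frequency must be non-negative")
    wt1 = w * params.tau1
    g1 = params.eta1 * w * wt1 / (1.0 + wt1**2)
    g2 = params.eta1 * w / (1.0 + wt1**2)
    if params.is_fast_newtonian:
        gp = g1
        gpp = g2 + w * params.eta0
    else:
        wt0 = w * params.tau0
        gp = g1 + params.eta0 * w * wt0 / (1.0 + wt0**2)
        gpp = g2 + params.eta0 * w / (1.0 + wt0**2)
    if gp.ndim == 0:
        return float(gp), float(gpp)
    return gp, gpp


def zero_shear_viscosity(params: BurgersParameters) -> float:
    """eta0 + eta1, equal to lim_{w->0} G''(w)/w."""
    return params.eta


_BRACKET_DECADES = 6


def crossover_frequency(params: BurgersParameters) -> float | None:
    """Smallest omega > 0 with G'(omega) = G''(omega), or None if no crossing.

    Searched by sign-change bracketing of G' - G'' on a log grid over
    [1e-6/tau1, 1e6/max(tau0, 1e-6 tau1)], then bisection (brentq) to 1e-12
    relative.  Tangencies without a sign change count as absent.
    """
    lo = 10.0**-_BRACKET_DECADES / params.tau1
    hi = 10.0**_BRACKET_DECADES / max(params.tau0, params.tau1 * 1e-6)

    def diff(w: float) -> float:
        gp, gpp = complex_moduli(params, w)
        return gp - gpp

    grid = np.logspace(math.log10(lo), math.log10(hi), 4000)
    vals = np.array([diff(w) for w in grid])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        # a grid point may sit exactly on the root
        exact = np.nonzero(vals == 0.0)[0]
        return float(grid[exact[0]]) if exact.size else None
    i = int(idx[0])
    root = optimize.brentq(diff, grid[i], grid[i + 1], xtol=1e-300, rtol=1e-13)
    return float(root)


@dataclass(frozen=True)
class ComplexModuliDataset:
    """(omega, G', G'') rows with replicate SEMs.

    omega strictly increasing and positive; G'' must be positive everywhere
    (a fluid always dissipates).  Rows with G' <= 0 are legal noisy data and
    are exposed through :meth:`flagged_rows`.
    """

    omega: np.ndarray
    g_prime: np.ndarray
    g_dprime: np.ndarray
    sem_g_prime: np.ndarray | None = None
    sem_g_dprime: np.ndarray | None = None
    n_replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        gp = np.asarray(self.g_prime, dtype=float)
        gpp = np.asarray(self.g_dprime, dtype=float)
        if not (w.shape == gp.shape == gpp.shape) or w.ndim != 1:
            raise ValueError("omega, g_prime, g_dprime must be 1-d and equal length")
        if np.any(w <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("omega must be positive and strictly increasing")
        if np.any(gpp <= 0):
            raise ValueError("G'' must be positive at every frequency")
        object.__setattr__(self, "omega", w)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_dprime", gpp)
        for name in ("sem_g_prime", "sem_g_dprime", "n_replicates"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != w.shape:
                    raise ValueError(f"{name} must match omega in shape")
                object.__setattr__(self, name, v)

    def __len__(self) -> int:
        return self.omega.size

    def flagged_rows(self) -> np.ndarray:
        """Boolean mask of rows with non-positive G' (noise artefacts)."""
        return self.g_prime <= 0

    def without_flagged(self) -> "ComplexModuliDataset":
        keep = ~self.flagged_rows()
        return ComplexModuliDataset(
            self.omega[keep],
            self.g_prime[keep],
            self.g_dprime[keep],
            None if self.sem_g_prime is None else self.sem_g_prime[keep],
            None if self.sem_g_dprime is None else self.sem_g_dprime[keep],
            None if self.n_replicates is None else self.n_replicates[keep],
        )

    # --- CSV interchange (frequency in Hz at the boundary) -----------------
    @staticmethod
    def from_csv(path) -> "ComplexModuliDataset":
        df = pd.read_csv(path, comment="#")
        kwargs = {}
        if "sem_g_prime_pa" in df:
            kwargs["sem_g_prime"] = df["sem_g_prime_pa"].to_numpy()
        if "sem_g_dprime_pa" in df:
            kwargs["sem_g_dprime"] = df["sem_g_dprime_pa"].to_numpy()
        if "n" in df:
            kwargs["n_replicates"] = df["n"].to_numpy()
        return ComplexModuliDataset(
            2.0 * np.pi * df["freq_hz"].to_numpy(),
            df["g_prime_pa"].to_numpy(),
            df["g_dprime_pa"].to_numpy(),
            **kwargs,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "freq_hz": self.omega / (2.0 * np.pi),
                "g_prime_pa": self.g_prime,
                "g_dprime_pa": self.g_dprime,
            }
        )
        if self.sem_g_prime is not None:
            df["sem_g_prime_pa"] = self.sem_g_prime
        if self.sem_g_dprime is not None:
            df["sem_g_dprime_pa"] = self.sem_g_dprime
        if self.n_replicates is not None:
            df["n"] = self.n_replicates.astype(int)
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class BurgersFit:
    """Result of fitting a moduli dataset to the Burgers model."""

    params: BurgersParameters
    param_stderrs: dict = field(default_factory=dict)
    residual: float = float("nan")
    converged: bool = False

    @property
    def eta(self) -> float:
        return self.params.eta

    @property
    def omega_x(self) -> float | None:
        return crossover_frequency(self.params)

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "eta0_pa_s": p.eta0,
                "tau0_s": p.tau0,
                "eta1_pa_s": p.eta1,
                "tau1_s": p.tau1,
                "stderrs": self.param_stderrs,
                "eta_pa_s": self.eta,
                "omega_x_rad_s": self.omega_x,
                "residual": self.residual,
                "converged": self.converged,
            },
            indent=2,
        )


# tau0 at this floor (in units of tau1) is reported as exactly zero
_TAU0_ZERO_FRAC = 1e-6
_LOG_TAU0_FLOOR = math.log(1e-12)


def _fit_weights(data: ComplexModuliDataset, weights: str) -> tuple[np.ndarray, np.ndarray]:
    if weights == "sem" and data.sem_g_prime is not None and data.sem_g_dprime is not None:
        wp = 1.0 / np.maximum(data.sem_g_prime, 1e-300)
        wpp = 1.0 / np.maximum(data.sem_g_dprime, 1e-300)
        return wp, wpp
    # constant relative error; floor protects exact zeros (e.g. Newtonian G')
    scale = max(np.max(np.abs(data.g_prime)), np.max(data.g_dprime))
    floor = 1e-6 * scale
    wp = 1.0 / np.maximum(np.abs(data.g_prime), floor)
    wpp = 1.0 / np.maximum(data.g_dprime, floor)
    return wp, wpp


def fit_burgers(
    data: ComplexModuliDataset,
    weights: str = "sem",
    include_flagged: bool = True,
) -> BurgersFit:
    """Weighted least-squares Burgers fit of a (omega, G', G'') dataset.

    Minimises the joint sum of squares over the G' and G'' rows, weighted by
    1/SEM^2 when SEMs are present (``weights='sem'``) and by 1/value^2
    otherwise.  Optimisation runs in log-parameter space with eight
    deterministic multi-starts spanning relaxation times at the edges and
    middle of the sampled band; tau0 may reach a floor that is reported as an
    exactly Newtonian fast component.  Set ``include_flagged=False`` to drop
    rows with G' <= 0 before fitting.
    """
    if not include_flagged:
        data = data.without_flagged()
    n_rows = len(data)
    if n_rows < 4:
        raise ValueError("need at least 4 frequency rows to fit 4 parameters")
    if weights not in ("sem", "relative"):
        raise ValueError("weights must be 'sem' or 'relative'")

    w = data.omega
    wp, wpp = _fit_weights(data, weights)

    def unpack(x: np.ndarray) -> BurgersParameters:
        eta0, tau0, eta1, tau1 = np.exp(x)
        if tau0 > tau1:
            eta0, tau0, eta1, tau1 = eta1, tau1, eta0, tau0
        if tau0 < _TAU0_ZERO_FRAC * tau1:
            tau0 = 0.0
        return BurgersParameters(eta0, tau0, eta1, tau1)

    def residuals(x: np.ndarray) -> np.ndarray:
        eta0, tau0, eta1, tau1 = np.exp(x)
        wt0, wt1 = w * tau0, w * tau1
        gp = eta0 * w * wt0 / (1 + wt0**2) + eta1 * w * wt1 / (1 + wt1**2)
        gpp = eta0 * w / (1 + wt0**2) + eta1 * w / (1 + wt1**2)
        return np.concatenate(
            [(gp - data.g_prime) * wp, (gpp - data.g_dprime) * wpp]
        )

    # deterministic multi-starts: taus at band edges/middle, two eta splits
    w_lo, w_hi = w[0], w[-1]
    w_mid = math.sqrt(w_lo * w_hi)
    eta_guess = max(float(np.median(data.g_dprime / w)), 1e-12)
    tau_cands = [1.0 / w_hi, 1.0 / w_mid, 1.0 / w_lo]
    starts = []
    for i, t0 in enumerate(tau_cands):
        for t1 in tau_cands[i:]:
            starts.append((0.5 * eta_guess, t0, 0.5 * eta_guess, max(t1, t0 * 1.001)))
    starts.append((0.2 * eta_guess, tau_cands[0], 0.8 * eta_guess, tau_cands[2]))
    starts.append((0.8 * eta_guess, tau_cands[0], 0.2 * eta_guess, tau_cands[2]))

    best = None
    for s in starts:
        x0 = np.log(np.asarray(s))
        lb = np.array([-60.0, _LOG_TAU0_FLOOR, -60.0, -60.0])
        ub = np.full(4, 60.0)
        try:
            res = optimize.least_squares(
                residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    params = unpack(best.x)
    # standard errors from the Jacobian in log space, mapped back (delta method)
    dof = max(2 * n_rows - 4, 1)
    s2 = 2.0 * best.cost / dof
    try:
        jtj = best.jac.T @ best.jac
        cov_log = s2 * np.linalg.pinv(jtj)
        log_se = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        vals = np.exp(best.x)
        se = vals * log_se
        stderrs = {
            "eta0": float(se[0]),
            "tau0": float(se[1]) if params.tau0 > 0 else 0.0,
            "eta1": float(se[2]),
            "tau1": float(se[3]),
        }
    except np.linalg.LinAlgError:
        stderrs = {}
    converged = bool(best.success)
    return BurgersFit(
        params=params,
        param_stderrs=stderrs,
        residual=float(2.0 * best.cost),
        converged=converged,
    )


def moduli_from_model(
    params: BurgersParameters,
    omega: Sequence[float],
    sem_frac: float | None = None,
) -> ComplexModuliDataset:
    """Evaluate the model on a frequency grid as a dataset (optionally with
    nominal fractional SEMs attached, for weighting round-trip tests)."""
    w = np.sort(np.asarray(omega, dtype=float))
    gp, gpp = complex_moduli(params, w)
    kwargs = {}
    if sem_frac is not None:
        kwargs["sem_g_prime"] = np.abs(gp) * sem_frac + 1e-12
        kwargs["sem_g_dprime"] = gpp * sem_frac
    return ComplexModuliDataset(w, gp, gpp, **kwargs)
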