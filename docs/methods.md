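# Methods

## Constitutive model

The medium is described by the Burgers model: two Maxwell elements in
parallel, with relaxation modulus

    G(t) = (eta0/tau0) exp(-t/tau0) + (eta1/tau1) exp(-t/tau1),   t > 0,

and complex modulus G*(w) = G'(w) + iG''(w) obtained as iw times the
one-sided Fourier transform of G(t). Parameters are stored in canonical
order tau0 <= tau1. The limit tau0 = 0 is handled as an explicit algebraic
branch, not a small-tau numerical approximation: the fast component then
contributes nothing to G' and a Newtonian w*eta0 to G''. The zero-shear
viscosity is eta = eta0 + eta1 in all cases, and equals lim G''(w)/w. The
crossover frequency w_x (smallest positive root of G' = G'') is found by
sign-change bracketing on a 4000-point log grid spanning
[1e-6/tau1, 1e6/max(tau0, 1e-6 tau1)] followed by Brent refinement to 1e-13
relative; a tangency without sign change is reported as "no crossover",
as is the genuinely crossing-free case of a dominant Newtonian component.

Units are pN, um, s throughout, in which Pa = pN/um^2 and Pa s = pN s/um^2
identically, so no conversion factors appear in any formula.

## Burgers fitting

`fit_burgers` minimises the joint weighted sum of squares over the G' and
G'' rows of a moduli dataset. Weights are 1/SEM^2 when replicate SEMs are
available and 1/value^2 (constant relative error, with a 1e-6-of-maximum
floor protecting exact zeros) otherwise. The optimiser works in
log-parameter space — two-timescale fits are multimodal and
scale-heterogeneous — with eight deterministic starts placing (tau0, tau1)
at the edges and geometric middle of the sampled band and splitting the
low-frequency viscosity estimate median(G''/w) between the components in
50/50, 20/80 and 80/20 proportions. tau0 is bounded below at e^-27.6 s and
reported as exactly 0 when it lands below 1e-6*tau1. Standard errors come
from the Gauss-Newton covariance at the optimum, mapped from log space by
the delta method. Noise-free synthetic datasets are recovered to ~1e-11
relative; the suite asserts 1e-6.

## Synthetic experiments

The generators emulate a dual-trap optical-tweezer instrument holding a
1-um-radius bead (2-um polystyrene bead) at room temperature
(kBT = 4.116e-3 pN um), with trap stiffness 310 pN/um in the three softer
condensates and 1850 pN/um in S:L, matching the experimental settings.
All stochastic generators are pure functions of (parameters, seed).

**Passive traces.** The bead obeys an overdamped generalized-Langevin force
balance against the trap and the viscoelastic medium; its one-sided
position spectrum is

    P_x(w) = 2 kBT xi_m(w) / |kappa_t + kappa_m(w) + i w xi_m(w)|^2,

with kappa_m = 6 pi a G'(w) and xi_m = 6 pi a G''(w)/w. Bead inertia is
neglected: the inertial corner for a micron bead in media of >= 0.3 Pa s
lies far above the 0.1-100 Hz band of interest. Traces are synthesised in
the frequency domain (independent complex Gaussian Fourier coefficients
with variance proportional to P_x, Hermitian symmetry, inverse FFT), which
realises the target spectrum exactly with no time-stepping bias. Faxen
boundary corrections are excluded (beads sit several diameters from any
boundary).

A model property worth stating explicitly: with inertia dropped, the total
variance (1/pi) int P_x dw equals kBT (1/kappa_t - 1/(kappa_t + kappa_minf))
with kappa_minf = 6 pi a (eta0/tau0 + eta1/tau1), as the Kramers-Kronig sum
rule of the response function shows. When both Maxwell components have
finite relaxation times the medium retains an elastic plateau at all
frequencies and the equipartition value kBT/kappa_t is *not* reached — the
missing variance lives near the (unmodelled) inertial corner. When a
Newtonian component is present (tau0 = 0, e.g. the S:P preset or water),
drag survives at high frequency, the plateau is screened and equipartition
against the trap alone holds exactly. Equipartition-based tests therefore
use media with a Newtonian component.

**Driven traces.** The steady-state response to a sinusoidal trap motion is
computed exactly: with Z = kappa_m + i w xi_m, the trapping-force phasor is
kappa_t Z/(kappa_t + Z) times the trap-position phasor, giving the force
amplitude and the phase lag Delta analytically. The noise-free branch makes
no stochastic calls; with thermal noise enabled, the force trace receives
-kappa_t times a passive position trace, preserving the
fluctuation-response consistency the active-passive calibration relies on,
rather than generic white noise. Sampling defaults to 10 s at 1 kHz for
drives up to 10 Hz and 2 s at 4 kHz above (the experimental records are
"a few seconds" per frequency; these choices keep >= 5 periods and >= 2000
samples everywhere).

**Stretching, rupture, fusion.** Stretching emits a linear trap-1 ramp
(0.5 um total at v = 0.05 um/s by default) and two force ramps with slopes
-/+ v*chi_sys0 plus additive Gaussian noise; chi_sys0 composes the droplet
spring chi0 = (pi alpha(theta0)/2) gamma with both traps in series. Rupture
emits a ramp peaking at F_rup = 2 pi a f gamma at a seed-randomised time,
then collapsing. Fusion datasets draw tau_fu = s*R + N(0, sd), truncated
positive, for radii in the studied 0.8-8 um range. Droplet shape dynamics
during fusion are not modelled — only the proportionality tau_fu ∝ R.

## Trap calibration

Spectra are estimated by Welch averaging with boxcar windows and no
overlap, normalised so (1/pi) int P dw equals the sample variance, then
octave-smoothed onto ~12 bins/decade and fitted in log-density space
(periodogram noise is multiplicative). The Lorentzian fit fixes alpha = 2;
the stretched-Lorentzian fit frees alpha in (1, 3]. The active-passive
procedure combines the equipartition integral of the fitted spectrum
(first identity) with the amplitude and phase of a low-frequency drive
read in raw detector volts (second identity) to yield both epsilon (um/V)
and kappa_t with no second laser.

Two practical notes. First, droplet spectra have sub-10-Hz corners, so the
passive record must resolve well below 1 Hz; the droplet defaults use
200 s at 500 Hz with 10 segments and restrict the fit to <= 10 Hz. Second,
the procedure is exact only insofar as the stretched Lorentzian represents
the true spectrum. For water it is exact (the suite recovers
kappa_t = 307 pN/um to ~2% and epsilon to <1%); for strongly two-timescale
Burgers media the spectrum has two corners that the model cannot follow,
leaving an O(20-30%) systematic on (kappa_t, epsilon). The droplet test
asserts agreement at that level, together with the qualitative signature
omega_eff/2pi < 10 Hz.

## Oscillatory rheology

The drive frequency is commanded by the instrument and treated as known,
so cosine fitting is linear least squares on {cos wt, sin wt, 1}; traces
must span >= 2 periods. The phase difference Delta is wrapped to (-pi, pi],
with sin Delta > 0 required downstream (a fluid dissipates). Moduli follow
from the amplitude ratio, Delta, and Upsilon = F_t0/(kappa_t X_t0);
Upsilon >= 1 is rejected as an inconsistent calibration. Noisy rows with
G' <= 0 are retained and flagged, never silently clipped; an explicit
filter excludes them from fitting on request. Replicates on a shared grid
aggregate to mean +/- SEM with the replicate count recorded.

## Interfacial tension

Force ramps are smoothed by a centred 64-ms moving average (odd-reflection
padding, which preserves linear trends exactly at the edges) before OLS
slope fits. The droplet spring follows from the series relation
1/chi0 = 1/chi_sys0 - 1/kt1 - 1/kt2, rejected when the measured system is
softer than the traps alone. The geometry factor uses
theta0 = a/(R - a) with 1/alpha = -0.5 ln(theta0) + 0.34, valid for
theta0 <= 0.5 (R >= 3a), which the code enforces; the droplet radius is an
input (image-based radius measurement is out of scope; the instrument's
0.0866 um/pixel conversion is noted for provenance). Negative pulling
speeds denote retraction and yield the same spring constant with flipped
slopes. Rupture tensiometry uses the smoothed peak force with the
empirical adhesion factor f = 1.1 and demands a >= 50% post-peak drop; a
configurable force limit flags lower-bound-only results when the peak
exceeds the trapping power.

## Fusion analysis

The inverse fusion speed is fit through the origin (fusion time vanishes
with droplet size; an intercept option exists but is off by default).
Derived quantities at the reference radius R = 3 um: tau_vc = eta R/gamma,
tau_fu^N = 1.97 tau_vc, tau_fu* = sqrt(tau_fu tau_fu^N),
eta_eff/eta = tau_fu/tau_fu^N, and the percent deviation
200 |tau_fu - tau_fu^N| / (tau_fu + tau_fu^N) (symmetric-mean basis, which
reproduces the reference comparison at printed precision for three of four
condensates; the fourth differs only through input rounding). The regime
label uses a 5% tolerance band around eta_eff/eta = 1. The relative
viscosity is referenced to water at 25 C (8.9e-4 Pa s).

## Condensate presets

eta, tau1, gamma, trap stiffnesses and inverse fusion speeds of the four
presets are the measured headline values for the pK:H, P:H, S:P and S:L
systems. The decomposition of eta into (eta0, tau0, eta1) is constrained
only qualitatively by the measurements — tau0 is 5-35x shorter than tau1
except in S:P where the fast component is Newtonian; eta0/eta1 exceeds
0.26 in pK:H and S:L and exceeds 1 only in S:L — and is fixed here at
definite values satisfying those constraints so that synthetic experiments
have an exact ground truth.

## Problem sizes and numerical choices

Test and acceptance runs use 3 replicate droplets at 7 frequencies
(0.5-40 Hz) for rheology, 10-s 100-Hz stretching records at 1% force
noise, 20-50-seed Monte-Carlo loops for dispersion checks, and 100-200-s
passive records for calibration; the whole suite completes in a few
minutes on one CPU. Optimisers run with tolerances at 1e-15 and
deterministic multi-starts; all randomness flows from explicit integer
seeds through `numpy.random.default_rng`, with per-stage sub-seeds derived
by `SeedSequence`.

## What passing tests do and do not show

The synthetic generators realise exactly the model the analysis assumes:
stationary Gaussian thermal motion with the overdamped Burgers spectrum,
perfectly linear stretching ramps, strictly proportional fusion times.
Passing round trips therefore validate the *analysis chain* — its algebra,
estimators, weighting, and error propagation — not the adequacy of the
Burgers model for any real condensate. Real data add drift, detector
filtering, bead polydispersity, non-spectral noise, and media whose
spectra are not two-component; none of those are emulated. Known
limitations: no bead inertia or hydrodynamic memory, no Faxen corrections,
no multi-component (>2 Maxwell) or fractional rheology, no droplet shape
dynamics, and the calibration model-mismatch bias discussed above.
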