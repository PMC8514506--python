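# condense-rheo

Optical-tweezer micro-rheology and micro-tensiometry of biomolecular
condensates, as a tested, fully synthetic-data-driven analysis pipeline.

Biomolecular condensates — micron-scale droplets formed by phase separation
of proteins and nucleic acids — are viscoelastic fluids: shear stress in
them relaxes at a finite rate rather than instantaneously. Droplet-fusion
kinetics are traditionally interpreted with the *viscocapillary* model of a
Newtonian fluid, which predicts a fusion time
τ<sub>fu</sub><sup>N</sup> = 1.97 ηR/γ for droplets of radius R, viscosity η
and interfacial tension γ. This package implements the complete measurement
chain needed to put that model to the test on a single condensate system:

* **Burgers viscoelasticity** — two Maxwell elements in parallel,
  G(t) = (η₀/τ₀)e^(−t/τ₀) + (η₁/τ₁)e^(−t/τ₁), with elastic/viscous moduli
  G′(ω), G″(ω), zero-shear viscosity η = η₀+η₁, and the crossover frequency
  ω<sub>x</sub> where G′ = G″ (`condense_rheo.viscoelastic`);
* **trap calibration** — Lorentzian and stretched-Lorentzian
  power-spectrum fits, and an active–passive procedure that determines both
  the trap stiffness κ<sub>t</sub> and the detector volt→μm conversion ε
  from volt-unit data alone (`condense_rheo.calibration`);
* **oscillatory micro-rheology** — cosine fits of driven trap/force traces
  and the inversion G*(ω) = [F<sub>t0</sub>e^{iΔ}]/[6πa X<sub>t0</sub>(1 − Υe^{iΔ})]
  with Υ = F<sub>t0</sub>/(κ<sub>t</sub>X<sub>t0</sub>)
  (`condense_rheo.rheology`);
* **interfacial tension** — from two-trap droplet stretching
  (force-ramp slopes → springs-in-series → γ = (1/π)[ln(R/a−1)+0.68]χ₀) and
  from bead-rupture tensiometry (γ = F<sub>rup</sub>/(2πa·f), f = 1.1)
  (`condense_rheo.tension`);
* **fusion analysis** — proportional fits τ<sub>fu</sub> = s·R, the
  viscocapillary prediction, the geometric-mean timescale
  τ<sub>fu</sub>* = √(τ<sub>fu</sub>τ<sub>fu</sub><sup>N</sup>), and the
  shear thinning/thickening classification (`condense_rheo.fusion`);
* **synthetic experiments** — seeded generators for every input the
  pipeline consumes: passive thermal bead traces (exact spectral synthesis
  of the overdamped trapped-bead spectrum), driven oscillation pairs,
  stretching ramps, rupture ramps, and fusion datasets
  (`condense_rheo.simulate`), with reference parameter sets for four model
  condensates (pK:H, P:H, S:P, S:L) in `condense_rheo.presets`.

Everything runs without an instrument or a download; all units are pN, μm,
s (so moduli are numerically in Pa and tensions in pN/μm = mN/m).

## Worked example

Recover the zero-shear viscosity of the P:H condensate medium from fully
synthetic driven-oscillation experiments:

```python
from condense_rheo.pipeline import recover_viscosity
from condense_rheo.presets import P_H

fit = recover_viscosity(P_H.burgers, kappa_t=310.0, seed=1)
print(f"eta = {fit.eta:.3f} Pa s, tau1 = {fit.params.tau1*1e3:.0f} ms")
```

```
eta = 0.529 Pa s, tau1 = 125 ms
```

The true values are η = 0.53 Pa s and τ₁ = 125 ms: the full chain — thermal
noise on the force traces, cosine fitting at 0.5–40 Hz, moduli extraction,
replicate aggregation, SEM-weighted Burgers fit — recovers them to better
than 1%.

The numbered scripts under `analysis/` run the complete campaign and write
tables under `results/`:

```sh
python analysis/01_simulate_experiments.py   # example traces of every kind
python analysis/02_trap_calibration.py       # active-passive calibration
python analysis/03_oscillatory_rheology.py   # moduli + Burgers fits
python analysis/04_interfacial_tension.py    # stretching + rupture tensions
python analysis/05_fusion_comparison.py      # viscocapillary comparison
```

The final script prints the materials-and-fusion table for the four
condensates, e.g. (abridged):

```
name  eta_pa_s  gamma_pn_per_um  tau_fu_ms  tau_fu_newtonian_ms  eta_eff_over_eta     regime
pK:H      0.30             57.1       30.3                 31.1              0.98  newtonian
 P:H      0.53             67.0       39.3                 46.8              0.84   thinning
 S:P      3.75             73.4      384.0                302.0              1.30 thickening
 S:L     10.10            106.0     1774.0                563.0              3.20 thickening

predicted spread 18.1-fold vs measured 58.5-fold
```

The viscocapillary model compresses the predicted spread of fusion times to
~18-fold while the measured spread is ~59-fold: condensates made of
disordered polymers fuse faster than predicted (shear thinning), those with
folded domains fuse slower (shear thickening), and the ratio of the shear
relaxation time τ₁ to the fusion timescale τ<sub>fu</sub>* decides which.

A thin CLI mirrors the library (`condense-rheo simulate|calibrate|rheology|
fit-burgers|tension|fusion-report|run`, see `--help`).

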