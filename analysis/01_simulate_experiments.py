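#!/usr/bin/env python
"""Generate one synthetic example of every experiment type.

Produces, for the pK:H condensate preset: a passive thermal trace, a 1-Hz
driven trap/force pair, a two-trap stretching ramp triple, a rupture ramp,
and a 17-droplet fusion dataset, all seeded, under results/synthetic/.
These files illustrate the raw material every later stage consumes; the
later numbered scripts regenerate what they need in memory.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from condense_rheo.pipeline import child_seeds
from condense_rheo.presets import PK_H
from condense_rheo.simulate import (SimulationConfig, simulate_driven_trace,
                                    simulate_fusion_dataset,
                                    simulate_passive_trace,
                                    simulate_rupture_trace,
                                    simulate_stretch_experiment)
from condense_rheo.trace import write_trace, write_traces_hdf5

OUT = Path("results/synthetic")
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    s_pass, s_drive, s_stretch, s_rupt, s_fus = child_seeds(SEED, 5)
    kt = PK_H.kappa_t_oscillation

    cfg = SimulationConfig(trap_stiffness=kt, sampling_rate=1000.0,
                           duration=10.0, seed=s_pass)
    passive = simulate_passive_trace(PK_H.burgers, cfg)
    write_trace(passive, OUT / "passive_pkh.csv")

    trap, force = simulate_driven_trace(PK_H.burgers,
                                        SimulationConfig(trap_stiffness=kt,
                                                         seed=s_drive),
                                        2 * np.pi * 1.0)
    write_traces_hdf5({"trap_position": trap, "force1": force},
                      OUT / "driven_pkh_1hz.h5")

    cfg_s = SimulationConfig(sampling_rate=100.0, duration=10.0, seed=s_stretch)
    pos, f1, f2 = simulate_stretch_experiment(PK_H.gamma, 5.0, 1.0, 600.0,
                                              600.0, 0.05, cfg_s, noise_sd=0.3)
    for name, tr in [("trap1", pos), ("force1", f1), ("force2", f2)]:
        write_trace(tr, OUT / f"stretch_pkh_{name}.csv")

    cfg_r = SimulationConfig(sampling_rate=100.0, duration=30.0, seed=s_rupt)
    write_trace(simulate_rupture_trace(PK_H.gamma, 1.0, 1.1, 0.1, cfg_r,
                                       noise_sd=1.0),
                OUT / "rupture_pkh.csv")

    rng = np.random.default_rng(s_fus)
    radii = rng.uniform(0.8, 4.0, 17)
    data = simulate_fusion_dataset(PK_H.inverse_fusion_speed, radii,
                                   noise_sd=3.0, seed=s_fus)
    pd.DataFrame({"radius_um": data.radius_um,
                  "tau_fu_ms": data.tau_fu_ms}).to_csv(
        OUT / "fusion_pkh.csv", index=False)

    (OUT / "ground_truth.json").write_text(json.dumps({
        "seed": SEED,
        "burgers": [PK_H.burgers.eta0, PK_H.burgers.tau0,
                    PK_H.burgers.eta1, PK_H.burgers.tau1],
        "gamma_pn_per_um": PK_H.gamma,
        "inverse_fusion_speed_ms_per_um": PK_H.inverse_fusion_speed,
    }, indent=2))
    print(f"wrote synthetic pK:H experiments (seed {SEED}) to {OUT}/")
    print(f"  passive trace var = {passive.values.var():.3e} um^2 "
          f"(kBT/kappa_t = {cfg.kBT / kt:.3e})")


if __name__ == "__main__":
    main()
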