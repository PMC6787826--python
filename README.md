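# chelonia

A spatially explicit individual-based model of adult female green sea
turtles (*Chelonia mydas*) foraging, migrating, and nesting on a gridded
seascape — for movement ecologists and conservation modelers who want to
explore how landscape configuration (rookery placement, feeding-patch
distribution, coastal barriers, ocean currents, localized habitat
degradation) shapes migratory corridors, feeding-ground mixing, and
rookery reproductive output.

## The model in brief

Turtles are capital breeders cycling through five behavioral states:
`feeding → prenesting → nesting → postnesting → feeding`, with occasional
`feeding ⇄ foraging_migration` patch switches. On a half-day time step:

* feeding gains energy `α·Φ_p,t` from a patch whose resource follows
  logistic regrowth with density-dependent grazing,
  `ΔΦ = β·Φ(1 − Φ/Φ_max) − α·N·Φ`, with `β = 2αN_T/N_F` calibrated so the
  evenly grazed system equilibrates at `Φ_max/2`;
* a turtle leaves a depleting patch with per-step probability
  `(1 − S_F)·10⁻³·[1 − σ((Φ − b)/a)]` (`S_F`: patch fidelity, 1 = stayer)
  and picks a new patch with distance-decay weights `(1 − d_rel)^λ`;
* prenesting migration starts once reserves cover a full cycle
  `ε_cycle = 2·Δε_m·d/c + S_N·T_n,max·Δε_n` (`S_N`: nesting allocation,
  1 = investment); nesting lasts `S_N·T_n,max` days and costs `Δε_n`/day;
* migrants swim at `c = 65` km/day toward their target, optionally
  advected by currents, avoiding coasts with a wall-following heuristic
  whose turn side is memorized and mirrored between outbound and return
  legs.

Remigration intervals, rookery reproductive output
(`RO_n = S_N·ΣΣ ε_i,k/ΔT_i,k`), patch usage, origin diversity (normalized
Shannon), and migration-corridor kernel densities all *emerge* from
individual behavior. See `docs/methods.md` for the full description.

## Worked example

```python
import numpy as np
from chelonia import (SimulationConfig, generate_synthetic_landscape,
                      run_simulation, remigration_intervals,
                      reproductive_output)

world = generate_synthetic_landscape(seed=1, preset="reference")
print(len(world.nesting_sites), len(world.feeding_patches), world.width_km)
# 14 47 3969.0

cfg = SimulationConfig(n_turtles=500, steps_total=16_100,
                       steps_burn_in=1_500, min_allocation=3, seed=1)
out = run_simulation(cfg, world)
iv = remigration_intervals(out.nesting_events)
print(len(out.nesting_events), len(iv),
      round(iv.mean_interval_years.mean(), 2))
# 2346 470 4.27

ro = reproductive_output(out.nesting_events, cfg.s_n)
print(ro.head(3).round(3).to_string(index=False))
#  site_id  reproductive_output
#        1               35.657
#        2               33.552
#        3               22.275
```

Reading: on the packaged reference world (14 rookeries, 47 feeding
patches, 7 km cells spanning 3,969 km east–west), 500 turtles over 20
recorded years produce ~2,300 nesting events; the 470 turtles with at
least two events have a grand mean remigration interval of 4.3 years —
inside the 2–7 year band observed for green turtle rookeries worldwide,
which is the model's calibration target. The per-rookery reproductive
output (energy per day of remigration interval, scaled by nesting
investment) is highest for the heavily weighted rookery 1.

The same is available from the shell:

```bash
chelonia landscape generate --preset reference --seed 1 --out world/
chelonia simulate --config config.yaml --landscape world/ --out run0/
chelonia analyze reproduction --runs runs/ --out summary/
```

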