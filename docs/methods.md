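# Model description and methods

`chelonia` is a spatially explicit individual-based model of adult female
green sea turtles (*Chelonia mydas*) cycling between seagrass feeding
patches and natal rookeries on a gridded seascape. It simulates foraging,
energy-gated breeding migration, nesting, resource depletion and regrowth,
current advection and coast avoidance, and derives population-level
statistics: feeding-patch usage and origin mixing, migration-corridor
kernel densities, remigration intervals, and rookery reproductive output.

## World and scheduling

The world is a regular grid of square cells (7 × 7 km in the reference
preset, 567 × 577 cells covering a 3,969 × 4,039 km region, geographic
bounds 25–65°E, 30°S–10°N under an equirectangular map). Cells are
terrestrial (barriers), ocean, nesting sites, or feeding patches; ocean
cells carry a current vector (km/day). Geometry is planar Euclidean in km;
agents hold continuous positions; grid edges are hard boundaries.

One time step is half a day. Each step processes all turtles, then all
feeding patches, both in freshly randomized order with immediate state
updates. A run lasts 36,500 steps (~50 years) at full scale, of which the
first 1,500 are burn-in with no recording. All rate parameters are stored
in daily units and halved once per half-day step.

## Turtles

A turtle carries a position, a natal rookery, a current preferred feeding
patch, an energy reserve, two fixed strategy indices, a coast-avoidance
side memory, and one of five behavioral states with transitions

    feeding → foraging_migration → feeding
    feeding → prenesting → nesting → postnesting → feeding

* **Feeding.** Energy grows by `α·Φ` per step (per-step rates), where `Φ`
  is the patch resource level and `α` the depletion/intake coefficient.
* **Leaving a patch.** Per-step probability
  `P = (1 − S_F) · 10⁻³ · [1 − σ((Φ − b)/a)]` with `σ` the logistic,
  `a` the steepness, `b` the leaving threshold. `S_F ∈ [0, 1]` is the
  patch-fidelity strategy: 1 = "stayer" (never leaves), 0 = "mover".
* **Choosing a new patch.** Distance-decay weights `(1 − d_rel)^λ` over
  all other patches, `d_rel = (d − d_min)/(d_max − d_min)` clamped to
  [0, 1] with `d_min`, `d_max` the extreme inter-patch distances of the
  landscape. The same rule (measured from the rookery) assigns initial
  patches.
* **Breeding trigger.** A turtle departs on prenesting migration once its
  reserve covers a full cycle,
  `ε_cycle = 2·Δε_m·(d/c) + S_N·T_n,max·Δε_n`, i.e. the round trip to the
  rookery at speed `c` and cost `Δε_m`/day plus the nesting stay. The
  threshold is inclusive and deterministic.
* **Nesting.** The stay lasts `round(2·S_N·T_n,max)` half-day steps at a
  cost of `Δε_n`/day; `S_N ∈ [0, 1]` is the nesting allocation strategy
  (1 = "investment", 0 = "conservative"). Completion records a nesting
  event (date, post-nesting energy) and the turtle returns to its last
  preferred patch. There is no mortality or metabolic maintenance cost;
  energy may go negative on unexpectedly long migrations and is logged,
  not clamped.

## Movement and coast avoidance

Migrating turtles swim at a fixed motor speed `c` (default 65 km/day,
32.5 km per step) toward their target. When land blocks the ray within one
step length (sensing horizon 100 km), the heading rotates in fixed
increments (default 15°) on a memorized side, by the minimal angle that
clears. The side is chosen at the first obstruction of a leg as the one
requiring the smaller turn (ties go left), is flipped when postnesting
migration starts (favoring mirror-image out/return routes), and is cleared
at foraging-migration boundaries. While wall-following the heading
persists between steps and relaxes incrementally back toward the target
whenever the way is clear; coast-following ends when the target bearing
itself clears.

Three provisions make the operator total on realistic coastlines; all
three failure modes were observed as permanent limit cycles without them:

1. A bearing whose first obstruction lies beyond the target itself counts
   as clear — otherwise sites and patches tucked against a coast (one cell
   offshore) can never be approached.
2. On final approach (target closer than one step) the motor vector is
   aimed so that the *net* displacement, including the local current,
   lands exactly on the target; otherwise a cross-current can park a
   turtle in a limit cycle just outside the arrival radius.
3. With currents on, the motor step (whose ray is verified clear) is
   applied first and only the drift component is truncated at the coast;
   truncating the summed displacement can cancel a turtle's entire step
   against a shore indefinitely.

Arrival uses a closed detection radius (default 7 km, one cell). Under
the currents scenario the cell-local current (halved per step) is added to
the motor displacement as a true vector sum. Each migrating step costs
`Δε_m/2` regardless of progress.

## Seagrass dynamics

Each patch holds `Φ ∈ [0, Φ_max]` updated per step by logistic regrowth
and density-dependent grazing,

    ΔΦ = β·Φ·(1 − Φ/Φ_max) − α·N·Φ,

with `N` the number of turtles currently feeding there. The regrowth rate
is calibrated as `β = 2·α·N_T/N_F` so that a population spread evenly over
the patches (`N = N_T/N_F`) has its fixed point at `Φ_max/2`; `β` is
recomputed from the configured population and patch count, which preserves
the equilibrium property under uniform down-scaling.

A perturbation (scenario 3) is a latitude band: patches whose latitudinal
distance `d` from the perturbation latitude `σ_y` is below a range
`d_σ,max` lose an extra `σ_i·β·(d_σ,max/d)·Φ` per step. The 1/d factor is
floored at one cell's latitude extent and the result clamped at zero,
making the operator total even for a patch at the perturbation latitude
(the source description only notes the distance "remains positive").

## Scenarios, experiments, initialization

Scenario 1 has no currents, scenario 2 adds current advection, scenario 3
has no currents but activates the perturbation (default: centred at 28°S
with a 13° range, intensity 0.2, covering the southern feeding grounds).
The default experiment is the full factorial 3 scenarios × 4 values of
`S_F` × 4 values of `S_N` (0.2, 0.4, 0.6, 0.8) × 5 replicates = 240 runs,
each with a distinct derived seed.

Initialization allocates 7,000 turtles to rookeries proportionally to
their weights with a minimum head-count of 45 (scaled as
`round(45·N_T/7000)` at other population sizes). Rookeries whose
proportional share floors to at most the minimum are pinned exactly at the
minimum and the remainder is split among the others by largest remainder,
so counts always sum exactly to `N_T`. Each turtle starts feeding at a
distance-decay-assigned patch with energy uniform on `(0, ε_cycle)` for
its own patch–rookery distance; patch resources start uniform on
`(0, Φ_max)`, or at `Φ_max` when depletion is disabled (`α = 0`). One root
seed per run drives every stochastic draw; identical (config, seed) runs
are bit-identical.

## Observation and statistics

After burn-in the engine records per-patch tallies (time usage,
postnesting visits with rookery of origin, foraging visits), nesting
events, and Bernoulli-thinned track samples of pre/postnesting migrants
(probability 1/500 per migrating turtle-step — a rate, not a stride, so
records are independent of turtle indexing; foraging migrations are not
sampled). Statistics:

* **Origin diversity** per patch: normalized Shannon index
  `H = −Σ r ln r / ln N_N ∈ [0, 1]` over the origin rookeries of
  postnesting visitors.
* **Remigration interval**: per-individual mean difference between
  successive nesting dates, converted at 0.5 day/step and 365.25
  days/year; individuals with fewer than two events are excluded.
* **Reproductive output** per rookery:
  `RO_n = S_N · Σ_i Σ_k ε_i,k / ΔT_i,k` with `ΔT` in days, summing each
  individual's post-nesting energy over its remigration intervals.
* **Corridor kernels**: Gaussian product-kernel density of pooled track
  positions (default 125 subsampled per run, without replacement),
  bandwidth by a Silverman-type rule unless given, normalized to integrate
  to 1 over the grid.

## Parameter defaults and calibration

| parameter | default | units | meaning |
|---|---|---|---|
| `N_T` | 7,000 | turtles | population (no birth/death) |
| steps | 36,500 / 1,500 | half-days | run length / burn-in |
| `c` | 65 | km/day | motor speed (regional telemetry estimate) |
| `α` | 0.001 | 1/day | depletion & intake coefficient |
| `Φ_max` | 1,000 | resource units | patch carrying capacity |
| `a`, `b` | 50, 300 | resource units | leave-probability steepness, threshold |
| `λ` | 5 | – | distance-decay exponent |
| `Δε_m` | 10 | energy/day | migration cost |
| `Δε_n` | 5 | energy/day | nesting cost |
| `T_n,max` | 100 | days | maximum nesting stay |
| detection | 7 | km | arrival radius |
| sensing | 100 | km | coast sensing horizon |
| angle step | 15 | degrees | wall-following increment |

`Φ_max` is a pure scale choice (`α·Φ` and the equilibria scale with it).
The energy parameters were calibrated once, jointly, against the model's
own design target: the emergent mean remigration interval on the reference
world should fall in the 2–7 year band reported for green turtle rookeries
worldwide. With these defaults desk-scale reference runs (500 turtles,
20 recorded years, three seeds) yield a grand mean of ≈4.5 years. Nesting investment
lengthens the interval (higher `S_N` → costlier cycles → longer recovery),
as expected for a capital breeder.

## Synthetic worlds

Real seascape rasters are not shipped; `generate_synthetic_landscape`
builds three deterministic worlds:

* **minimal** — a 10×10 all-ocean world, 1 rookery, 2 patches, no
  currents; the smallest world the full scheduler runs on.
* **channel** — 140×140 cells: a western continental coastline, an
  elongated tilted barrier island partitioning a channel, patch clusters
  hugging both coasts, three island rookeries, and the parametric gyre.
* **reference** — 567×577 cells with 14 rookeries carrying the reference
  relative weights (10,000 : 5,000×3 : 2,000×2 : 200×8, summing to
  30,600) and 47 feeding patches, structurally mimicking the south-west
  Indian Ocean: continental coast in the west with a northern cape,
  a large elongated island in the south-centre, island rookeries in and
  around the channel.

The current field derives from a Stommel-type western-intensified gyre
stream function: a narrow strong boundary jet (peak ~40 km/day over
water, roughly half the turtles' motor speed, matching an energetic
western boundary current) along the western coast and channel, and a
broad moderate interior return flow. An earlier draft used a
symmetric-cell gyre whose currents vanished along every coast; that is
physically wrong for a region dominated by boundary currents and put the
strong flow exactly where no turtle travels, so it was replaced.

What the synthetic worlds do *not* emulate: real bathymetry and coastline
shape, seasonal and mesoscale current variability, true seagrass-bed
extents, and the actual geographic placement of rookeries. Tests that
pass on these worlds demonstrate the mechanics and directional behavior
of the model, not quantitative predictions for the real region.

## Desk-scale study conditions

Full-scale runs (7,000 turtles × 36,500 steps) are supported but slow on
one core. The packaged verification runs use a uniformly scaled design:
500 turtles on the full reference grid, 16,100 steps (1,500 burn-in +
20 recorded years), three replicate seeds. `β` recomputed from the scaled
`N_T` preserves the resource equilibrium, and the scaled minimum rookery
allocation (3) preserves the allocation rule's behavior. Directional
strategy comparisons run on the reference world at the same desk scale
(500 turtles, ~7.5 recorded years, ≥5 replicate pairs with shared seeds,
one-sided Wilcoxon signed-rank).

## Known limitations

* Two strategy×scenario interactions are not resolved at desk scale.
  The mover/stayer differential in reproductive-output loss under
  currents has the expected sign but is weak: with the 10⁻³ cap on the
  per-step leaving probability, foraging migrations are rare, so the
  extra current exposure of "movers" is a small signal against
  between-run RO variance (roughly 6× less noise would be available at
  full scale). The conservative/investment differential in perturbation
  loss does not emerge under the shipped calibration at all — its sign is
  not forced by the model equations and depends on the relative weight of
  migration and nesting costs in the energy cycle. Both checks are kept
  in the verification suite at full strictness and currently fail there;
  the nearest-rookery perturbation impact reproduces robustly.
* Wall-following is a heuristic: on strongly concave coasts paths are
  near-minimal only up to the angular increment, and a fully enclosed
  turtle stays put (reported) rather than re-routing.
* The perturbation acts uniformly within its latitude band; no spatial
  recovery dynamics or patch-specific vulnerability.
* No demography: reproductive output is an energy-flux proxy, not a
  population projection.
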