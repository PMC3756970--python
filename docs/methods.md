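# Methods

## Model overview and assumptions

`invadrift` is a stochastic cellular automaton for the spread of a
broadcast-spawning coastal fish with pelagic larvae. Its core assumptions:

* **Kernels, not individuals.** Larval output is quantized into transport
  kernels (default 20 per spawning event, each standing for ~750 viable
  larvae). A kernel moves, survives and settles as a unit; there is no
  within-cell demography and no density dependence. A settled kernel is one
  population unit, juvenile until the maturation age, then an adult that
  spawns every in-window cycle until killed.
* **Passive transport.** Larvae drift with the monthly mean current field;
  adults do not move between cells. There is no behavioural swimming, no
  vertical structure, and no local retention bonus at the natal cell.
* **Binary habitat.** A cell is habitable in a given month iff SST,
  chlorophyll and depth all lie inside their configured ranges. A graded
  (triangular, peak mid-range) scoring variant exists behind
  `graded_suitability` but is off by default, because tolerance data for
  newly observed invaders are range-type, not response-curve-type.
* **Climatological forcing.** Twelve monthly layers are recycled across
  simulation years: calendar month = ((SM − 1 + cycle − 1) mod 12) + 1 with
  starting month SM. Interannual variability is out of scope.
* **Founder persistence.** A run starts from a single breeding-eligible
  founder at the origin (a protogynous hermaphrodite can found a breeding
  population alone). By default the founder faces the same monthly
  mortality draw as every other adult; `founder_immortal=True` instead
  holds the origin population permanently, for experiments whose premise is
  that a breeding population persists at the origin.

## Parameters

Defaults describe a panther-grouper-like life history. All are fields of
`ModelConfig` (units in comments there); the consequential ones:

| parameter | default | meaning |
|---|---|---|
| `cycles` | 78 | monthly steps per run (a 60-cycle variant is documented in the config schema) |
| `grid_size` | 6 arc-min | lattice cell size (~10 km) |
| `propagule_duration` D | 40 d | drift time before settlement |
| `propagule_mortality` Z_p | 0.2 d⁻¹ | instantaneous larval mortality |
| `adult_mortality` Z | 0.26 y⁻¹ | instantaneous adult mortality |
| `breeding_age` | 18 mo | settlement-to-maturity lag |
| `egg_quantity` × rates | 200,000 × 0.25 × 0.30 | viable larvae Q = 15,000 per spawn |
| `kernel_count` K | 20 | kernels per spawning event (Q/K ≈ 750 larvae each) |
| `sst_range` | 16–32.82 °C | thermal tolerance |
| `cc_range` | 0.10–99.981 µg L⁻¹ | chlorophyll (productivity proxy) tolerance |
| `depth_range` | 1–40 m | neritic habitat limit |
| weights (OC, SST, CC, OD) | 0.90, 0.02, 0.02, 0.02 | neighbor-score weights, normalized to sum to 1 at construction |

### Hazard conversions

Mortality inputs are instantaneous rates on different time bases, so they
are converted to per-event probabilities with the standard exponential
survival model: a kernel survives its whole drift with exp(−Z_p·D)
(3.355 × 10⁻⁴ at the defaults), and an adult dies in a 30-day cycle with
1 − exp(−Z/12) (0.02143 at Z = 0.26 y⁻¹). A `mortality_mode="literal"`
flag instead uses Z directly as a per-cycle probability — the naive
reading of "random value falls below Z" — which at 26% monthly adult
death is demographically implausible and exists only for comparison.

## The monthly cycle

Order of operations in `step_month`:

1. every alive, breeding adult whose calendar month is inside the breeding
   window releases `kernel_count` kernels, `spawns_per_cycle` times;
2. kernels drift (below) and settle or die; survivors become age-0
   juveniles;
3. the whole settled pool — including this cycle's recruits — takes the
   adult-mortality Bernoulli draw;
4. survivors age one month; any reaching `breeding_age` is promoted and
   begins contributing from the *next* cycle;
5. cycle and calendar month advance.

A cell's establishment cycle is the first cycle it holds a breeding
population (the origin counts from cycle 0).

### Transit mechanics

Step probabilities to the 8 neighbors combine current alignment
(cosine of the angle between the cell's current bearing and the bearing to
the neighbor, clipped at 0, scaled by speed relative to the grid-wide
monthly maximum) with the neighbor's weighted binary suitability. In slack
water the current term vanishes and the static habitat weights take over;
if every neighbor scores zero the step is uniform over marine neighbors.
Land cells are never entered; a kernel whose 8 neighbors are all land dies
(conservative choice; the alternative of waiting in place would let
kernels survive in enclosed ponds indefinitely).

Dwell time in a cell is its east–west width at that latitude
(cell-degrees × 111,200 m × cos φ, using the destination cell's width)
divided by current speed, with speed floored at `min_current_speed`
(0.01 m s⁻¹, i.e. a maximum dwell of ~13 days) so stagnant cells cannot
trap a kernel forever. The running drift-time sum advances the monthly
fields at each 30-day boundary; when it reaches D the kernel stops, takes
the exp(−Z_p·D) survival draw, and settles iff the final cell is habitable
in the month the clock expired. The entire walk is resolved within the
spawning cycle.

### Stochastic stream contract

Each simulation consumes a single `numpy` PCG64 generator in a fixed
order: per spawning adult (list order), one survival-uniform vector over
its kernels; then all surviving kernels of the cycle walk as one batch,
drawing one uniform per still-drifting kernel per hop; then one
mortality-uniform vector over the settled pool. Runs are therefore
bit-reproducible given (config, environment, origin, months, seed). The
survival draw is taken *before* the walk so that kernels destined to die
in transit are never traced — statistically identical to drawing after
the walk, since the draws are independent, but much faster at realistic
survival rates.

## Validation statistics

* **Quadrant sequences.** A run reduces to the list of 0.5° × 0.5°
  quadrants ordered by first establishment cycle (ties broken by
  lexicographically smaller quadrant id; a quadrant appears once).
* **Representative sequence / model.** Across replicates, the modal
  quadrant at each of the first n steps, where n is the number of
  quadrants common to *all* replicate sequences; position ties take the
  lexicographically smallest id. The Representative Model (RM) is the
  replicate agreeing with the modal sequence at the most positions
  (ties → lowest index). All tie rules are stated in the report text.
* **Spearman's ρ.** Two sequences are aligned on their common quadrants
  and re-ranked 1..n in each sequence's own order (this leaves no rank
  ties), then ρ = 1 − 6·Σd²/(n(n²−1)). At least 3 common quadrants are
  required; comparisons below that are reported "not calculable" rather
  than forced.
* **Critical values.** P(|ρ| ≥ c) under the uniform-random-permutation
  null, restricted to the achievable support of ρ, reported to two
  decimals: exact enumeration of all n! permutations for n ≤ 10 (a
  vectorized first-element decomposition keeps n = 10 under a second),
  Monte-Carlo with ≥ 10⁷ permuted rank vectors otherwise. This reproduces
  the published two-tailed 0.05 values 0.65 (n = 10) and 0.59 (n = 12).
  Reports computed inside `validation_report` default to 2 × 10⁵ draws for
  speed; the acceptance script uses the full 10⁷.
* **Null model.** Pure random contagion: each cycle every occupied cell
  establishes one uniformly random not-yet-occupied marine neighbor
  (snapshot semantics; new cells activate next cycle), with currents,
  habitat and fecundity all removed, run to closure of the reachable
  marine component. This is the simplest spread process driven by a single
  stochastic variable; the growth rule is isolated behind
  `run_null_model` and can be swapped.

## Synthetic environment

`generate_synthetic_environment` builds a deterministic-per-seed 6° × 6°
(60 × 60 cell) shelf sea emulating a subtropical western-boundary system:

* land to the west with a gently meandering coastline;
* a coast-parallel northward jet (peak 1.8 m s⁻¹ — the exact grid/12-month
  maximum by construction) that separates from the coast at 27.5° N and
  veers offshore to the northeast;
* a weak recirculation inshore and north of the separation: a fast-ish
  (0.18 m s⁻¹) offshore delivery branch, a slow (0.06 m s⁻¹) coastal
  counter-current, so larvae that leave the jet are carried to the far end
  of the retention zone first and back-fill southward — the transport
  structure that makes establishment order *not* a function of radial
  distance from the origin;
* discrete shallow (< 40 m) shelf habitat bands along the coast separated
  by deeper nearshore floors, giving stepping-stone establishment staged
  over generations;
* SST with a steep meridional gradient and a seasonal cycle (August peak)
  such that winter values north of 29° N fall below the 16 °C tolerance
  for any noise seed;
* chlorophyll decaying offshore below the 0.10 µg L⁻¹ suitability floor.

The domain compresses a much larger physical system into 6° of latitude,
so its SST gradient (2.9 °C per degree) is deliberately steeper than any
real ocean. What the generator does **not** emulate: mesoscale eddies,
interannual variability, tides, realistic bathymetric texture, and any
correspondence between its coordinates and real coastlines. Tests passing
on this environment demonstrate the engine's transport, demographic and
statistical machinery — not a validated forecast for a real coastline,
which requires real current/SST/chlorophyll/bathymetry rasters (loadable
through the same readers).

## Test scenario sizes

The replicate-ensemble tests run 20 simulations × 78 cycles on the 60 × 60
synthetic environment with Z_p = 0.05 d⁻¹, two spawning events per cycle
and a persistent founder. The lowered larval mortality (well inside the
0.01–0.69 d⁻¹ range documented for marine teleost larvae) and doubled
spawning give each replicate a rich establishment sequence — at the
default Z_p = 0.2 d⁻¹ a single founder settles less than one kernel per
78-month run in expectation, which is the regime the sensitivity analysis
probes but is useless for exercising sequence statistics. Sensitivity
comparisons (Z_p 0.18 vs 0.22 d⁻¹) use common random numbers: replicate i
receives the same derived seed in every scenario, coupling the survival
draws so the settled-count ordering reflects the mortality change, not
sampling noise.

## File formats

Rasters are plain-text ESRI ASCII grids (row 0 = north, NODATA → NaN,
above-sea-level cells forced to land); whole stacks round-trip through a
single NetCDF3 file (scipy engine) or a directory of per-layer grids.
Current fields may be supplied as speed + bearing-from-north or as u/v
components, which are converted on read (monthly means of daily fields
should be vector means). Occurrence records, event logs, sequences and
reports are CSV; every CLI run writes a `run.json` sidecar with the
config hash, seed and package version.

## Known limitations

* Absolute settled-kernel counts are steeply sensitive to Z_p (they scale
  with exp(−Z_p·D)) and to spawning richness; only relative comparisons
  under common random numbers are meaningful across configurations.
* Establishment requires a single kernel to survive to maturity — there is
  no Allee effect, so forecasts are optimistic for species that need
  multiple colonists.
* The 8-neighbor walk discretizes direction to 45° sectors; strongly
  anisotropic flow at angles between sectors acquires lattice artifacts.
* Monthly climatology plus a 30-day cycle means larval timescales shorter
  than a month are unresolved; D is best kept ≥ a few days' worth of cell
  crossings.
* Suitability is evaluated at settlement only; established populations
  never die of habitat change (winter cold kills recruitment, not
  standing populations).
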