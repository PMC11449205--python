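# Methods

This document describes the movement model, the randomization schemes, the
interaction/network definitions, the inferential procedure, and the numerical
and design choices behind `movenull`. Nothing here reports empirical results;
for reproducible numbers run `scripts/acceptance.py` and the test suite.

## 1. Movement model (BCRW simulator)

Each agent performs a biased-correlated random walk (BCRW) in a continuous
2-D plane, organised into days of a fixed number of steps.

**Step lengths** are gamma-distributed. The gamma is parameterised by moment
matching: shape = (mean/sd)², scale = sd²/mean, so the configured `step_mean`
and `step_sd` are the exact distribution mean and standard deviation.

**Step directions.** At every step the agent has a *bias target* (see below).
The realised heading is the bearing to the target plus Von Mises(0, κ_step)
noise. With `heading_blend > 0` the bearing is first blended with the
previous heading (circular interpolation), giving an explicit correlated
component; the default `heading_blend = 0` is a pure biased walk whose
directional persistence comes from the persistence of the target itself.
If an agent sits exactly on its target, the bearing is defined as 0 radians;
with κ_step = 4 noise this is a negligible, documented convention.

**Home ranges.** Each agent has a home-range (hr) centre that moves once per
day by a gamma step (mean `hr_step_mean_factor × step_mean`, sd
`hr_step_sd_factor ×` that mean) in a direction that depends on the scenario:

- `static` — uniform random direction, tiny daily step (factor 0.01): the
  centre jitters but does not move at the season scale.
- `local` — uniform random direction, large daily step (factor 10): the
  centre wanders without persistent direction.
- `directional` — Von Mises(previous hr heading, κ_hr = 20) direction, large
  daily step: the centre drifts persistently across the landscape, the
  scenario in which path shuffling teleports animals the furthest.

Agents start at their hr centre; hr centres start uniformly in a square of
side `start_square_side` (default ⅔ of the perception distance) so that
neighbours are initially perceivable.

**Social rule.** When `social=True`, an agent whose nearest neighbour lies
within `perception_distance` (inclusive; ties broken toward the lowest agent
id) targets the convex combination
`w · nearest_neighbour + (1 − w) · hr_centre` with `w = social_weight`;
otherwise (and always when `social=False`) it targets its hr centre.
`social=True, social_weight=0` is bit-identical to `social=False`.

### Parameter defaults

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `n_agents` | 30 | — | population size of the validation experiments |
| `n_days` | 50 | days | tracking-period length of the validation experiments |
| `steps_per_day` | 50 | steps | within-day resolution |
| `step_mean` | 7 | length units | calibration target of the step-length gamma |
| `step_sd` | 5 | length units | calibration target of the step-length gamma |
| `kappa_step` | 4 | — | Von Mises concentration; gives semi-linear daily paths rather than Brownian wiggle |
| `heading_blend` | 0 | — | pure bias toward target; raise for explicit heading memory |
| `social_weight` | 0.75 | — | strong but not total attraction when `social=True` |
| `perception_distance` | 1000 | length units | radius within which a neighbour can be targeted |
| `hr_scenario` | `static` | — | simplest spatial-constraint scenario |
| `hr_step_mean_factor` | 0.01 (static) / 10 (local, directional) | — | daily hr displacement relative to `step_mean` |
| `hr_step_sd_factor` | 0.75 | — | sd of the daily hr step relative to its mean |
| `kappa_hr_directional` | 20 | — | strong heading persistence of drifting hr centres |
| `start_square_side` | ⅔ × `perception_distance` | length units | initial crowding so interactions can occur |
| `seed` | None | — | explicit seeding required for reproducibility |

Reproducibility: all randomness derives from per-agent
`numpy.random.SeedSequence` substreams spawned from the single config seed, so
results are independent of vectorization order and bit-reproducible across
runs.

## 2. Randomizations

Both schemes operate on *whole tracked days per individual*: the within-day
path is never altered, only which day label it carries. The randomized
dataset keeps an `orig_day` provenance column and a plan object recording
every shift/permutation.

**Wrap-around.** For each individual draw k ~ Uniform{−s, …, +s} (k = 0 is a
legal draw and is not re-drawn; it leaves that individual unchanged, which is
the correct marginal behaviour of the scheme). Sort the individual's tracked
days; the day at sorted position i receives the data of the day at position
(i + k) mod n. Structural guarantee: at most one pair of adjacent slots holds
non-consecutive original days (the wrap seam), i.e. ≤ 1 teleportation, and
exactly 0 when k ≡ 0 (mod n). Two gap conventions are provided: `tracked`
(default) rotates the sequence of actually-tracked days, and `calendar`
rotates positions on the full calendar so gaps travel with the shift.

**Path shuffling.** A uniform random permutation of each individual's tracked
days, optionally restricted to contiguous windows of `window` days. Up to
n − 1 teleportations are possible.

**Downsampling** keeps `points_per_day` fixes per day at (1-based) indices
⌈1 + (j − 1)·S/p⌉, emulating coarser GPS schedules.

## 3. Interactions and networks

- **Co-location**: two individuals within a distance threshold at the same
  (day, step). The threshold is *strictly less than* `2 × step_mean`
  (default 14 length units) — twice the mean step, the distance two animals
  can close in one step.
- **Co-movement**: co-located at two consecutive steps *within the same day*;
  runs never chain across day boundaries; the record is placed at the second
  step.
- **In-flight interaction** (for timestamped GPS data): both individuals
  moving faster than `speed_min` (default 5 m/s, computed from the previous
  grid interval) while within `dist_max` (default 1000 m) for at least
  `n_consecutive` (default 2) consecutive grid intervals (default 600 s).
  Timestamps must already sit on a regular grid
  (`regularize_timestamps` snaps them, dropping fixes further than the
  tolerance from the grid and keeping the nearest fix on collisions).

Distances are Euclidean for projected coordinates and great-circle
(haversine, R = 6 371 000 m) for lon/lat degrees; no projection management is
attempted — declare the coordinate convention in the file dialect.

Networks are undirected `networkx` graphs over a chosen node set (by default
all tracked individuals, so isolates exist and count in means). Edge weights
are raw interaction counts or the Simple Ratio Index (SRI): counts divided by
the number of jointly tracked (day, step) periods of the pair. Node metrics
are degree (count of associates) and strength (sum of incident edge weights);
population summaries are means over *all* nodes, isolates included.

## 4. Inference

An observed network statistic (population mean degree or mean strength) is
compared against the distribution of the same statistic over `n_iterations`
randomized datasets:

- **z-score**: (observed − null mean) / null sd (NaN when the null has zero
  variance; significance then falls back to strict comparison against the
  constant null value).
- **Significance** (two-tailed, α = 0.05): observed above the empirical
  97.5th percentile or below the 2.5th percentile of the null values
  (`numpy.quantile`, default linear interpolation).
- **tail_fraction**: 2 × min(fraction of null ≥ observed, fraction ≤),
  clipped to [0, 1] — a counting-based two-tailed p analogue.
- Replicate-level error rates: `false_positive_rate` is the fraction of
  non-social replicates declared significant; `false_negative_rate` the
  fraction of social replicates not declared significant.

`run_experiment_grid` crosses methods × shift ranges × social weights ×
downsampling levels × replicates; replicate seeds are drawn from a
`SeedSequence` of the grid seed and kept below 2³¹ so they are portable to
any RNG or file format.

## 5. What the generator does and does not emulate

The simulator is a *validation instrument*, not a wildlife emulator. It
captures the two confounded causes of proximity — social attraction and
shared/static/drifting space use — with enough realism to test whether a
randomization can separate them. It deliberately omits: central-place
(roost) returns, landscape heterogeneity and resource patches, group-level
decision making (each agent tracks only its single nearest neighbour),
day/night activity cycles, variable fix success, and observation error.
Conclusions about the randomizations' error rates transfer only insofar as
real systems share the simulated structure of spatial constraint.

## 6. Numerical choices and limitations

- Gamma moment matching is exact for mean/sd; no fitting is involved.
- Von Mises sampling uses `numpy.random.Generator.vonmises`; κ = 0 is treated
  as the uniform circular distribution.
- Movement files are parsed with `float_precision="round_trip"` so
  write → read is lossless for coordinates.
- Empirical percentiles with few iterations are coarse: with 100 iterations
  the 2.5th/97.5th percentiles interpolate between order statistics 3–4 and
  97–98; use ≥ 1000 iterations for publication-grade tails.
- Problem sizes used in the test suite (e.g. 15 agents × 25 days for
  detection and false-positive checks, full 30 × 50 for the
  directional-scenario comparison) are the package's own accuracy/runtime
  trade-offs, chosen so the full suite runs in minutes on one CPU.
- The wrap-around preserves each individual's *set* of daily paths exactly;
  it cannot control for within-day social processes, and with very small `s`
  the null is close to the observed data, making the test conservative.
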