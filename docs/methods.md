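# Methods

## Model

`beeloop` simulates a central-place-foraging bumblebee as a persistent
turning walker (PTW): 2-D flight at constant speed `v` whose signed
angular speed `ω(t)` (rad/s) follows an Ornstein–Uhlenbeck process

    dω = −γ [ω − ω*(t)] dt + σ dW,

with autocorrelation coefficient `γ` (1/s) and noise amplitude `σ`
(rad/s^½). The target angular speed implements intermittent homing:

    ω*(t) = η(t) φ(t),    η(t) = 0 for t < τ,  η* for t ≥ τ,

where `φ` is the signed angle from the current velocity to the homing
vector (nest − position), assumed available through path integration, and
`τ ~ Exp(mean α = 1/p_return)` is the per-loop switch from exploration to
return. A loop ends on the first sample inside the nest disc
(`nest_radius` = 13 m) during the return phase; loops still open after one
hour are censored. Homing makes the spatial distribution around the nest
stationary (a non-equilibrium stationary state); with `η* = 0` the model
degenerates to an unbounded diffusive search.

### Discrete-time update

With step `Δt` (default 0.01 s), each step applies, in order: position
advances with the current velocity; heading advances with the current
`ω` (wrapped to (−π, π]); velocity is recomputed from the new heading at
constant speed; and `ω` takes the exact OU transition

    ω ← ω e^(−γΔt) + ω* (1 − e^(−γΔt)) + s ξ,
    s² = σ² (1 − e^(−2γΔt)) / (2γ),   ξ ~ N(0, 1).

The transition is exact for the OU process, so halving `Δt` changes loop
statistics only through the kinematic integration (checked by a
distributional Δt-halving test). We use the minus sign in `s²`: it is the
standard OU Green-function variance, the only version that vanishes as
`Δt → 0` and approaches the stationary variance `Ω = σ²/(2γ)` as
`Δt → ∞`, consistent with the variance identity used for fitting.
`φ` is recomputed every step during the return phase.

Within a multi-loop trip, a walker re-entering the nest disc in return
phase starts a fresh loop from its current position: heading redrawn
uniformly, `ω = 0`, fresh `τ`. This makes loops i.i.d., matching the
assumption behind the batch-of-independent-loops calibration. Once in the
return phase the walker stays there until nest re-entry (the switch is
one-way per loop).

### Parameters

| name | unit | default | meaning |
|---|---|---|---|
| `gamma` | 1/s | 1.0 | angular-speed autocorrelation (relaxation) |
| `sigma` | rad/s^½ | 0.37 | angular-speed noise amplitude |
| `p_return` | 1/s | 1/30 | switch probability per unit time (α = 30 s) |
| `eta_star` | 1/s | 0.2 | homing steering strength |
| `speed` | m/s | 5.0 | constant flight speed |
| `dt` | s | 0.01 | integration step |
| `nest_radius` | m | 13 | loop-termination disc radius |
| `max_loop_duration` | s | 3600 | loop censoring cap |

The first four defaults are the calibrated population-level values for
*Bombus terrestris* exploration flights. The derived fitting
parameterization is `Ω = σ²/(2γ)` (≈ 0.07 rad²/s²) and `α = 1/p_return`;
both round-trip exactly with the native parameters.

Flight speed is not identifiable from the loop observables (they are
either speed-free shapes or scale linearly with `v`), and we treat
`v = 5 m/s` as a plausible bumblebee ground speed. Every absolute spatial
magnitude downstream — MSD, localization radius, discovery radius —
scales with `v`, so those magnitudes should be read as order-of-magnitude
(the package's tests check their directions and orderings, not their
absolute values).

## Loop observables

Tracks are segmented into nest-to-nest loops by crossings of the 13 m
disc; the entering/exiting samples inside the disc are included so
lengths are not truncated. Fragments with no observed departure (track
starts outside the disc) or no observed return are flagged censored, and
excursions that never leave the disc are not loops. Note that a simulated
behavioural loop can dip back inside the disc during exploration, so
disc-crossing extraction of a chained trip can yield more loops than the
simulator's internal return events; calibration therefore treats each
independently simulated loop as one loop, exactly as the termination rule
defines it.

Four observables summarize each loop: total length (m); extension
(maximum nest distance, m); self-intersections per 100 m; re-departures
per 100 m (three consecutive samples approaching then receding from the
nest). The two rates are rounded to the nearest integer: they are event
counts, and integer binning makes their PMF L1 distance well defined.
Self-intersections are transversal crossings of non-adjacent polyline
segments (strict orientation test; endpoint touches and collinear
overlaps excluded), cross-checked in the tests against a shapely-based
all-pairs oracle.

Simulated observables are computed after resampling to the 3.3 s
harmonic-radar cadence (nearest-sample rule, endpoints kept) so that
sampling-rate-dependent counts are compared like with like against
radar-derived references; the interval is a configuration switch. The
radar preprocessing step that collapses hovering near a feeder (all
consecutive samples within 6 m of a flower → one sample at the flower) is
provided for experimental tracks; 6 m is the 20 cm-flower perception
distance (~4 m) plus ~2 m radar noise.

## Calibration

`fit_grid` scores every combination of a `(γ, Ω, α, η*)` grid (the full
default grid has 11 × 10 × 7 × 8 = 6160 combinations) by simulating a
batch of loops (default 10³), computing the four observable
distributions, and measuring for each observable a distance to the
reference: area between empirical CDFs for the continuous observables,
L1 distance between relative-frequency PMFs for the discrete ones.
Distances are rank-normalized to quantiles (rank/N, mid-ranks for ties)
within each observable so heterogeneous scales get equal weight, and the
combination with the lowest mean quantile wins; ties break
lexicographically on the parameter tuple, making the fit deterministic
given (seed, grid, n_loops). Combinations whose loops are all censored
get infinite distances and are logged.

By default all combinations share one noise stream (common random
numbers): the same initial headings, switch-time draws and OU noise paths
are reused for every combination, so Monte-Carlo error in the distances
is strongly correlated across the grid and largely cancels under ranking.
This markedly sharpens discrimination at a fixed simulation budget and is
switchable (`common_random_numbers=False`) for independent streams.

A structural identifiability caveat: at the 3.3 s radar cadence the
sampled path carries little information about `γ` and `Ω` separately —
the coarse-grained path geometry depends mainly on the heading diffusivity
`Ω/γ`, because the angular-speed correlation time 1/γ (~1 s) is shorter
than the sampling interval. Distribution distances between
immediately neighbouring grid points along this ridge are small compared
with Monte-Carlo noise at a few hundred loops per combination. The
package's parameter-recovery experiment therefore uses a coarse
surrounding subgrid (centre and extremes of each parameter's fitted
range), where adjacent combinations are statistically distinguishable at
that budget; with common random numbers the generating combination is
recovered reliably.

## Flower fields and discovery

A flower of diameter `D` is perceived at distance `D / (2 tan(θ/2))`
with `θ = 3°` (the bee's angular detection threshold): 3.8 m for 20 cm,
13.4 m for 70 cm flowers. Fields are squares of half-width 1000 m
(≥ 3× the exploration range at the calibrated parameters, so boundary
effects are negligible) with a deterministic `round(density × area)`
flower count placed uniformly — matching an *average* density while
keeping the count reproducible.

Discovery is tested at every simulated position (step length
`vΔt = 0.05 m` is far below perception distances of metres, so
segment-vs-disc misses are negligible); a uniform spatial grid of cells
no smaller than the perception radius keeps the per-step test O(flowers
in the 3×3 neighbourhood). Each flower is discovered at most once per
trip. Policies: *no masking* records every zone entered and never
truncates; *masking* truncates the trip at the F-th discovery (F = 1
default; the walker does not pause at flowers); *depletion* truncates on
the first fresh discovery or after `F_depleted` encounters with flowers
depleted by earlier trips (unbounded budget allowed). The
discovery-probability profile averages per-flower discovery indicators in
10 m distance bins, then across environments; the discovery radius is the
outer edge of the contiguous run of bins (from the nest outward) with
probability ≥ 10⁻² per trip, skipping never-populated bins. Colony
counts fix one field per replicate, run sequential trips (depletion
threads the depleted set across trips), and count flowers discovered at
least once.

The study conditions for the density sweeps (the discovery-experiment
axes) are log-spaced densities between 10⁻⁵ and 10⁻² flowers/m² with
flower diameters of 25–70 cm; defaults for the profile and colony
experiments are scaled to 200 trips × 20 environments and 100 trips ×
20 replicates respectively, with the larger published-scale sizes
(6000/10000, 100/80) reachable through the same arguments.

`estimate_msd` pools squared nest distances (sampled every 10 steps)
over chained loops; censored-loop samples are included up to the one-hour
cap, which only matters in the weak-homing diffusive regime where no
stationary state exists.

## What the synthetic data does and does not show

All tests run on data generated by the simulator itself (there is no
bundled radar dataset). Parameter recovery on simulator-generated
references validates the calibration machinery — that the distances,
quantile normalization and argmin pick out a generating process — but
not that the PTW family fits real bee tracks; the published 207-loop
radar dataset is external to this package. Likewise the discovery
experiments establish the *qualitative* masking phenomena (profile
ordering, shrinking discovery radius, interior density optimum, its loss
under unbounded depletion) robustly across seeds; their absolute
magnitudes inherit the uncertainty of the unmeasured flight speed.
Real radar data also contain measurement noise (~2 m), learning flights
near the nest, and behavioural heterogeneity between individuals, none of
which the generator emulates.

## Numerical choices

- Angle wrapping to (−π, π] via `π − (π − x) mod 2π`; `φ` at the nest is
  undefined (error in the scalar API; the kernels terminate on nest
  re-entry before the singularity can matter).
- ECDF area distance integrates the piecewise-constant |F_a − F_b|
  exactly over the union support; no binning.
- PMF L1 uses relative frequencies on the union of observed integer
  values; disjoint supports give the maximal distance 2.
- Rate rounding uses floor(x + 0.5) (half-counts round up) for
  determinism across platforms.
- Degenerate loops (never outside the nest disc) are excluded from
  observable distributions in both simulated and reference samples.
- Compiled kernels (numba) mirror the pure-Python reference operations;
  both paths are cross-checked in the deterministic (σ = 0) limit. All
  kernels consume randomness in a fixed order, so a truncated discovery
  trip can be replayed exactly by the plain trip kernel with the same
  seed.
- Per-stream seeds derive from `numpy` `SeedSequence`s of the user seed;
  identical seed + parameters ⇒ bitwise-identical trajectories.

## Known limitations

- 2-D flight at constant speed; no wind, altitude, or variable airspeed.
- No learning flights, route memory or traplining; depletion is binary.
- The exploration→return switch is memoryless and one-way per loop.
- Absolute spatial scales depend linearly on the assumed 5 m/s speed.
- `γ` and `Ω` are jointly weakly identified from coarsely sampled tracks
  (see the calibration caveat above); fits on real 3.3 s data constrain
  `Ω/γ` much more tightly than either parameter alone.
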