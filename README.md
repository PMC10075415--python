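# beeloop

Central-place foraging as a persistent turning walker: simulation,
calibration and flower-discovery experiments for bumblebee exploration
flights.

## The problem

Bumblebees leave their nest, explore in smooth meandering loops, and come
back — over and over. How far such a forager effectively searches, and
which flowers it will ever find, depends on the interplay between the
smoothness of its flight and its urge to return home. `beeloop`
implements a minimal stochastic model of this behaviour for anyone
studying pollinator movement, plant–pollinator encounter rates, or
central-place foragers generally.

## The model

The bee flies at constant speed `v` in 2-D. Its signed angular speed
ω(t) follows an Ornstein–Uhlenbeck process relaxing towards a target ω*:

    dω = −γ [ω − ω*(t)] dt + σ dW(t)
    ω*(t) = η(t) φ(t),   η(t) = 0 if t < τ, η* if t ≥ τ

where φ is the signed angle between the velocity and the homing vector
(nest − position) and τ ~ Exp(α) is the moment the bee decides to head
home. The discrete-time update uses the exact OU transition over
Δt = 0.01 s. Loops end on re-entering a 13 m disc around the nest.
Calibrated defaults: γ = 1.0 s⁻¹, σ = 0.37 rad/s^½ (Ω = σ²/2γ ≈ 0.07
rad²/s²), α = 30 s, η* = 0.2 s⁻¹.

On top of the walker, the package provides:

- **observables** — loop segmentation of timestamped tracks and the four
  per-loop summaries (length, extension, self-intersections/100 m,
  re-departures/100 m) at harmonic-radar cadence;
- **calibration** — exhaustive grid search over (γ, Ω, α, η*) matching
  full observable distributions via CDF-area and PMF-L1 distances with
  per-observable quantile normalization;
- **discovery** — flower fields with 3°-threshold visual perception, and
  the masking / multi-discovery / depletion trip policies, discovery
  probability profiles, discovery radii, colony-level distinct-flower
  counts and MSD sensitivity sweeps.

## A worked example

```python
from numpy.random import default_rng
from beeloop import (DiscoveryPolicy, ModelParams,
                     discovery_probability_profile, discovery_radius)

params = ModelParams()                     # calibrated defaults
masking = discovery_probability_profile(
    params, density=1.3e-4, diameter=0.70, policy=DiscoveryPolicy("masking"),
    n_trips=200, n_environments=20, rng=default_rng(11))
print(f"radius: {discovery_radius(masking):.0f} m")
```

prints

```
radius: 190 m
```

the radius of the area around the nest inside which a 70 cm flower keeps
a ≥ 1 % chance of being found per 900 s trip when the bee returns home
after its first find. Dropping the density to 1e-5 widens the radius to
310 m (trips are rarely intercepted); raising it to 1e-3 shrinks it to
50 m — the perceptual masking effect. The `examples/` directory has one
narrative script per capability (loop simulation, observables,
calibration, masking, the colony-level density optimum, MSD sweeps):

```
python examples/04_masking_effect.py
```

A thin CLI covers the same ground from the shell:

```
beeloop simulate --n-loops 100 --radar-format --seed 1 --out runs/
beeloop fit --reference runs/ --grid grid.json --n-loops 200 --out fit.csv
beeloop discover --density 1.3e-4 --policy masking --seed 1
beeloop msd --alphas 10,20,30,40,50
```

Each command writes a JSON manifest (parameters, seed, version,
wall-clock) alongside its outputs.

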