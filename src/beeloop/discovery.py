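"""Flower-discovery experiments: masking, multi-discovery, depletion.

A flower counts as discovered the moment the walker comes within its
perception distance.  Three trip policies:

* ``none`` (no masking): every flower whose zone is entered is recorded;
  the trip always runs its full duration.
* ``masking``: the trip ends at the F-th discovery (F = 1 reproduces the
  basic "return home after the first find" behaviour that produces the
  perceptual masking effect — near-nest flowers intercept trips that would
  otherwise have reached distant ones).
* ``depletion``: flowers found on earlier trips are depleted; a fresh
  discovery ends the trip, while depleted encounters end it only after
  F_depleted of them (unbounded budget: only fresh finds end trips).

Also provides the per-distance discovery-probability profile, the derived
discovery radius, colony-level distinct-flower counts, and the
mean-squared-displacement estimator used for parameter-sensitivity sweeps.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.random import Generator, default_rng

from . import _kernels
from .environment import FlowerField, generate_field, perception_distance
from .motion import Track, _kernel_seed
from .params import ModelParams

__all__ = [
    "DiscoveryPolicy",
    "TripOutcome",
    "DiscoveryProfile",
    "run_trip_with_discovery",
    "discovery_probability_profile",
    "discovery_radius",
    "colony_distinct_flowers",
    "estimate_msd",
]

_MODE_CODE = {"no_masking": 0, "none": 0, "masking": 1, "depletion": 2}


@dataclass(frozen=True)
class DiscoveryPolicy:
    """What ends a trip: nothing, the F-th discovery, or depletion limits."""

    mode: str = "masking"             # no_masking | masking | depletion
    F: int = 1                        # discoveries before returning (masking)
    F_depleted: Optional[int] = None  # depleted-visit budget; None = unbounded

    def __post_init__(self) -> None:
        if self.mode not in _MODE_CODE:
            raise ValueError(f"unknown policy mode {self.mode!r}")
        if self.F < 1:
            raise ValueError("F must be >= 1")
        if self.F_depleted is not None and self.F_depleted < 1:
            raise ValueError("F_depleted must be >= 1 or None")

    @property
    def _code(self) -> int:
        return _MODE_CODE[self.mode]

    @property
    def _budget(self) -> int:
        if self.mode == "depletion":
            return -1 if self.F_depleted is None else self.F_depleted
        return self.F


@dataclass
class TripOutcome:
    """Result of one trip: flower ids in encounter order, truncation time."""

    discovered: np.ndarray     # flower indices, in order of first encounter
    end_time: float            # s; < duration when the policy truncated
    track: Optional[Track] = None


@dataclass
class DiscoveryProfile:
    """Per-trip discovery probability binned by flower-nest distance."""

    bin_edges: np.ndarray      # m, length n_bins + 1
    probability: np.ndarray    # per-trip per-flower probability; NaN if no flowers
    n_flowers: np.ndarray      # flowers observed per bin (all environments)
    n_trips: int
    n_environments: int


def _cell_list(field: FlowerField):
    """Uniform-grid cell list (CSR layout) over the flower positions."""
    fx = np.ascontiguousarray(field.positions[:, 0])
    fy = np.ascontiguousarray(field.positions[:, 1])
    cell = max(25.0, field.perception_distance)
    if fx.size == 0:
        return (fx, fy, cell, 0.0, 0.0, 1, 1,
                np.zeros(2, np.int64), np.zeros(0, np.int64))
    ox = fx.min() - cell
    oy = fy.min() - cell
    ncx = int((fx.max() - ox) // cell) + 2
    ncy = int((fy.max() - oy) // cell) + 2
    cx = ((fx - ox) // cell).astype(np.int64)
    cy = ((fy - oy) // cell).astype(np.int64)
    flat = cx * ncy + cy
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=ncx * ncy)
    cell_start = np.zeros(ncx * ncy + 1, np.int64)
    np.cumsum(counts, out=cell_start[1:])
    return fx, fy, cell, ox, oy, ncx, ncy, cell_start, order.astype(np.int64)


def _run_kernel(seed: int, params: ModelParams, field: FlowerField,
                policy: DiscoveryPolicy, duration: float,
                depleted: np.ndarray, seen: np.ndarray, grid):
    fx, fy, cell, ox, oy, ncx, ncy, cell_start, cell_items = grid
    disc, end_step = _kernels.discovery_kernel(
        seed, params.gamma, params.sigma, params.eta_star, params.p_return,
        params.speed, params.dt, params.nest_radius, duration,
        fx, fy, field.perception_distance ** 2, cell, ox, oy, ncx, ncy,
        cell_start, cell_items,
        policy._code, policy._budget, depleted, seen,
    )
    return disc, end_step * params.dt


def run_trip_with_discovery(params: ModelParams, field: FlowerField,
                            policy: DiscoveryPolicy, duration: float = 900.0,
                            depleted_set=None, rng: Generator | None = None,
                            record_track: bool = False) -> TripOutcome:
    """One foraging trip through a flower field under a discovery policy.

    ``depleted_set`` (depletion mode) is a boolean mask or an iterable of
    flower indices depleted by earlier trips.  With ``record_track`` the
    full trajectory up to truncation is attached (replayed from the same
    seed, so it is exactly the path the walker flew).
    """
    rng = default_rng() if rng is None else rng
    nf = field.n_flowers
    depleted = np.zeros(nf, dtype=np.bool_)
    if depleted_set is not None:
        depleted_set = np.asarray(depleted_set)
        if depleted_set.dtype == np.bool_:
            depleted[:] = depleted_set
        elif depleted_set.size:
            depleted[depleted_set.astype(int)] = True
    seen = np.zeros(max(nf, 1), dtype=np.bool_)
    grid = _cell_list(field)
    seed = _kernel_seed(rng)
    disc, end_time = _run_kernel(seed, params, field, policy, duration,
                                 depleted, seen, grid)
    track = None
    if record_track:
        xs, ys, _ = _kernels.trip_kernel(
            seed, params.gamma, params.sigma, params.eta_star, params.p_return,
            params.speed, params.dt, params.nest_radius, duration,
        )
        k = int(round(end_time / params.dt))
        track = Track(np.arange(k + 1) * params.dt,
                      np.column_stack([xs[:k + 1], ys[:k + 1]]),
                      params.dt)
    return TripOutcome(discovered=disc, end_time=end_time, track=track)


def discovery_probability_profile(params: ModelParams, density: float,
                                  diameter: float, policy: DiscoveryPolicy,
                                  n_trips: int = 200,
                                  n_environments: int = 20,
                                  bins=None, duration: float = 900.0,
                                  extent: float = 1000.0,
                                  rng: Generator | None = None
                                  ) -> DiscoveryProfile:
    """Per-trip flower discovery probability as a function of nest distance.

    For each environment a fresh uniform field is drawn and ``n_trips``
    independent trips are run; a flower's probability is the fraction of
    trips that discovered it.  Probabilities are averaged over flowers
    within each distance bin, then over environments that contributed
    flowers to the bin (bins never populated are NaN).
    """
    rng = default_rng() if rng is None else rng
    if bins is None:
        bins = np.arange(0.0, 510.0, 10.0)
    bins = np.asarray(bins, dtype=float)
    n_bins = len(bins) - 1
    prob_sum = np.zeros(n_bins)
    env_count = np.zeros(n_bins, dtype=int)
    flower_count = np.zeros(n_bins, dtype=int)
    for _ in range(n_environments):
        fld = generate_field(density, diameter, extent, rng)
        nf = fld.n_flowers
        if nf == 0:
            continue
        grid = _cell_list(fld)
        seen = np.zeros(nf, dtype=np.bool_)
        depleted = np.zeros(nf, dtype=np.bool_)
        hits = np.zeros(nf)
        for _ in range(n_trips):
            disc, _ = _run_kernel(_kernel_seed(rng), params, fld, policy,
                                  duration, depleted, seen, grid)
            hits[disc] += 1
        p_flower = hits / n_trips
        dist = np.hypot(fld.positions[:, 0], fld.positions[:, 1])
        which = np.digitize(dist, bins) - 1
        for b in range(n_bins):
            mask = which == b
            if mask.any():
                prob_sum[b] += p_flower[mask].mean()
                env_count[b] += 1
                flower_count[b] += int(mask.sum())
    probability = np.where(env_count > 0, prob_sum / np.maximum(env_count, 1),
                           np.nan)
    return DiscoveryProfile(bin_edges=bins, probability=probability,
                            n_flowers=flower_count, n_trips=n_trips,
                            n_environments=n_environments)


def discovery_radius(profile: DiscoveryProfile, threshold: float = 1e-2) -> float:
    """Radius within which discovery probability *remains* above threshold.

    Scans bins outward from the nest and returns the outer edge of the
    last bin in the initial contiguous run with probability >= threshold
    (0 if the first populated bin already falls below it).  Bins that never
    contained a flower (NaN) carry no evidence and are skipped.
    """
    if len(profile.probability) == 0:
        raise ValueError("empty profile")
    radius = 0.0
    for b, p in enumerate(profile.probability):
        if np.isnan(p):
            continue
        if p < threshold:
            break
        radius = profile.bin_edges[b + 1]
    return radius


def colony_distinct_flowers(params: ModelParams, density: float,
                            diameter: float, policy: DiscoveryPolicy,
                            n_trips: int = 100, n_replicates: int = 80,
                            duration: float = 900.0, extent: float = 1000.0,
                            rng: Generator | None = None,
                            return_replicates: bool = False):
    """Mean number of distinct flowers a colony discovers.

    Each replicate fixes one field and runs ``n_trips`` sequential trips;
    in depletion mode the depleted set threads across trips (a flower is
    depleted after its first discovery in any earlier trip).  Returns the
    mean distinct-flower count over replicates (optionally the full
    per-replicate array).
    """
    rng = default_rng() if rng is None else rng
    counts = np.empty(n_replicates)
    for r in range(n_replicates):
        fld = generate_field(density, diameter, extent, rng)
        nf = fld.n_flowers
        if nf == 0:
            counts[r] = 0.0
            continue
        grid = _cell_list(fld)
        seen = np.zeros(nf, dtype=np.bool_)
        depleted = np.zeros(nf, dtype=np.bool_)
        ever = np.zeros(nf, dtype=np.bool_)
        for _ in range(n_trips):
            disc, _ = _run_kernel(_kernel_seed(rng), params, fld, policy,
                                  duration, depleted, seen, grid)
            ever[disc] = True
            if policy.mode == "depletion":
                depleted[disc] = True
        counts[r] = float(ever.sum())
    mean = float(counts.mean())
    if return_replicates:
        return mean, counts
    return mean


def estimate_msd(params: ModelParams, n_loops: int = 10000,
                 rng: Generator | None = None,
                 sample_stride: int = 10) -> float:
    """Mean squared distance to the nest of the loop-chained process, m^2.

    Estimated by pooling squared distances sampled every
    ``sample_stride`` steps over ``n_loops`` consecutive loops; this is the
    variance scale of the stationary spatial distribution around the nest
    (censored-loop samples are included up to the one-hour cap, which only
    matters in the weak-homing diffusive regime).
    """
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    rng = default_rng() if rng is None else rng
    msd, _ = _kernels.msd_kernel(
        _kernel_seed(rng), params.gamma, params.sigma, params.eta_star,
        params.p_return, params.speed, params.dt, params.nest_radius,
        params.max_loop_duration, n_loops, sample_stride,
    )
    return float(msd)
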