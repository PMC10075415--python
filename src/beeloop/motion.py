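"""Stochastic dynamics of the central-place persistent turning walker.

The walker moves at constant speed ``v`` in 2-D.  Its signed angular speed
``omega`` follows an exact discrete-time Ornstein-Uhlenbeck transition
towards a target ``omega* = eta(t) * phi(t)``, where ``phi`` is the signed
angle from the current velocity to the homing vector (nest minus position).
During the exploration phase ``eta = 0`` (aimless, smoothly turning
search); at an exponentially distributed switch time ``tau`` the walker
enters the return phase with ``eta = eta*`` and steers home until it
re-enters the nest disc.

Update order within one step of length ``dt``:

1. position advances with the current velocity,
2. heading advances with the current angular speed (wrapped to (-pi, pi]),
3. velocity is recomputed from the new heading at constant speed,
4. the angular speed is updated with the exact OU transition
   ``omega <- omega e^(-gamma dt) + omega* (1 - e^(-gamma dt)) + s xi``
   with ``s^2 = sigma^2 (1 - e^(-2 gamma dt)) / (2 gamma)``.

The scalar functions here are the reference semantics; bulk simulation is
delegated to the compiled kernels in :mod:`beeloop._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.signal import lfilter

from . import _kernels
from .params import ModelParams

__all__ = [
    "BeeState",
    "NoiseSpec",
    "Track",
    "Loop",
    "wrap_angle",
    "homing_angle",
    "target_angular_speed",
    "ou_update",
    "advance_state",
    "draw_switch_time",
    "simulate_loop",
    "simulate_trip",
    "simulate_angular_speed",
]

EXPLORATION = "exploration"
RETURN = "return"


def wrap_angle(angle: float) -> float:
    """Wrap an angle (or array of angles) to (-pi, pi]."""
    return np.pi - (np.pi - np.asarray(angle)) % (2.0 * np.pi)


@dataclass
class Track:
    """A timestamped 2-D polyline (seconds, metres)."""

    times: np.ndarray
    positions: np.ndarray  # shape (n, 2)
    sampling_interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Loop:
    """A nest-to-nest fragment of a track.

    ``censored`` marks loops truncated by the duration cap or by the track
    ending (or starting) away from the nest disc.
    """

    track: Track
    censored: bool = False
    switch_time: Optional[float] = None  # tau, known for simulated loops

    def __len__(self) -> int:
        return len(self.track)


@dataclass
class BeeState:
    """Instantaneous kinematic and phase state of one walker."""

    position: np.ndarray
    heading: float
    angular_speed: float
    phase: str = EXPLORATION
    switch_time: float = math.inf  # tau, s, drawn at loop start
    clock: float = 0.0             # elapsed time within the current loop, s

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = float(wrap_angle(self.heading))
        if self.phase not in (EXPLORATION, RETURN):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Reproducible randomness: one root seed, independent child streams.

    Identical ``rng_seed`` + parameters give bitwise-identical
    trajectories.
    """

    rng_seed: int

    def generator(self) -> Generator:
        return default_rng(self.rng_seed)

    def child_seed(self, index: int) -> int:
        """A 31-bit seed for stream ``index``, independent across indices."""
        return int(SeedSequence([self.rng_seed, index]).generate_state(1)[0] >> 1)


def _kernel_seed(rng: Generator) -> int:
    return int(rng.integers(0, 2**31))


# ---------------------------------------------------------------------------
# Elementary operations (reference semantics)
# ---------------------------------------------------------------------------

def homing_angle(position: Sequence[float], heading: float,
                 nest: Sequence[float]) -> float:
    """Signed angle phi in (-pi, pi] from the velocity direction to the
    homing vector H = nest - position.

    Positive phi means the nest lies counterclockwise of the current
    heading, so a positive target angular speed ``eta * phi`` steers toward
    it under ``theta <- theta + omega dt``.
    """
    position = np.asarray(position, dtype=float)
    nest = np.asarray(nest, dtype=float)
    h = nest - position
    if h[0] == 0.0 and h[1] == 0.0:
        raise ValueError("homing direction undefined: position coincides with nest")
    return float(wrap_angle(math.atan2(h[1], h[0]) - heading))


def target_angular_speed(state: BeeState, params: ModelParams,
                         nest: Sequence[float]) -> float:
    """omega* = eta(t) * phi(t): zero while exploring, eta* phi homeward."""
    if state.phase == EXPLORATION:
        return 0.0
    return params.eta_star * homing_angle(state.position, state.heading, nest)


def ou_update(omega: float, omega_target: float, params: ModelParams,
              noise: float) -> float:
    """Exact OU transition of the angular speed over one step.

    ``noise`` is a standard-normal draw; the transition noise standard
    deviation is ``s = sigma sqrt((1 - e^(-2 gamma dt)) / (2 gamma))``,
    which vanishes as dt -> 0 and tends to sqrt(Omega) as dt -> inf.
    """
    a = math.exp(-params.gamma * params.dt)
    s = params.sigma * math.sqrt(
        (1.0 - math.exp(-2.0 * params.gamma * params.dt)) / (2.0 * params.gamma)
    )
    return omega * a + omega_target * (1.0 - a) + s * noise


def advance_state(state: BeeState, params: ModelParams,
                  nest: Sequence[float], noise: float) -> BeeState:
    """One full step: kinematics, phase bookkeeping, OU update.

    Returns a new :class:`BeeState`; the input is not modified.  The phase
    flips (one-way) to return when the post-step clock reaches the switch
    time; ``phi`` is recomputed at the new position and heading.
    """
    v = params.speed
    dt = params.dt
    new_pos = state.position + v * dt * np.array(
        [math.cos(state.heading), math.sin(state.heading)]
    )
    new_heading = float(wrap_angle(state.heading + state.angular_speed * dt))
    new_clock = state.clock + dt
    phase = RETURN if (state.phase == RETURN or new_clock >= state.switch_time) \
        else EXPLORATION
    interim = BeeState(
        position=new_pos,
        heading=new_heading,
        angular_speed=state.angular_speed,
        phase=phase,
        switch_time=state.switch_time,
        clock=new_clock,
    )
    omega_t = target_angular_speed(interim, params, nest)
    interim.angular_speed = ou_update(state.angular_speed, omega_t, params, noise)
    return interim


def draw_switch_time(params: ModelParams, rng: Generator, size=None):
    """Exponential switch time(s) tau with mean alpha = 1/p_return, s."""
    return rng.exponential(1.0 / params.p_return, size=size)


# ---------------------------------------------------------------------------
# Whole-loop / whole-trip simulation (compiled kernels)
# ---------------------------------------------------------------------------

def simulate_loop(params: ModelParams, nest: Sequence[float],
                  rng: Generator) -> Loop:
    """Simulate one nest-to-nest loop.

    The walker starts at the nest with a uniform random heading and zero
    angular speed, explores until its exponential switch time, then steers
    home; the loop ends on the first sample inside ``nest_radius`` during
    the return phase, or is censored at ``max_loop_duration``.
    """
    nest = np.asarray(nest, dtype=float)
    seed = _kernel_seed(rng)
    xs, ys, tau, censored = _kernels.loop_kernel(
        seed, params.gamma, params.sigma, params.eta_star, params.p_return,
        params.speed, params.dt, params.nest_radius, params.max_loop_duration,
    )
    n = len(xs)
    positions = np.column_stack([xs, ys]) + nest
    track = Track(times=np.arange(n) * params.dt, positions=positions,
                  sampling_interval=params.dt)
    return Loop(track=track, censored=bool(censored), switch_time=float(tau))


def simulate_trip(params: ModelParams, nest: Sequence[float], duration: float,
                  rng: Generator,
                  stop_hook: Optional[Callable[[BeeState], bool]] = None):
    """Simulate a foraging trip of fixed ``duration`` seconds, chaining loops.

    Whenever the walker re-enters the nest disc in return phase, a fresh
    loop starts from the current position: uniform random heading, zero
    angular speed, fresh switch time.  Returns ``(track, return_times)``
    where ``return_times`` are the nest re-entry times in seconds.

    ``stop_hook``, if given, is called after every step with the current
    :class:`BeeState` and may return True to end the trip early (this path
    runs the pure-Python stepper and is intended for small, bespoke
    experiments; the flower-discovery policies use their own compiled
    kernel).
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    nest = np.asarray(nest, dtype=float)
    if stop_hook is None:
        seed = _kernel_seed(rng)
        xs, ys, returns = _kernels.trip_kernel(
            seed, params.gamma, params.sigma, params.eta_star, params.p_return,
            params.speed, params.dt, params.nest_radius, duration,
        )
        positions = np.column_stack([xs, ys]) + nest
        track = Track(times=np.arange(len(xs)) * params.dt,
                      positions=positions, sampling_interval=params.dt)
        return track, returns * params.dt
    return _simulate_trip_python(params, nest, duration, rng, stop_hook)


def _simulate_trip_python(params, nest, duration, rng, stop_hook):
    n = int(round(duration / params.dt))
    state = BeeState(position=nest.copy(),
                     heading=rng.uniform(-math.pi, math.pi),
                     angular_speed=0.0,
                     switch_time=float(draw_switch_time(params, rng)))
    positions = [nest.copy()]
    return_times = []
    r2 = params.nest_radius**2
    for i in range(1, n + 1):
        noise = rng.standard_normal()
        state = advance_state(state, params, nest, noise)
        positions.append(state.position.copy())
        if state.phase == RETURN and \
                np.sum((state.position - nest) ** 2) <= r2:
            return_times.append(i * params.dt)
            state = BeeState(position=state.position,
                             heading=rng.uniform(-math.pi, math.pi),
                             angular_speed=0.0,
                             switch_time=float(draw_switch_time(params, rng)))
        if stop_hook is not None and stop_hook(state):
            break
    track = Track(times=np.arange(len(positions)) * params.dt,
                  positions=np.array(positions),
                  sampling_interval=params.dt)
    return track, np.array(return_times)


def simulate_angular_speed(params: ModelParams, n_steps: int, rng: Generator,
                           burn_in: int = 0) -> np.ndarray:
    """The angular-speed process alone (omega* = 0), as an exact AR(1).

    Simulates ``burn_in + n_steps`` steps of
    ``omega_{k+1} = a omega_k + s xi_k`` starting from omega = 0 and
    returns the last ``n_steps`` values.  Used for stationary-variance
    diagnostics; the stationary variance is sigma^2/(2 gamma).
    """
    a = math.exp(-params.gamma * params.dt)
    s = params.sigma * math.sqrt(
        (1.0 - math.exp(-2.0 * params.gamma * params.dt)) / (2.0 * params.gamma)
    )
    noise = s * rng.standard_normal(burn_in + n_steps)
    omega = lfilter([1.0], [1.0, -a], noise)
    return omega[burn_in:]


def distances_at_horizons(params: ModelParams, horizons: Sequence[float],
                          n_trips: int, rng: Generator,
                          nest: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
    """Distance to the nest at the given time horizons, across trips.

    Runs ``n_trips`` independent trips of length ``max(horizons)`` and
    returns an array of shape (n_trips, len(horizons)).  This is the
    stationarity-vs-diffusion diagnostic: with homing the columns share one
    stationary distribution; without (eta* = 0) they widen with time.
    """
    horizons = np.asarray(horizons, dtype=float)
    duration = float(horizons.max())
    idx = np.round(horizons / params.dt).astype(int)
    nest = np.asarray(nest, dtype=float)
    out = np.empty((n_trips, len(horizons)))
    for k in range(n_trips):
        seed = _kernel_seed(rng)
        xs, ys, _ = _kernels.trip_kernel(
            seed, params.gamma, params.sigma, params.eta_star, params.p_return,
            params.speed, params.dt, params.nest_radius, duration,
        )
        out[k] = np.hypot(xs[idx], ys[idx])
    return out
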