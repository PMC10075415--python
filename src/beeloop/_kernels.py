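"""Numba step kernels for the persistent turning walker.

These compiled loops are the throughput-critical core: exact discrete-time
OU update of the angular speed, constant-speed kinematics, the
exploration->return phase switch, loop chaining, and flower-zone detection
on a uniform spatial grid.  The pure-Python operations in
:mod:`beeloop.motion` define the reference semantics; the kernels must agree
with them (checked in the noise-free limit by the test suite).

RNG contract: every kernel seeds numba's own ``np.random`` state from an
explicit integer, so identical seed + parameters give bitwise-identical
trajectories.  All kernels consume randomness in the same order (initial
heading uniform, switch time exponential, then one normal per step; a fresh
uniform + exponential at each within-trip loop reset), which lets a
truncated discovery trip be replayed exactly by the plain trip kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _wrap(a):
    """Wrap an angle to (-pi, pi]."""
    return np.pi - (np.pi - a) % (2.0 * np.pi)


@njit(cache=False)
def loop_kernel(seed, gamma, sigma, eta_star, p_return, v, dt,
                nest_radius, max_dur):
    """One nest-to-nest loop from the nest at the origin.

    Returns (xs, ys, tau, censored).  Positions are recorded every dt,
    starting at the nest.  The loop ends at the first step with the walker
    inside ``nest_radius`` while in the return phase, or is censored at
    ``max_dur``.
    """
    np.random.seed(seed)
    theta = np.random.uniform(-np.pi, np.pi)
    tau = np.random.exponential(1.0 / p_return)
    a = np.exp(-gamma * dt)
    s = sigma * np.sqrt((1.0 - np.exp(-2.0 * gamma * dt)) / (2.0 * gamma))
    r2 = nest_radius * nest_radius
    n_max = int(np.ceil(max_dur / dt))
    cap = 16384  # grown on demand; typical loops are ~1e4 steps
    if cap > n_max + 1:
        cap = n_max + 1
    xs = np.empty(cap)
    ys = np.empty(cap)
    xs[0] = 0.0
    ys[0] = 0.0
    x = 0.0
    y = 0.0
    omega = 0.0
    censored = True
    i = 0
    while i < n_max:
        # M1: position with current velocity; M2: heading with current omega
        x += v * np.cos(theta) * dt
        y += v * np.sin(theta) * dt
        theta = _wrap(theta + omega * dt)
        i += 1
        if i >= cap:
            new_cap = cap * 2
            if new_cap > n_max + 1:
                new_cap = n_max + 1
            nxs = np.empty(new_cap)
            nys = np.empty(new_cap)
            nxs[:cap] = xs
            nys[:cap] = ys
            xs = nxs
            ys = nys
            cap = new_cap
        xs[i] = x
        ys[i] = y
        if i * dt >= tau:  # return phase
            if x * x + y * y <= r2:
                censored = False
                break
            phi = _wrap(np.arctan2(-y, -x) - theta)
            omega_t = eta_star * phi
        else:
            omega_t = 0.0
        # M4: exact OU transition over dt
        omega = omega * a + omega_t * (1.0 - a) + s * np.random.normal()
    return xs[: i + 1], ys[: i + 1], tau, censored


@njit(cache=False)
def trip_kernel(seed, gamma, sigma, eta_star, p_return, v, dt,
                nest_radius, duration):
    """A foraging trip of fixed duration, chaining loops.

    On each return-phase nest re-entry the walker resets: fresh uniform
    heading, zero angular speed, fresh exponential switch time.  Returns
    (xs, ys, return_steps) where ``return_steps`` are the step indices of
    nest re-entries.
    """
    np.random.seed(seed)
    n = int(round(duration / dt))
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    returns = np.empty(n, np.int64)
    n_ret = 0
    theta = np.random.uniform(-np.pi, np.pi)
    tau = np.random.exponential(1.0 / p_return)
    a = np.exp(-gamma * dt)
    s = sigma * np.sqrt((1.0 - np.exp(-2.0 * gamma * dt)) / (2.0 * gamma))
    r2 = nest_radius * nest_radius
    xs[0] = 0.0
    ys[0] = 0.0
    x = 0.0
    y = 0.0
    omega = 0.0
    clock = 0.0
    for i in range(1, n + 1):
        x += v * np.cos(theta) * dt
        y += v * np.sin(theta) * dt
        theta = _wrap(theta + omega * dt)
        clock += dt
        xs[i] = x
        ys[i] = y
        if clock >= tau:
            if x * x + y * y <= r2:
                returns[n_ret] = i
                n_ret += 1
                theta = np.random.uniform(-np.pi, np.pi)
                tau = np.random.exponential(1.0 / p_return)
                omega = 0.0
                clock = 0.0
                continue
            phi = _wrap(np.arctan2(-y, -x) - theta)
            omega_t = eta_star * phi
        else:
            omega_t = 0.0
        omega = omega * a + omega_t * (1.0 - a) + s * np.random.normal()
    return xs, ys, returns[:n_ret]


@njit(cache=False)
def msd_kernel(seed, gamma, sigma, eta_star, p_return, v, dt,
               nest_radius, max_dur, n_loops, stride):
    """Mean squared distance to the nest over ``n_loops`` chained loops.

    Squared distances are sampled every ``stride`` steps; censored-loop
    samples (loops hitting ``max_dur``) are included up to the cap, which
    matters only in the weak-homing diffusive regime.  Returns
    (msd, n_censored).
    """
    np.random.seed(seed)
    a = np.exp(-gamma * dt)
    s = sigma * np.sqrt((1.0 - np.exp(-2.0 * gamma * dt)) / (2.0 * gamma))
    r2 = nest_radius * nest_radius
    n_max = int(np.ceil(max_dur / dt))
    total = 0.0
    count = 0
    n_cens = 0
    for k in range(n_loops):
        theta = np.random.uniform(-np.pi, np.pi)
        tau = np.random.exponential(1.0 / p_return)
        x = 0.0
        y = 0.0
        omega = 0.0
        censored = True
        for i in range(1, n_max + 1):
            x += v * np.cos(theta) * dt
            y += v * np.sin(theta) * dt
            theta = _wrap(theta + omega * dt)
            d2 = x * x + y * y
            if i % stride == 0:
                total += d2
                count += 1
            if i * dt >= tau:
                if d2 <= r2:
                    censored = False
                    break
                phi = _wrap(np.arctan2(-y, -x) - theta)
                omega_t = eta_star * phi
            else:
                omega_t = 0.0
            omega = omega * a + omega_t * (1.0 - a) + s * np.random.normal()
        if censored:
            n_cens += 1
    return total / count, n_cens


@njit(cache=False)
def discovery_kernel(seed, gamma, sigma, eta_star, p_return, v, dt,
                     nest_radius, duration,
                     fx, fy, perc2, cell, ox, oy, ncx, ncy,
                     cell_start, cell_items,
                     mode, budget, depleted, seen):
    """A foraging trip with flower-zone detection.

    The walker dynamics and RNG consumption mirror :func:`trip_kernel`
    exactly.  At every step, flowers in the 3x3 grid-cell neighbourhood of
    the walker are tested against the squared perception distance
    ``perc2``; each flower is recorded at most once per trip.

    mode 0 (no masking): record every distinct flower, never truncate.
    mode 1 (masking): truncate at the ``budget``-th discovery.
    mode 2 (depletion): a non-depleted discovery truncates; depleted
    encounters truncate after ``budget`` of them (budget <= 0: unbounded).

    ``seen`` is caller-provided per-flower scratch (reset here).
    Returns (discovered ids in order, end step index).
    """
    np.random.seed(seed)
    n = int(round(duration / dt))
    nf = fx.size
    for j in range(nf):
        seen[j] = False
    disc = np.empty(nf, np.int64)
    nd = 0
    depl_hits = 0
    theta = np.random.uniform(-np.pi, np.pi)
    tau = np.random.exponential(1.0 / p_return)
    a = np.exp(-gamma * dt)
    s = sigma * np.sqrt((1.0 - np.exp(-2.0 * gamma * dt)) / (2.0 * gamma))
    r2 = nest_radius * nest_radius
    x = 0.0
    y = 0.0
    omega = 0.0
    clock = 0.0
    for i in range(1, n + 1):
        x += v * np.cos(theta) * dt
        y += v * np.sin(theta) * dt
        theta = _wrap(theta + omega * dt)
        clock += dt
        # flower detection at the new position
        if nf > 0:
            cx = int(np.floor((x - ox) / cell))
            cy = int(np.floor((y - oy) / cell))
            gx0 = max(cx - 1, 0)
            gx1 = min(cx + 2, ncx)
            gy0 = max(cy - 1, 0)
            gy1 = min(cy + 2, ncy)
            for gx in range(gx0, gx1):
                for gy in range(gy0, gy1):
                    c = gx * ncy + gy
                    for p in range(cell_start[c], cell_start[c + 1]):
                        f = cell_items[p]
                        if seen[f]:
                            continue
                        dxf = fx[f] - x
                        dyf = fy[f] - y
                        if dxf * dxf + dyf * dyf <= perc2:
                            seen[f] = True
                            disc[nd] = f
                            nd += 1
                            if mode == 1 and nd >= budget:
                                return disc[:nd], i
                            if mode == 2:
                                if depleted[f]:
                                    depl_hits += 1
                                    if budget > 0 and depl_hits >= budget:
                                        return disc[:nd], i
                                else:
                                    return disc[:nd], i
        if clock >= tau:
            if x * x + y * y <= r2:
                theta = np.random.uniform(-np.pi, np.pi)
                tau = np.random.exponential(1.0 / p_return)
                omega = 0.0
                clock = 0.0
                continue
            phi = _wrap(np.arctan2(-y, -x) - theta)
            omega_t = eta_star * phi
        else:
            omega_t = 0.0
        omega = omega * a + omega_t * (1.0 - a) + s * np.random.normal()
    return disc[:nd], n
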