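"""Exact stochastic simulation (Gillespie direct method) of the burst model.

Two entry points:

* :func:`simulate` records the full event sequence as a :class:`Trajectory`
  (every reaction time and the state after it), suitable for plots and for
  event-level statistics (jump-size law, holding times).
* :func:`stationary_histogram` streams a long run directly into a
  time-weighted occupancy histogram without materializing the trajectory,
  which is what the convergence checks against the CME use.

Both are the exact direct method — waiting times drawn exponentially from
the total propensity ``a0(x) = k1 + k2 x + k3 x²/r + k4 x³``, the channel
chosen proportionally to its propensity — with the inner loop JIT-compiled.
A run is reproduced bit-exactly by (params, x0, seed).  Time units are
arbitrary (inverse rate units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import SchloglParams, fixed_points

__all__ = [
    "Trajectory",
    "OccupancyHistogram",
    "simulate",
    "occupancy_histogram",
    "stationary_histogram",
    "default_initial_state",
]


@njit(cache=False)
def _ssa_kernel(k1, k2, k3, k4, r, x0, t_max, seed, max_events, times, states):
    """Direct-method SSA recording every event; returns (n_events, t_final).

    `times`/`states` are preallocated with length max_events.
    """
    np.random.seed(seed)
    t = 0.0
    x = x0
    n = 0
    while t < t_max and n < max_events:
        xf = float(x)
        a1 = k1
        a2 = k2 * xf
        a3 = k3 * xf * xf / r
        a4 = k4 * xf * xf * xf
        a0 = a1 + a2 + a3 + a4
        dt = np.random.exponential(1.0 / a0)
        t += dt
        if t >= t_max:
            break
        u = np.random.random() * a0
        if u < a1:
            x += 1
        elif u < a1 + a2:
            x -= 1
        elif u < a1 + a2 + a3:
            x += r
        else:
            x -= 1
        if x < 0:
            # unreachable: the -1 channels have zero propensity at x = 0
            return -1, t
        times[n] = t
        states[n] = x
        n += 1
    return n, t


@njit(cache=False)
def _ssa_occupancy_kernel(k1, k2, k3, k4, r, x0, t_max, seed, t_burn, weights):
    """Streaming occupancy accumulation; returns (post-burn-in time, max state).

    `weights` is a preallocated array indexed by state; holding time of each
    state after t_burn is accumulated in place.  Returns (-1.0, x) if the
    state exceeds the array, signalling the caller to enlarge it.
    """
    np.random.seed(seed)
    cap = weights.shape[0] - 1
    t = 0.0
    x = x0
    x_seen = x0
    while t < t_max:
        if x > cap:
            return -1.0, x_seen
        xf = float(x)
        a1 = k1
        a2 = k2 * xf
        a3 = k3 * xf * xf / r
        a4 = k4 * xf * xf * xf
        a0 = a1 + a2 + a3 + a4
        dt = np.random.exponential(1.0 / a0)
        t_next = t + dt
        if t_next > t_max:
            t_next = t_max
        lo = t if t > t_burn else t_burn
        if t_next > lo:
            weights[x] += t_next - lo
        t = t + dt
        if t >= t_max:
            break
        u = np.random.random() * a0
        if u < a1:
            x += 1
        elif u < a1 + a2:
            x -= 1
        elif u < a1 + a2 + a3:
            x += r
        else:
            x -= 1
        if x > x_seen:
            x_seen = x
    return t_max - t_burn, x_seen


@dataclass(frozen=True)
class Trajectory:
    """One SSA sample path: event times and the state after each event.

    The path is piecewise constant and right-continuous; ``states[i]`` holds
    on ``[times[i], times[i+1])``.  ``x0`` holds on ``[0, times[0])``.
    """

    params: SchloglParams
    x0: int
    seed: int
    t_max: float
    times: np.ndarray
    states: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def default_initial_state(params: SchloglParams) -> int:
    """Nearest integer to the largest non-repelling deterministic root."""
    return int(round(fixed_points(params).largest_stable))


def simulate(
    params: SchloglParams,
    x0: int | None = None,
    t_max: float = 1.0,
    seed: int = 0,
    max_events: int = 20_000_000,
) -> Trajectory:
    """Exact SSA sample path of length ``t_max``.

    Raises ``RuntimeError`` if the event budget ``max_events`` is exhausted
    before ``t_max`` (the event rate of this model is of order
    ``k1 + k4 x³`` per time unit, so desk-scale rate sets produce millions
    of events per time unit; use :func:`stationary_histogram` for long
    runs).
    """
    params.require_stochastic()
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if x0 is None:
        x0 = default_initial_state(params)
    if x0 < 0:
        raise ValueError("x0 must be a non-negative integer")

    times = np.empty(max_events, dtype=np.float64)
    states = np.empty(max_events, dtype=np.int64)
    n, t = _ssa_kernel(
        params.k1, params.k2, params.k3, params.k4, params.r,
        int(x0), float(t_max), int(seed), int(max_events), times, states,
    )
    if n < 0:
        raise AssertionError("state went negative; propensity guard violated")
    if t < t_max and n == max_events:
        raise RuntimeError(
            f"max_events={max_events} exhausted at t={t:.4g} < t_max={t_max}; "
            "increase max_events or use stationary_histogram for long runs"
        )
    return Trajectory(params, int(x0), int(seed), float(t_max),
                      times[:n].copy(), states[:n].copy())


@dataclass(frozen=True)
class OccupancyHistogram:
    """Time-weighted state occupancy of a trajectory after burn-in.

    ``weights[x]`` is the total holding time in state x; weights sum to the
    post-burn-in duration, and ``probabilities`` is the normalized view —
    the SSA estimate of the stationary law.
    """

    weights: np.ndarray
    burn_in_fraction: float
    total_time: float

    @property
    def states(self) -> np.ndarray:
        return np.arange(len(self.weights))

    @property
    def probabilities(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def occupancy_histogram(traj: Trajectory, burn_in_fraction: float = 0.1) -> OccupancyHistogram:
    """Histogram of holding times per state, discarding an initial burn-in.

    Each visited state is weighted by the total time the path spends in it
    after ``burn_in_fraction * t_max``; intervals straddling the burn-in
    cut or the final time are clipped accordingly.
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    t_burn = burn_in_fraction * traj.t_max

    starts = np.concatenate([[0.0], traj.times])
    ends = np.concatenate([traj.times, [traj.t_max]])
    occupants = np.concatenate([[traj.x0], traj.states])

    lo = np.maximum(starts, t_burn)
    hi = np.minimum(ends, traj.t_max)
    dur = np.clip(hi - lo, 0.0, None)
    if dur.sum() <= 0:
        raise ValueError("no post-burn-in duration; shorten the burn-in or run longer")

    weights = np.bincount(occupants, weights=dur)
    return OccupancyHistogram(weights, burn_in_fraction, float(traj.t_max - t_burn))


def stationary_histogram(
    params: SchloglParams,
    t_max: float,
    seed: int = 0,
    x0: int | None = None,
    burn_in_fraction: float = 0.1,
    x_cap: int | None = None,
) -> OccupancyHistogram:
    """Long-run occupancy histogram streamed in the JIT kernel.

    Equivalent to ``occupancy_histogram(simulate(...))`` but without storing
    the event sequence, so run lengths are limited by time only.  The state
    array is enlarged and the run repeated (same seed, hence identical
    path) in the rare case the path escapes the initial cap.
    """
    params.require_stochastic()
    if x0 is None:
        x0 = default_initial_state(params)
    if x_cap is None:
        fps = fixed_points(params)
        top = max(max(fps.roots, default=1.0), float(x0), 1.0)
        x_cap = int(4 * top + 50 * params.r)
    t_burn = burn_in_fraction * t_max

    for _ in range(6):
        weights = np.zeros(x_cap + 1, dtype=np.float64)
        span, x_seen = _ssa_occupancy_kernel(
            params.k1, params.k2, params.k3, params.k4, params.r,
            int(x0), float(t_max), int(seed), float(t_burn), weights,
        )
        if span >= 0:
            return OccupancyHistogram(weights, burn_in_fraction, float(span))
        x_cap = max(2 * x_cap, int(x_seen) + 10 * params.r)
    raise RuntimeError("state cap kept being exceeded; check parameters")
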