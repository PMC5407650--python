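"""Exact stationary solution of the chemical master equation (truncated).

The CME for the burst-Schlögl model acts on integer molecule counts with
jump sizes +1 (production), -1 (both degradation channels) and +r (burst
autocatalysis).  The transition rates out of state x are::

    x -> x+1   at  k1
    x -> x-1   at  k2 x + k4 x^3
    x -> x+r   at  k3 x^2 / r

These are the model's polynomial rates taken verbatim, not combinatorial
mass-action factors x(x-1)...: the polynomial forms define this model family
and are what the Fokker-Planck reduction is derived from.

The state space is truncated to 0..x_max with a mass-conserving policy:
burst jumps that would overshoot x_max are redirected to x_max, so the
generator remains a proper rate matrix and the stationary solve is exact on
the truncated chain.  The truncation is validated a posteriori through the
tail-mass criterion.  This module is the brute-force oracle against which
the Fokker-Planck densities and SSA histograms are checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import logsumexp

from .fpe import TruncationError
from .model_core import SchloglParams

__all__ = [
    "TruncatedStateSpace",
    "DiscreteStationaryDistribution",
    "build_generator",
    "stationary_distribution",
    "distribution_mode",
    "detailed_balance_r1",
]

_TAIL_TOL = 1e-9


@dataclass(frozen=True)
class TruncatedStateSpace:
    """Sparse CME generator on states 0..x_max.

    ``generator`` is the rate matrix Q with Q[to, from] holding the
    transition rate, so that dp/dt = Q p and every column sums to zero.
    """

    params: SchloglParams
    x_max: int
    generator: sp.csc_matrix
    truncation: str = "redirect_to_boundary"

    @property
    def n_states(self) -> int:
        return self.x_max + 1


def build_generator(params: SchloglParams, x_max: int) -> TruncatedStateSpace:
    """Assemble the truncated CME generator.

    Requires ``k1 > 0`` (otherwise state 0 is absorbing) and
    ``x_max >= 10 r`` so the redirected burst jumps cannot dominate.
    """
    params.require_stochastic()
    r = params.r
    if x_max < 10 * r:
        raise ValueError(f"x_max must be at least 10*r = {10 * r}, got {x_max}")

    n = x_max + 1
    x = np.arange(n, dtype=float)
    birth = np.full(n, params.k1)
    death = params.k2 * x + params.k4 * x**3
    burst = params.k3 * x**2 / r

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    # +1 jumps (from every state except the boundary, where they are
    # redirected onto the boundary itself, i.e. dropped from the generator
    # but also removed from the outflow: equivalently no-op at x_max)
    i = np.arange(n - 1)
    rows.append(i + 1)
    cols.append(i)
    vals.append(birth[:-1])

    # -1 jumps
    i = np.arange(1, n)
    rows.append(i - 1)
    cols.append(i)
    vals.append(death[1:])

    # +r jumps, redirected to x_max when they would overshoot
    i = np.arange(1, n)  # burst rate vanishes at x = 0
    dest = np.minimum(i + r, x_max)
    keep = dest != i  # a jump that lands on its origin is a no-op
    rows.append(dest[keep])
    cols.append(i[keep])
    vals.append(burst[1:][keep])

    rows_a = np.concatenate(rows)
    cols_a = np.concatenate(cols)
    vals_a = np.concatenate(vals)

    Q = sp.coo_matrix((vals_a, (rows_a, cols_a)), shape=(n, n)).tocsc()
    outflow = np.asarray(Q.sum(axis=0)).ravel()
    Q = Q - sp.diags(outflow)
    return TruncatedStateSpace(params, x_max, Q.tocsc())


@dataclass(frozen=True)
class DiscreteStationaryDistribution:
    """Stationary probability vector of the truncated CME."""

    p: np.ndarray
    modes: tuple[int, ...]
    tail_mass: float
    boundary_mode: bool = False
    tied_modes: tuple[int, ...] = ()

    @property
    def states(self) -> np.ndarray:
        return np.arange(len(self.p))


def _interior_modes(p: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior local maxima; ties broken toward the smaller state."""
    modes: list[int] = []
    tied: list[int] = []
    for i in range(1, len(p) - 1):
        if p[i] > p[i - 1] and p[i] >= p[i + 1]:
            modes.append(i)
            if p[i] == p[i + 1]:
                tied.append(i)
    return modes, tied


def stationary_distribution(space: TruncatedStateSpace) -> DiscreteStationaryDistribution:
    """Unique stationary law p with Q p = 0, sum(p) = 1.

    Solved as a sparse linear system with one equation replaced by the
    normalization constraint (deterministic, no spectral-gap sensitivity).
    Raises :class:`TruncationError` when the top 1% of states carry more
    than 1e-9 of the mass.
    """
    n = space.n_states
    A = space.generator.tolil(copy=True)
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    p = spla.spsolve(A.tocsc(), b)
    p = np.clip(p, 0.0, None)
    p /= p.sum()

    n_tail = max(1, n // 100)
    tail = float(p[-n_tail:].sum())
    if tail > _TAIL_TOL:
        raise TruncationError(
            f"tail mass {tail:.3e} on the top 1% of states exceeds {_TAIL_TOL}; "
            f"rebuild the generator with x_max >= {2 * space.x_max}"
        )

    modes, tied = _interior_modes(p)
    boundary = False
    if not modes:
        # monotone distribution: the mode sits on a boundary state
        modes = [int(np.argmax(p))]
        boundary = True
    return DiscreteStationaryDistribution(
        p, tuple(modes), tail, boundary_mode=boundary, tied_modes=tuple(tied)
    )


def distribution_mode(dist: DiscreteStationaryDistribution) -> list[int]:
    """All interior local maxima of the stationary law (boundary flagged)."""
    return list(dist.modes)


def detailed_balance_r1(params: SchloglParams, x_max: int) -> np.ndarray:
    """Closed-form stationary law of the r = 1 birth-death chain.

    For nearest-neighbour jumps detailed balance holds and

        p(x+1) / p(x) = T(x+1|x) / T(x-1|x+1)
                      = (k1 + k3 x^2) / (k2 (x+1) + k4 (x+1)^3).

    Evaluated in log-space and normalized; independent of the nullspace
    solve, this is the exactness oracle for the generator construction.
    """
    params.require_stochastic()
    if params.r != 1:
        raise ValueError("detailed balance requires the nearest-neighbour chain r = 1")
    x = np.arange(x_max + 1, dtype=float)
    up = params.k1 + params.k3 * x[:-1] ** 2
    down = params.k2 * x[1:] + params.k4 * x[1:] ** 3
    logp = np.concatenate([[0.0], np.cumsum(np.log(up) - np.log(down))])
    logp -= logsumexp(logp)
    return np.exp(logp)
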