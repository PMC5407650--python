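"""Parameterization and deterministic analysis of the (burst-)Schlögl model.

The Schlögl model is the minimal one-species mass-action scheme showing
bistability::

    0  -> X   (k1)         X  -> 0    (k2 x)
    2X -> 3X  (k3 x^2)     3X -> 2X   (k4 x^3)

The burst variant replaces the autocatalytic step by ``2X -> (2+r)X`` firing
at rate ``k3 x^2 / r``: each firing produces ``r`` molecules but occurs ``r``
times less often, so the deterministic rate equation

    dx/dt = A(x) = k1 - k2 x + k3 x^2 - k4 x^3

is independent of the burst size ``r`` while the intrinsic noise grows with
it.  This module holds the parameter container, the propensity/stoichiometry
description, and everything deterministic: drift, fixed points, the cubic
discriminant and mono-/bistability classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SchloglParams",
    "ReactionSystem",
    "FixedPointSet",
    "build_system",
    "drift",
    "drift_prime",
    "fixed_points",
    "discriminant",
]


@dataclass(frozen=True)
class SchloglParams:
    """Rate constants and burst size of the burst-modified Schlögl model.

    Parameters
    ----------
    k1, k2, k3, k4 : float
        Mass-action rate constants of the four reaction channels.  ``k4``
        defaults to 1, which makes ``k1..k3`` coincide with the reduced
        parameters ``k̃i = ki / k4``.
    r : int
        Burst size of the autocatalytic production step (``r = 1`` is the
        unmodified model).

    Notes
    -----
    ``k1 = 0`` is admitted so that degenerate cubics can be analysed
    deterministically, but the stochastic modules reject it (state 0 would
    be absorbing and no stationary law exists); they call
    :meth:`require_stochastic`.
    """

    k1: float
    k2: float
    k3: float
    k4: float = 1.0
    r: int = 1

    def __post_init__(self) -> None:
        for name in ("k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.k1) or self.k1 < 0:
            raise ValueError(f"k1 must be non-negative, got {self.k1!r}")
        if isinstance(self.r, float) and not float(self.r).is_integer():
            raise ValueError(f"burst size r must be an integer >= 1, got {self.r!r}")
        if int(self.r) < 1:
            raise ValueError(f"burst size r must be an integer >= 1, got {self.r!r}")
        object.__setattr__(self, "r", int(self.r))

    @classmethod
    def from_reduced(cls, k1: float, k2: float, k3: float, r: int = 1) -> "SchloglParams":
        """Build from reduced parameters ``k̃i = ki / k4`` (implies k4 = 1)."""
        return cls(k1=k1, k2=k2, k3=k3, k4=1.0, r=r)

    @property
    def reduced(self) -> tuple[float, float, float]:
        """Reduced parameters ``(k̃1, k̃2, k̃3)`` with ``k̃i = ki / k4``."""
        return (self.k1 / self.k4, self.k2 / self.k4, self.k3 / self.k4)

    def with_(self, **kwargs) -> "SchloglParams":
        d = dict(k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4, r=self.r)
        d.update(kwargs)
        return SchloglParams(**d)

    def require_stochastic(self) -> None:
        if self.k1 <= 0:
            raise ValueError(
                "k1 must be strictly positive for stochastic analysis: with "
                "k1 = 0 the state x = 0 is absorbing and no unique stationary "
                "distribution exists"
            )

    def as_dict(self) -> dict:
        return dict(k1=self.k1, k2=self.k2, k3=self.k3, k4=self.k4, r=self.r)


@dataclass(frozen=True)
class ReactionSystem:
    """Propensities and stoichiometry of the four reaction channels.

    For burst size ``r`` the stoichiometric vector is ``S = [+1, -1, +r, -1]``
    and the propensity vector is ``ν(x) = [k1, k2 x, k3 x²/r, k4 x³]``, so
    that ``S·ν(x) = A(x)`` for every state: the burst leaves the drift
    unchanged.
    """

    params: SchloglParams
    stoichiometry: tuple[int, int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", (1, -1, self.params.r, -1))

    def propensities(self, x) -> np.ndarray:
        """Propensity vector ν(x); vectorized, returns shape ``(4,) + x.shape``."""
        p = self.params
        x = np.asarray(x, dtype=float)
        return np.stack(
            [
                np.broadcast_to(p.k1, x.shape).astype(float),
                p.k2 * x,
                p.k3 * x**2 / p.r,
                p.k4 * x**3,
            ]
        )

    def total_propensity(self, x) -> np.ndarray:
        return self.propensities(x).sum(axis=0)


def build_system(params: SchloglParams) -> ReactionSystem:
    """Reaction-channel description (ν, S) for the given parameters."""
    return ReactionSystem(params)


def drift(params: SchloglParams, x):
    """Deterministic drift ``A(x) = k1 - k2 x + k3 x² - k4 x³`` (r-independent)."""
    x = np.asarray(x, dtype=float)
    out = params.k1 - params.k2 * x + params.k3 * x**2 - params.k4 * x**3
    return out.item() if out.ndim == 0 else out


def drift_prime(params: SchloglParams, x):
    """``A'(x) = -k2 + 2 k3 x - 3 k4 x²``."""
    x = np.asarray(x, dtype=float)
    out = -params.k2 + 2 * params.k3 * x - 3 * params.k4 * x**2
    return out.item() if out.ndim == 0 else out


def discriminant(params: SchloglParams) -> float:
    """Discriminant Δ of the reduced cubic ``A(x)/k4 = 0``.

    Δ = -27 k̃1² + 18 k̃1 k̃2 k̃3 - 4 k̃1 k̃3³ - 4 k̃2³ + k̃2² k̃3²

    with k̃i = ki / k4.  Δ > 0: three distinct real roots (deterministically
    bistable); Δ < 0: one real root (monostable); Δ = 0: saddle-node
    boundary (a repeated root).
    """
    a, b, c = params.reduced
    return -27.0 * a**2 + 18.0 * a * b * c - 4.0 * a * c**3 - 4.0 * b**3 + b**2 * c**2


@dataclass(frozen=True)
class FixedPointSet:
    """Non-negative real fixed points of the drift, sorted ascending.

    ``stability`` holds one label per root: ``"stable"`` (A' < 0),
    ``"unstable"`` (A' > 0) or ``"marginal"`` for a repeated (saddle-node)
    root where A' = 0.  ``delta`` is the cubic discriminant.
    """

    roots: tuple[float, ...]
    stability: tuple[str, ...]
    delta: float

    @property
    def n_stable(self) -> int:
        return sum(1 for s in self.stability if s == "stable")

    @property
    def largest_stable(self) -> float:
        cands = [x for x, s in zip(self.roots, self.stability) if s != "unstable"]
        if not cands:
            raise ValueError("no stable fixed point")
        return max(cands)


# relative gap below which two cubic roots are reported as one double root
_MERGE_RTOL = 1e-6


def _polish_root(params: SchloglParams, x0: float) -> float:
    """Newton polish of a cubic root; falls back to bisection on a bracket."""
    x = x0
    for _ in range(8):
        f = drift(params, x)
        df = drift_prime(params, x)
        if df == 0.0:
            break
        step = f / df
        x_new = x - step
        if not np.isfinite(x_new):
            break
        if abs(x_new - x) <= 1e-14 * max(1.0, abs(x)):
            x = x_new
            break
        x = x_new
    # bracket check: if sign change nearby, bisect for safety
    h = max(1e-9, 1e-9 * abs(x))
    lo, hi = x - h, x + h
    try:
        if drift(params, lo) * drift(params, hi) < 0:
            x = brentq(lambda t: drift(params, t), lo, hi, xtol=1e-13, rtol=1e-15)
    except ValueError:
        pass
    return x


def fixed_points(params: SchloglParams) -> FixedPointSet:
    """All real roots of ``A(x) = 0`` with ``x >= 0``, with stability labels.

    Roots are found from the cubic's companion matrix and polished by
    Newton/bisection; roots closer than 1e-6 relative are merged and
    reported once with the label ``"marginal"`` (saddle-node).  Negative
    roots are discarded (molecule counts live on x >= 0).
    """
    coeffs = [-params.k4, params.k3, -params.k2, params.k1]
    raw = np.roots(coeffs)
    scale = max(1.0, np.abs(raw).max())
    real = [float(z.real) for z in raw if abs(z.imag) <= 1e-8 * scale]
    real = sorted(_polish_root(params, x) for x in real)

    merged: list[list[float]] = []
    for x in real:
        if merged and abs(x - merged[-1][-1]) <= _MERGE_RTOL * max(1.0, abs(x)):
            merged[-1].append(x)
        else:
            merged.append([x])

    roots: list[float] = []
    labels: list[str] = []
    for group in merged:
        x = float(np.mean(group))
        if x < -_MERGE_RTOL:
            continue
        x = max(x, 0.0)
        if len(group) > 1:
            labels.append("marginal")
        else:
            ap = drift_prime(params, x)
            labels.append("stable" if ap < 0 else ("unstable" if ap > 0 else "marginal"))
        roots.append(x)

    return FixedPointSet(tuple(roots), tuple(labels), discriminant(params))
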