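"""Fokker-Planck description of the burst-Schlögl model.

The second-order Kramers-Moyal truncation of the chemical master equation
gives a Fokker-Planck equation with drift ``A`` and diffusion ``B``::

    A(x) = k1 - k2 x + k3 x^2   - k4 x^3      (independent of burst size r)
    B(x) = k1 + k2 x + r k3 x^2 + k4 x^3

The stationary density (zero-flux boundary at x = 0) is

    Ps(x) = N / B(x) * exp( \\int_0^x 2 A / B dx' ),

and its extrema are the roots of ``alpha(x) = A(x) - B'(x)/2``: the maxima
of Ps are the stochastic analogue of stable states, so counting them over
parameter sweeps reveals phenomenological (P-) bifurcations.

Densities are computed and stored in log-space throughout: the exponent
``\\int 2A/B`` reaches magnitudes of order 1e5 for the desk-scale rate sets
used here and would overflow any naive exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson, trapezoid
from scipy.optimize import brentq

from .model_core import SchloglParams, drift, drift_prime, fixed_points

__all__ = [
    "StationaryDensity",
    "ExtremaReport",
    "TruncationError",
    "DegenerateRootsError",
    "diffusion",
    "diffusion_prime",
    "alpha",
    "alpha_prime",
    "stationary_density",
    "closed_form_r1",
    "find_extrema",
    "default_x_max",
]

# fraction of total mass allowed in the top 1% of the grid before the
# domain is declared too small
_TAIL_TOL = 1e-9


class TruncationError(RuntimeError):
    """The chosen domain cuts off non-negligible probability mass."""


class DegenerateRootsError(ValueError):
    """Partial fractions are invalid for repeated drift roots (Δ = 0)."""


def diffusion(params: SchloglParams, x):
    """Diffusion ``B(x) = k1 + k2 x + r k3 x² + k4 x³`` (> 0 for x >= 0)."""
    x = np.asarray(x, dtype=float)
    out = params.k1 + params.k2 * x + params.r * params.k3 * x**2 + params.k4 * x**3
    return out.item() if out.ndim == 0 else out


def diffusion_prime(params: SchloglParams, x):
    """``B'(x) = k2 + 2 r k3 x + 3 k4 x²``."""
    x = np.asarray(x, dtype=float)
    out = params.k2 + 2 * params.r * params.k3 * x + 3 * params.k4 * x**2
    return out.item() if out.ndim == 0 else out


def alpha(params: SchloglParams, x):
    """Extremum function ``alpha(x) = A(x) - B'(x)/2``.

    Roots of alpha on x > 0 are exactly the interior extrema of the
    stationary density; a negative-going crossing is a maximum of Ps.
    """
    x = np.asarray(x, dtype=float)
    out = (
        params.k1
        - params.k2 * x
        + params.k3 * x**2
        - params.k4 * x**3
        - 0.5 * (params.k2 + 2 * params.r * params.k3 * x + 3 * params.k4 * x**2)
    )
    return out.item() if out.ndim == 0 else out


def alpha_prime(params: SchloglParams, x):
    """``alpha'(x) = A'(x) - B''(x)/2``."""
    x = np.asarray(x, dtype=float)
    out = drift_prime(params, x) - (params.r * params.k3 + 3 * params.k4 * x)
    return out.item() if out.ndim == 0 else out


def default_x_max(params: SchloglParams) -> float:
    """Default domain size: twice the largest deterministic root plus 10 r."""
    fps = fixed_points(params)
    top = max(fps.roots) if fps.roots else 1.0
    return 2.0 * max(top, 1.0) + 10.0 * params.r


@dataclass(frozen=True)
class StationaryDensity:
    """Stationary FPE density on a grid, stored in log-space.

    ``log_density`` is normalized so that the trapezoid integral of
    ``exp(log_density)`` over ``grid`` is 1; ``norm_const`` is the log of the
    normalization constant that was subtracted.
    """

    grid: np.ndarray
    log_density: np.ndarray
    norm_const: float
    method: str

    @property
    def density(self) -> np.ndarray:
        return np.exp(self.log_density)

    def integral(self) -> float:
        return float(trapezoid(self.density, self.grid))

    def grid_maxima(self) -> np.ndarray:
        """Interior local maxima of the gridded density (grid resolution)."""
        d = self.log_density
        idx = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
        return self.grid[idx]

    def tail_mass(self) -> float:
        """Probability mass carried by the top 1% of the grid."""
        n = max(2, len(self.grid) // 100)
        return float(trapezoid(self.density[-n:], self.grid[-n:]))


def _log_unnormalized(params: SchloglParams, grid: np.ndarray) -> np.ndarray:
    """log Ps up to a constant: -log B + cumulative Simpson of 2A/B."""
    B = diffusion(params, grid)
    integrand = 2.0 * drift(params, grid) / B
    expo = cumulative_simpson(integrand, x=grid, initial=0.0)
    return expo - np.log(B)


def _normalize(grid: np.ndarray, logp: np.ndarray, method: str) -> StationaryDensity:
    shift = logp.max()
    z = trapezoid(np.exp(logp - shift), grid)
    log_norm = shift + np.log(z)
    return StationaryDensity(grid, logp - log_norm, float(log_norm), method)


def stationary_density(
    params: SchloglParams,
    x_max: float | None = None,
    grid_step: float = 0.05,
    auto_extend: bool = True,
) -> StationaryDensity:
    """Stationary density by log-space quadrature; valid for every r >= 1.

    Parameters
    ----------
    x_max : float, optional
        Upper edge of the domain.  Defaults to ``default_x_max`` and, when
        ``auto_extend`` is true, is doubled until the top 1% of the grid
        carries less than 1e-9 of the mass.
    grid_step : float
        Grid spacing in molecules; must be <= 0.1 for the quadrature and
        extremum cross-checks to hold at their stated tolerances.

    Raises
    ------
    TruncationError
        If the tail criterion fails and the domain may not be enlarged.
    """
    params.require_stochastic()
    if grid_step > 0.1:
        raise ValueError("grid_step must be <= 0.1 molecules")
    if x_max is None:
        x_max = default_x_max(params)

    for _ in range(12):
        n = int(np.ceil(x_max / grid_step)) + 1
        grid = np.linspace(0.0, x_max, n)
        dens = _normalize(grid, _log_unnormalized(params, grid), "quadrature")
        if dens.tail_mass() < _TAIL_TOL:
            return dens
        if not auto_extend:
            raise TruncationError(
                f"tail mass {dens.tail_mass():.3e} at x_max={x_max} exceeds "
                f"{_TAIL_TOL}; enlarge x_max (try {2 * x_max})"
            )
        x_max *= 2.0
    raise TruncationError("domain doubling did not satisfy the tail criterion")


def closed_form_r1(params: SchloglParams, grid: np.ndarray) -> StationaryDensity:
    """Analytic stationary density for the unmodified model (r = 1).

    With ``A = -k4 (x-x1)(x-x2)(x-x3)`` and ``B = k4 (x+x1)(x+x2)(x+x3)``
    (B(x) = A(-x) for r = 1), a partial-fraction decomposition of ``2A/B``
    gives

        2A/B = -2 + sum_i c_i / (x + x_i),
        c_i  = 4 x_i (x_i+x_j)(x_i+x_k) / ((x_i-x_j)(x_i-x_k)),

    hence ``log Ps = -2x + sum_i (c_i - 1) log(x + x_i) + const``.  The roots
    may form a complex-conjugate pair (Δ < 0); the sum is then real and is
    evaluated with principal-branch complex logarithms, which are continuous
    on x >= 0 because every x_i has positive real part for the bistable/
    monostable families considered (Re x_i > 0 whenever all coefficients of
    the cubic alternate in sign).

    Raises
    ------
    DegenerateRootsError
        For repeated drift roots (Δ = 0), where partial fractions are
        invalid; use :func:`stationary_density` instead.
    """
    params.require_stochastic()
    if params.r != 1:
        raise ValueError("closed form is only valid for r = 1")
    grid = np.asarray(grid, dtype=float)

    roots = np.roots([-params.k4, params.k3, -params.k2, params.k1])
    scale = max(1.0, np.abs(roots).max())
    for i in range(3):
        for j in range(i + 1, 3):
            if abs(roots[i] - roots[j]) <= 1e-6 * scale:
                raise DegenerateRootsError(
                    "repeated drift roots (Δ = 0): partial fractions are "
                    "invalid; use the quadrature solver"
                )

    logp = -2.0 * grid.astype(complex)
    for i in range(3):
        xi = roots[i]
        others = [roots[j] for j in range(3) if j != i]
        ci = 4.0 * xi * (xi + others[0]) * (xi + others[1]) / (
            (xi - others[0]) * (xi - others[1])
        )
        logp = logp + (ci - 1.0) * np.log(grid + xi)
    logp = np.real(logp)
    return _normalize(grid, logp, "closed_form")


@dataclass(frozen=True)
class ExtremaReport:
    """Extrema of the stationary density located as roots of alpha.

    ``maxima`` and ``minima`` are sorted and interleave; ``merged_pairs``
    holds locations where a maximum and minimum coincide (tangential root of
    alpha, the P-bifurcation signature).  ``boundary_mode`` flags a density
    monotone on the whole domain, whose only mode sits at x = 0.
    """

    maxima: tuple[float, ...]
    minima: tuple[float, ...]
    merged_pairs: tuple[float, ...] = ()
    boundary_mode: bool = False

    @property
    def n_maxima(self) -> int:
        return len(self.maxima)


def find_extrema(
    params: SchloglParams,
    x_max: float | None = None,
    scan_step: float = 1.0,
    merge_rtol: float = 1e-6,
) -> ExtremaReport:
    """Locate all extrema of Ps in (0, x_max] as roots of alpha.

    A sign scan with step ``scan_step`` brackets simple roots, which are
    refined by bisection to 1e-9 absolute; a negative-going crossing of
    alpha is a maximum of Ps, a positive-going one a minimum.  A tangential
    (double) root — where alpha touches zero within ``merge_rtol`` of its
    scan-scale without changing sign — is reported in ``merged_pairs``
    rather than as two extrema.
    """
    if x_max is None:
        x_max = default_x_max(params)
    xs = np.arange(0.0, x_max + scan_step, scan_step)
    vals = alpha(params, xs)
    ref = np.abs(vals).max()

    maxima: list[float] = []
    minima: list[float] = []
    merged: list[float] = []

    sign = np.sign(vals)
    for i in range(len(xs) - 1):
        if sign[i] == 0.0:
            # grid point exactly on a root; classify by neighbours
            x0 = xs[i]
            if i > 0 and sign[i - 1] > 0:
                maxima.append(float(x0))
            elif i > 0 and sign[i - 1] < 0:
                minima.append(float(x0))
            continue
        if sign[i] * sign[i + 1] < 0:
            root = brentq(lambda t: alpha(params, t), xs[i], xs[i + 1], xtol=1e-9)
            if sign[i] > 0:
                maxima.append(float(root))
            else:
                minima.append(float(root))

    # tangential roots: local extrema of alpha that graze zero without crossing
    interior = np.flatnonzero(
        (np.abs(vals[1:-1]) <= np.abs(vals[:-2])) & (np.abs(vals[1:-1]) <= np.abs(vals[2:]))
    ) + 1
    for i in interior:
        if np.abs(vals[i]) < merge_rtol * ref and sign[i - 1] == sign[i + 1] != 0:
            x0 = float(xs[i])
            near = [z for z in maxima + minima if abs(z - x0) < 2 * scan_step]
            if not near:
                merged.append(x0)

    if not maxima and not minima:
        # density monotone on the domain: the single mode sits on the boundary
        mode = 0.0 if alpha(params, 0.0) <= 0 else float(x_max)
        return ExtremaReport((mode,), (), tuple(merged), boundary_mode=True)

    return ExtremaReport(tuple(sorted(maxima)), tuple(sorted(minima)), tuple(merged))
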