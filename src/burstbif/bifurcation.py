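"""Phenomenological-bifurcation (P-bifurcation) analysis.

A P-bifurcation is a qualitative change in the *shape* of the stationary
probability law — here, a change in its number of maxima, detected when two
extrema of Ps merge.  Because the burst size r enters only the diffusion
B(x) and not the drift A(x), sweeping r moves the extrema (and hence the
bifurcation boundaries in parameter space) without touching the
deterministic fixed points: burst noise can destroy a deterministic
saddle-node bifurcation or induce one where the rate equation has none.

The sensitivity of a bifurcation boundary to r follows from the implicit
function theorem applied to alpha(x; k, r) = 0 at fixed x:

    dk/dr = -(d alpha/dk)^(-1) * d alpha/dr
          = (d2B/dxdr) / (2 dA/dk - d2B/dkdx),

which evaluates to k̃3 x for k̃1, -2 k̃3 x/(2x+1) for k̃2 (tending to the
constant -k̃3 for x >> 1, which is why the boundary curves for successive r
are equidistant along k̃2), and k̃3/(x - r) for k̃3 (vanishing for x >> r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import cme, fpe
from .model_core import SchloglParams, discriminant, fixed_points

__all__ = [
    "StabilityLabel",
    "ShiftReport",
    "PhaseDiagram",
    "ExtremaTrack",
    "count_maxima",
    "shift_derivative",
    "track_extrema_vs_r",
    "scan_phase_diagram",
]

Source = Literal["deterministic", "fpe", "cme"]


@dataclass(frozen=True)
class StabilityLabel:
    """Mono-/bistability classification of one parameter point."""

    label: str  # monostable | bistable | bifurcation_point
    n_maxima: int
    source: str


def count_maxima(
    params: SchloglParams,
    source: Source = "fpe",
    x_max: float | None = None,
) -> StabilityLabel:
    """Number of stable states at one parameter point.

    source='deterministic' counts stable fixed points of the drift (which
    never depends on r); 'fpe' counts maxima of the stationary FPE density
    via the roots of alpha; 'cme' counts interior modes of the truncated
    master-equation stationary law.
    """
    if source == "deterministic":
        fps = fixed_points(params)
        if any(s == "marginal" for s in fps.stability):
            return StabilityLabel("bifurcation_point", fps.n_stable, source)
        n = fps.n_stable
    elif source == "fpe":
        rep = fpe.find_extrema(params, x_max=x_max)
        if rep.merged_pairs:
            return StabilityLabel("bifurcation_point", rep.n_maxima, source)
        n = rep.n_maxima
    elif source == "cme":
        xm = int(np.ceil(x_max if x_max is not None else fpe.default_x_max(params)))
        xm = max(xm, 10 * params.r)
        dist = cme.stationary_distribution(cme.build_generator(params, xm))
        n = len(dist.modes)
    else:
        raise ValueError(f"unknown source {source!r}")
    return StabilityLabel("bistable" if n >= 2 else "monostable", n, source)


@dataclass(frozen=True)
class ShiftReport:
    """Sensitivity dk̃i/dr of an extremum-defining parameter to burst size.

    ``analytic`` is the implicit-function-theorem value; ``finite_difference``
    re-solves alpha(x; k, r') = 0 for the parameter at r and r+1 with the
    extremum location x held fixed and takes the slope.
    """

    which: str
    x: float
    r: int
    analytic: float
    finite_difference: float

    @property
    def rel_error(self) -> float:
        if self.analytic == 0.0:
            return abs(self.finite_difference)
        return abs(self.finite_difference - self.analytic) / abs(self.analytic)


def _solve_k_on_manifold(params: SchloglParams, which: str, x: float, r: int) -> float:
    """The value of k̃_which that puts an extremum at x for burst size r.

    alpha is affine in each single rate parameter, so the solve is exact:
    alpha = alpha|_{k=0} + k * (d alpha/dk).
    """
    base = params.with_(r=r)
    # alpha(x) = A - (k2 + 2 r k3 x + 3 k4 x^2)/2; coefficients of each k̃:
    coef = {"k1": 1.0, "k2": -(x + 0.5), "k3": x * x - r * x}[which]
    probe = base.as_dict()
    rest = (
        fpe.alpha(base, x)
        - coef * probe[which]
    )
    return -rest / coef


def shift_derivative(params: SchloglParams, which: str, x: float, r: int | None = None) -> ShiftReport:
    """dk̃/dr at an extremum (x, r) of the stationary density.

    Special closed forms: dk̃1/dr = k̃3 x; dk̃2/dr = -2 k̃3 x/(2x+1);
    dk̃3/dr = k̃3/(x-r) (a pole at x = r, reported as undefined).  The
    formulas hold on the extremum manifold alpha(x; k, r) = 0; the input
    point is not required to lie on it, in which case the values describe
    the manifold through (x, r) at the given rates.
    """
    if which not in ("k1", "k2", "k3"):
        raise ValueError("which must be one of 'k1', 'k2', 'k3'")
    if r is None:
        r = params.r
    k3t = params.k3 / params.k4
    if which == "k3" and x == r:
        raise ZeroDivisionError(
            "dk̃3/dr has a pole at x = r (the extremum shift is undefined there)"
        )

    # implicit function theorem on alpha(x, k, r) = 0 at fixed x
    dalpha_dr = -k3t * x
    dalpha_dk = {"k1": 1.0, "k2": -(x + 0.5), "k3": x * x - r * x}[which]
    analytic = -dalpha_dr / dalpha_dk

    k_lo = _solve_k_on_manifold(params, which, x, r)
    k_hi = _solve_k_on_manifold(params, which, x, r + 1)
    fd = (k_hi - k_lo) / params.k4  # actual-rate slope -> reduced units
    return ShiftReport(which, float(x), int(r), float(analytic), float(fd))


@dataclass(frozen=True)
class ExtremaTrack:
    """Extrema of the stationary density as a function of burst size r."""

    table: pd.DataFrame  # columns: r, maxima, minima, n_maxima
    transitions: tuple[int, ...]  # r values where n_maxima changes vs r-1

    @property
    def deterministic_roots(self) -> tuple[float, ...]:
        return self._det_roots

    _det_roots: tuple[float, ...] = ()


def track_extrema_vs_r(
    params: SchloglParams,
    r_range: Iterable[int],
    x_max: float | None = None,
) -> ExtremaTrack:
    """Extrema locations per burst size; flags r where the mode count changes.

    The deterministic fixed points are attached for overlay; they are the
    same for every r because the burst leaves the drift unchanged.
    """
    rows = []
    prev_n = None
    transitions: list[int] = []
    for r in r_range:
        p = params.with_(r=int(r))
        rep = fpe.find_extrema(p, x_max=x_max)
        n = rep.n_maxima
        if prev_n is not None and n != prev_n:
            transitions.append(int(r))
        prev_n = n
        rows.append(dict(r=int(r), maxima=rep.maxima, minima=rep.minima, n_maxima=n))
    det = fixed_points(params)
    track = ExtremaTrack(pd.DataFrame(rows), tuple(transitions))
    object.__setattr__(track, "_det_roots", det.roots)
    return track


@dataclass(frozen=True)
class PhaseDiagram:
    """Mono-/bistable labels over a 1-D or 2-D reduced-parameter grid.

    ``n_maxima`` has shape (len(r_list), n_axis1) or
    (len(r_list), n_axis2, n_axis1).  ``boundaries[r]`` holds the bisected
    axis-1 locations where the label changes, per axis-2 value for 2-D
    scans: a list of (axis2_value, crossing) pairs (axis2_value is None in
    1-D scans).
    """

    axis1: str
    axis1_values: np.ndarray
    axis2: str | None
    axis2_values: np.ndarray | None
    fixed: dict
    r_list: tuple[int, ...]
    source: str
    n_maxima: np.ndarray
    boundaries: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ir, r in enumerate(self.r_list):
            if self.axis2 is None:
                for i1, v1 in enumerate(self.axis1_values):
                    n = int(self.n_maxima[ir, i1])
                    rows.append({self.axis1: v1, "r": r, "n_maxima": n,
                                 "label": "bistable" if n >= 2 else "monostable"})
            else:
                for i2, v2 in enumerate(self.axis2_values):
                    for i1, v1 in enumerate(self.axis1_values):
                        n = int(self.n_maxima[ir, i2, i1])
                        rows.append({self.axis1: v1, self.axis2: v2, "r": r,
                                     "n_maxima": n,
                                     "label": "bistable" if n >= 2 else "monostable"})
        return pd.DataFrame(rows)


_KNAMES = ("k1", "k2", "k3")


def _point_params(fixed: dict, r: int, **axis_vals) -> SchloglParams:
    kw = dict(fixed)
    kw.update(axis_vals)
    missing = [k for k in _KNAMES if k not in kw]
    if missing:
        raise ValueError(f"scan under-determined: missing {missing}")
    return SchloglParams.from_reduced(kw["k1"], kw["k2"], kw["k3"], r=r)


def _n_maxima_at(params: SchloglParams, source: str, x_max: float | None) -> int:
    return count_maxima(params, source=source, x_max=x_max).n_maxima


def scan_phase_diagram(
    axes: Sequence[tuple[str, Sequence[float]]],
    fixed: dict | None = None,
    r_list: Sequence[int] = (1,),
    source: Source = "fpe",
    x_max: float | None = None,
    refine_rtol: float = 1e-4,
) -> PhaseDiagram:
    """Label a reduced-parameter grid mono-/bistable for each burst size.

    Parameters
    ----------
    axes : one or two of ('k1', values), ('k2', values), ('k3', values)
        Reduced parameters swept; the remaining ones come from ``fixed``.
    r_list : burst sizes, one grid layer each.
    source : which stationary law defines the label (see
        :func:`count_maxima`).  The deterministic layer exposes the cusp
        geometry of the underlying rate equation.
    refine_rtol : relative tolerance of the bisected boundary locations
        along the first axis.

    Boundary crossings along the first axis are refined by bisection on the
    label, giving grid-independent boundary curves.
    """
    fixed = dict(fixed or {})
    if not 1 <= len(axes) <= 2:
        raise ValueError("axes must contain 1 or 2 swept parameters")
    names = [a[0] for a in axes]
    for nm in names:
        if nm not in _KNAMES:
            raise ValueError(f"unknown axis {nm!r}")
    a1_name, a1_vals = axes[0][0], np.asarray(axes[0][1], dtype=float)
    if len(axes) == 2:
        a2_name, a2_vals = axes[1][0], np.asarray(axes[1][1], dtype=float)
    else:
        a2_name, a2_vals = None, None

    r_list = tuple(int(r) for r in r_list)
    shape = (len(r_list), len(a1_vals)) if a2_name is None else (
        len(r_list), len(a2_vals), len(a1_vals))
    n_max = np.zeros(shape, dtype=int)
    boundaries: dict[int, list] = {r: [] for r in r_list}

    def bisect_boundary(r, lo, hi, n_lo, a2v):
        """Bisection in axis-1 between differing labels."""
        target_change = n_lo
        while (hi - lo) > refine_rtol * max(abs(hi), abs(lo), 1e-300):
            mid = 0.5 * (lo + hi)
            kw = {a1_name: mid}
            if a2_name is not None:
                kw[a2_name] = a2v
            n_mid = _n_maxima_at(_point_params(fixed, r, **kw), source, x_max)
            if n_mid == target_change:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    for ir, r in enumerate(r_list):
        a2_iter = [None] if a2_name is None else list(a2_vals)
        for i2, a2v in enumerate(a2_iter):
            row = np.zeros(len(a1_vals), dtype=int)
            for i1, v1 in enumerate(a1_vals):
                kw = {a1_name: float(v1)}
                if a2_name is not None:
                    kw[a2_name] = float(a2v)
                row[i1] = _n_maxima_at(_point_params(fixed, r, **kw), source, x_max)
            if a2_name is None:
                n_max[ir, :] = row
            else:
                n_max[ir, i2, :] = row
            for i1 in range(len(a1_vals) - 1):
                if row[i1] != row[i1 + 1]:
                    c = bisect_boundary(r, float(a1_vals[i1]), float(a1_vals[i1 + 1]),
                                        row[i1], a2v)
                    boundaries[r].append((None if a2v is None else float(a2v), c))

    return PhaseDiagram(a1_name, a1_vals, a2_name, a2_vals, fixed, r_list,
                        source, n_max, boundaries)
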