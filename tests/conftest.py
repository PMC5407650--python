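"""Shared fixtures: published parameter sets and random-model constructors."""

from __future__ import annotations

import numpy as np
import pytest

from burstbif.fixtures import fixtures
from burstbif.model_core import SchloglParams


@pytest.fixture(scope="session")
def fig6_params() -> SchloglParams:
    """Burst-induced-bistability demonstration set (r defaults to 1)."""
    return fixtures("fig6").params(r=1)


@pytest.fixture(scope="session")
def fig3_params() -> SchloglParams:
    """Deterministically bistable set used for the method cross-checks."""
    return fixtures("fig3").params(r=1)


def params_from_real_roots(x1: float, x2: float, x3: float, r: int = 1) -> SchloglParams:
    """Reduced parameters whose drift has the three given positive roots.

    From A/k4 = -(x - x1)(x - x2)(x - x3): k̃3 = e1, k̃2 = e2, k̃1 = e3
    (elementary symmetric polynomials).  Distinct roots give Δ > 0.
    """
    k3 = x1 + x2 + x3
    k2 = x1 * x2 + x1 * x3 + x2 * x3
    k1 = x1 * x2 * x3
    return SchloglParams.from_reduced(k1, k2, k3, r=r)


def params_from_complex_pair(a: float, b: float, c: float, r: int = 1) -> SchloglParams:
    """Reduced parameters with drift roots c and a ± bi (Δ < 0, monostable)."""
    k3 = c + 2 * a
    k2 = 2 * a * c + a * a + b * b
    k1 = c * (a * a + b * b)
    return SchloglParams.from_reduced(k1, k2, k3, r=r)


def random_param_sets(rng: np.random.Generator, n: int, bistable: bool | None = None):
    """Random desk-scale parameter sets built from drift-root placement.

    Root magnitudes stay below ~100 so truncated-CME state spaces remain
    small; ``bistable`` forces the sign of Δ, None alternates.
    """
    out = []
    for i in range(n):
        want_bi = bistable if bistable is not None else (i % 2 == 0)
        if want_bi:
            roots = np.sort(rng.uniform(2.0, 90.0, size=3))
            while np.min(np.diff(roots)) < 2.0:
                roots = np.sort(rng.uniform(2.0, 90.0, size=3))
            out.append(params_from_real_roots(*roots))
        else:
            out.append(
                params_from_complex_pair(
                    rng.uniform(2.0, 40.0), rng.uniform(2.0, 30.0), rng.uniform(5.0, 90.0)
                )
            )
    return out
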