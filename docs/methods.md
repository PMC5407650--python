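# Methods

## Model

One chemical species with four mass-action channels; state `x` is the
molecule count.  The burst parameter `r ≥ 1` modifies only the autocatalytic
channel, `2X → (2+r)X` at propensity `k₃x²/r`, so each firing delivers `r`
molecules but fires `r` times less often.  The propensity vector and
stoichiometry are

```
ν(x) = [k₁, k₂x, k₃x²/r, k₄x³],    S = [+1, −1, +r, −1],
```

and the drift `A(x) = S·ν(x) = k₁ − k₂x + k₃x² − k₄x³` is exactly
independent of r — a property the test suite asserts symbolically on grids.
All propensities are the model family's *polynomial* rates; we deliberately
do not use combinatorial factors `x(x−1)…`, because the Fokker–Planck
reduction and the discriminant analysis are derived from the polynomial
forms and the two conventions differ at small `x`.

Reduced parameters `k̃ᵢ = kᵢ/k₄` are used for all phase-diagram work; a rate
set quoted without `k₄` implies `k₄ = 1`, which is the only reading
consistent with the definition of the reduced variables.

`k₁ = 0` is accepted by the deterministic layer (it makes the cubic
factorable and is useful for boundary cases) but rejected by every
stochastic module, because `x = 0` is then absorbing and no unique
stationary law exists.

## Deterministic layer

Fixed points are the non-negative roots of the cubic `A(x) = 0`, obtained
from the companion matrix (`numpy.roots`) and polished by Newton iteration
with a bisection fallback on a bracketing interval.  Roots closer than 1e−6
(relative) are merged and labelled `marginal` — the saddle-node signature —
which keeps the classification robust on the bifurcation boundary `Δ = 0`.
Negative roots are discarded (molecule counts).  Stability comes from the
sign of `A′` at each root and alternates stable/unstable/stable when three
roots exist.

The discriminant
`Δ = −27k̃₁² + 18k̃₁k̃₂k̃₃ − 4k̃₁k̃₃³ − 4k̃₂³ + k̃₂²k̃₃²` classifies the
rate equation: `Δ > 0` ⇔ three distinct positive real roots (bistable).
The acceptance suite validates this equivalence on 1000 log-uniform random
draws against exact Sturm-sequence root counting (sympy, rationalized
coefficients) — an oracle fully independent of floating-point root finding.

## Fokker–Planck layer

Second-order Kramers–Moyal truncation of the master equation gives drift
`A(x)` and diffusion `B(x) = k₁ + k₂x + rk₃x² + k₄x³` (burst noise enters
only here).  With a zero-flux (reflecting) boundary at `x = 0`, the
stationary density is `Ps(x) = N/B · exp(∫₀ˣ 2A/B dx′)`.

Numerics:

* Everything is computed and stored in **log-space**; the exponent
  `∫2A/B` reaches magnitudes ~10⁵ for the demonstration rate sets and would
  overflow any direct exponential.  Normalization shifts by the maximum
  before exponentiating.
* The exponent integral uses cumulative Simpson quadrature on a uniform
  grid (default step 0.05 molecules, capped at 0.1).  Simpson rather than
  trapezoid keeps the quadrature/closed-form discrepancy below 1e−6
  sup-norm even for small-molecule-number parameter sets whose integrand
  curvature is large near the origin.
* Default domain: `x_max = 2·(largest deterministic root) + 10r`, doubled
  automatically until the top 1 % of the grid carries < 1e−9 of the mass;
  exceeding that tail budget without permission to extend raises a
  truncation error naming a suggested domain.

For `r = 1`, `B(x) = A(−x)`, so with drift roots `x₁, x₂, x₃` (possibly one
real plus a conjugate pair) a partial-fraction decomposition gives the
closed form

```
log Ps(x) = −2x + Σᵢ (cᵢ − 1)·log(x + xᵢ) + const,
cᵢ = 4xᵢ(xᵢ+xⱼ)(xᵢ+xₖ) / ((xᵢ−xⱼ)(xᵢ−xₖ)).
```

Complex-conjugate root pairs give conjugate `cᵢ`, so the sum is real; the
principal complex logarithm is continuous on `x ≥ 0` because every root has
positive real part when the cubic's coefficients alternate in sign.  The
closed form refuses repeated roots (`Δ = 0`, partial fractions invalid) and
directs the caller to the quadrature solver.  Quadrature and closed form
are verified against each other (sup-norm < 1e−6) on randomized parameter
sets of both discriminant signs.

**Extrema.**  Interior extrema of `Ps` are the roots of
`α(x) = A(x) − B′(x)/2`: the identity `d log Ps/dx = (2A − B′)/B` (also
regression-tested by finite differences) makes a negative-going crossing of
α a maximum.  Root finding is a unit-step sign scan over `[0, x_max]` with
bisection refinement to 1e−9 absolute — deterministic and bracketing-safe.
A tangential root (α grazing zero within 1e−6 of its scan-scale without a
sign change) is reported as a bifurcation point, not as two extrema, which
is exactly the "extrema merge" definition of the P-bifurcation.  If α has
no interior root the density is monotone and the report flags a boundary
mode.  Extrema are continuous reals; round to the nearest integer when a
molecule count is needed.

## Master-equation layer

States `0..x_max`, jumps `+1` at `k₁`, `−1` at `k₂x + k₄x³`, `+r` at
`k₃x²/r`, assembled as a sparse generator `Q` (columns sum to zero).  Burst
jumps that would overshoot the truncation are redirected to `x_max`, which
conserves probability exactly; the bias is negligible whenever the tail
criterion (top 1 % of states < 1e−9 of the mass) holds, and is verified by
the truncation-stability test (doubling `x_max` changes the law by
TV < 1e−9).  The stationary vector solves the sparse linear system with one
equation replaced by normalization — deterministic, no spectral-gap
sensitivity.  For `r = 1` the chain is nearest-neighbour, detailed balance
holds, and the closed-form recurrence
`p(x+1)/p(x) = (k₁+k₃x²)/(k₂(x+1)+k₄(x+1)³)` serves as an independent
oracle (agreement TV < 1e−10).

Mode extraction takes all interior local maxima, breaking flat ties toward
the smaller state (ties are flagged).  For the demonstration set
`k = (3·10⁶, 77518, 601, 1)` at `r = 25` the upper lobe of the exact CME
law is flat to < 0.2 % across states ≈ 358–374; the argmax (366) therefore
sits several states below the Fokker–Planck extremum (372.3), and any
histogram-derived estimate in that window is statistically indistinguishable
from either.  This is a genuine, reproducible feature of the exact solution,
cross-checked by two solvers and two truncation sizes.

Agreement between the gridded FPE density and the CME law is quantified by
total variation: TV ≈ 3.6e−5 at `r = 1` and 0.016 at `r = 11` for the
bistable demonstration set, degrading to ≈ 0.09 by `r = 41` — the expected
growth of the Kramers–Moyal truncation error with jump size.  The tests
assert TV < 0.05 for r ∈ {1, 11}; the large-r degradation is a property of
the FPE approximation, not of either solver.

## Stochastic simulation

Exact direct-method Gillespie: waiting time `Exp(a₀(x))` with
`a₀ = k₁ + k₂x + k₃x²/r + k₄x³`, channel chosen proportionally to its
propensity.  No tau-leaping or hybrid acceleration — exactness is the point
of the oracle chain.  The inner loop is JIT-compiled (numba) so that the
convergence checks at realistic event rates (~10⁸ events per time unit for
the demonstration sets) remain cheap; time units are arbitrary inverse-rate
units.  A run is reproduced bit-exactly by `(params, x0, seed)`; one named
stream per trajectory.

Occupancy histograms weight each visited state by its holding time after a
burn-in (default 10 % of `t_max`; the default initial state is the nearest
integer to the largest non-repelling deterministic root, so the burn-in
removes the transient).  A streaming variant accumulates the histogram
inside the kernel for runs too long to store event-by-event; the two paths
are verified to agree exactly on a common trajectory.

Event-level exactness is tested statistically on a small-rate system
(holding-time means within 3σ of `1/a₀`; burst-jump share binomial-tested
against `ν₃/a₀`), and distribution-level correctness by TV convergence to
the CME law.  For the bistable demonstration set the documented run is
`t_max = 1.0` time units (~6·10⁸ events) with burn-in 0.1 and a fixed seed,
giving TV ≈ 0.01–0.03 < 0.05 across seeds; mode switching is slow at these
parameters, so substantially shorter runs misweight the two lobes.

## Bifurcation analysis

`count_maxima` labels a parameter point by its number of stable states from
any of the three sources (deterministic root count, α-roots, CME modes);
`track_extrema_vs_r` sweeps the burst size and flags mode-count changes.
For the demonstration set the sequence is monostable (r = 1) → bistable
(r ≈ 2–40) → monostable again (r ≳ 50): burst noise first induces and then
destroys the bistability, with the deterministic picture unchanged
throughout.

Phase diagrams label 1-D or 2-D reduced-parameter grids per burst size;
boundary crossings along the scan axis are refined by bisection on the
label to 1e−4 relative, giving grid-independent curves (resolution
stability is tested by halving the grid).  The deterministic layer
reproduces the cusp geometry: the bistable window along `k̃₁` closes as
`k̃₂ → k̃₃²/3` and vanishes at the cusp point `(k̃₁, k̃₂) = (k̃₃³/27,
k̃₃²/3)`.

The sensitivity of a boundary to r follows from the implicit function
theorem on `α(x; k, r) = 0` at fixed `x` (α is affine in each rate, so the
finite-difference cross-check re-solves the manifold exactly):

* `∂k̃₁/∂r = k̃₃x` — grows with x, so the two saddle-node branches of a
  `k̃₁`-window shift at different rates and the window closes with
  increasing r (verified: the demonstration window at `k̃₂ = 1.65·10⁵,
  k̃₃ = 720` is gone by r = 11);
* `∂k̃₂/∂r = −2k̃₃x/(2x+1) → −k̃₃` for `x ≫ 1` — the boundary curves along
  `k̃₂` are equidistant in r (measured spacings within 0.2 % of `−k̃₃` per
  unit r);
* `∂k̃₃/∂r = k̃₃/(x−r)` — vanishes for `x ≫ r`, with a pole at `x = r`
  reported as undefined.

The `∂k̃₂/∂r` expression is derived from the implicit-function formula
rather than transcribed; its large-x limit `−k̃₃` is the tested statement.

## Synthetic test systems

Unit tests that need arbitrary rate sets construct them by *root
placement*: choosing drift roots (three reals, or one real plus a conjugate
pair) and recovering `k̃ᵢ` from the elementary symmetric polynomials.  This
guarantees the discriminant sign and keeps state spaces desk-scale
(roots ≤ 90) so truncated-CME oracles stay small.  These synthetic systems
exercise every code path but are still members of the same cubic family —
they say nothing about multi-species networks, extrinsic noise, or
non-polynomial propensities, all of which are out of scope.

## Known limitations

* Stationary analysis only: no time-dependent CME/FPE solutions, no mean
  first-passage or Kramers switching-time analysis, no flux-based
  (D-) bifurcations.
* The FPE route is an approximation whose error grows with burst size
  (see the TV figures above); the CME solver is the arbiter at large r.
* The SSA event loop is single-species and unoptimized beyond JIT; runs
  are practical up to ~10⁹ events.
* Phase-diagram boundary extraction assumes label changes are resolved by
  the input grid; windows narrower than the grid step are missed (the cusp
  test chooses its grid accordingly).
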