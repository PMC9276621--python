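# Methods

## Model reduction and constitutive choices

The three-phase mixture (cells `n`, liquid `w`, rigid scaffold `s`,
`n + w + s = 1`) is closed with Darcy laws for the two fluid phases and the
pressure relation `p_n = p_w + Σ(n)`. Eliminating `v_w, p_n, p_w`
analytically leaves a single nonlinear diffusivity

    Φ(n) = K(1−n−s) / [μ_n(1−n−s) + μ_w n] · dΣ/dn,

and the model reduces to the degenerate reaction–diffusion problem stated
in the README. The constitutive pressure uses one repulsion coefficient δ
for both cell–cell and cell–scaffold contact; the attraction coefficient χ
enters Σ only as a constant offset and is therefore dynamically inert (a
unit test asserts this). The dispersal coefficient must satisfy ν > 0 so
that Φ > 0 on the whole domain `0 ≤ n < 1−s`; the aggregation regime
ν ≤ 0 is outside the model's validity and is rejected at construction.

After scaling time by 1/r_m and length by √(Φ(0)/r_m), the dimensionless
diffusivity is

    φ(n) = (1−s)(1−n−s) / [(η(1−s)+s)(1−(1−μ)n−s)] · [(1−s)/(1−n−s)² + η − 1],

with φ(0) = 1 exactly. The mixture factor `1−(1−μ)n−s` is obtained by
factoring μ_n out of the Darcy denominator; it makes φ identical to
Φ(n)/Φ(0) (asserted to 1e−12 in tests) and gives the physically expected
trend that fronts speed up as μ → 0 (cells far more viscous than the
liquid) and as η → 0. Domain evaluation is guarded within 1e−9 of the
packing singularity at n = 1−s.

Defaults throughout: s = 0.2 (porosity 0.8, typical of engineered
scaffolds), μ = η = 1, quadratic seeding ω = 0.03 with L0 = 1, cosh-mode
amplitudes A0 = 0.05, B0 = 0.01. These are the study conditions for all
regime and asymptotic experiments, and tests do not vary them.

## Moving-boundary solver

The front is immobilised with ξ = x/L(t), putting the problem on ξ ∈ [0,1]
at the cost of an advective term (ξ/L)L'(t)∂n/∂ξ. Discretisation:

* **Diffusion** in conservative form, second-order midpoint fluxes
  `F_{i+1/2} = D((n_i+n_{i+1})/2)(n_{i+1}−n_i)/h` with mobility
  D(n) = nφ(n); the mobility argument is clipped at zero so tolerance-level
  undershoots cannot create negative diffusivity. No regularisation is
  added at the degenerate point n = 0: the flux vanishes there naturally.
* **Advection** with second-order upwind-biased differences, direction
  switched per step on the sign of dL/dt (dL/dt < 0 occurs transiently for
  κ < 0); the node adjacent to the inflow boundary uses a central
  difference. First-order upwinding was tried and rejected: its numerical
  diffusion converges too slowly for the logarithmic-slope and wave-speed
  diagnostics at affordable grids.
* **Boundaries**: zero flux at ξ = 0 via ghost-node reflection
  (F_{−1/2} = 0); the ξ = 1 row is pinned to n = 0, and the edge gradient
  driving dL/dt = −(1/L)∂n/∂ξ(1,t) uses a second-order one-sided
  three-point stencil.
* **Time integration**: SciPy BDF with a sparse Jacobian pattern
  (pentadiagonal nodal coupling plus the dense L row/column), default
  tolerances rel 1e−8 / abs 1e−10. L is an extra state variable integrated
  monolithically, so the ξL' coupling carries no splitting error.

Grids: 401 nodes for production runs, 101 for tests (grid-convergence
tests confirm second order; observed orders ≈ 2 ± 0.5). Default horizon
t_end = max(50, 10/|κ|) for regime runs; long asymptotic comparisons run
to t = 10⁴ with logarithmically spaced report times. With the reaction
switched off the scheme conserves total mass L∫n dξ to ≈ 6×10⁻⁵ relative
over t ∈ [0, 50], which is the audit used to validate the flux form.

The regime classifier combines the sign rule for κ with late-time
evidence over the final 20% of the run: a flat positive dL/dt (linear), a
flat positive t·dL/dt (logarithmic; L ~ b ln t gives t·dL/dt → b), or a
vanishing dL/dt (stationary). Disagreement between the sign rule and the
fit evidence yields an `inconclusive` label rather than a silent guess.

## Travelling-wave shooting

For κ > 0 the wave is the heteroclinic orbit of
dq/dn = −[q(c+q) + n(κ−n)φ(n)]/(qn) joining the saddle (κ, 0) to (0, −c).
Both endpoints are singular, so the orbit is launched at n = κ−ε along the
local linearisation q = λ(n−κ), λ the positive root of
κλ² + cλ − κφ(κ) = 0, and integrated down to n_floor with event
termination (q → 0 from below, or |q| beyond a large bound). Defaults:
ε = 10⁻⁴κ, n_floor = 10⁻⁶κ, bisection tolerance 10⁻⁸ in c; the computed
speed is insensitive to halving ε and n_floor (tested), which justifies
the singular-endpoint treatment.

The root-finder bisects on the terminal mismatch F(c) = q(n_floor; c) + c.
Empirically (and by the saddle-slope argument: λ decreases with c), orbits
with c too small plunge to q → −∞ (F < 0) and orbits with c too large
terminate shallow near q = 0 (F > 0); the sign pattern is verified when
the bracket is built rather than assumed. The initial bracket
[10⁻³κ, 2·max(√(κφ_max), κ)] covers both the small-κ law c ≈ κ/√2 and
Fisher-like 2√(κφ) scalings, and widens geometrically on failure. The wave
shape n(z) is reconstructed by quadrature of dz = φ(n)/q dn along the
orbit, anchored at z = 0 where n = 0.

## Small-|κ| asymptotics

The substitution n = e^{κt}N(x, T), T = (e^{κt}−1)/κ (computed with expm1,
and in log space where κt is large, to avoid cancellation and overflow)
maps the small-κ problem onto the marginal case, whose cosh-mode ansatz
N = A(T) − B(T)cosh(x/√2) closes **exactly**: the implicit solution
(front law sinh(√2L) − √2L = αT + β with α = 2B₀⁻²(A₀²−B₀²)^{3/2},
β = sinh(√2L₀) − √2L₀) satisfies the amplitude ODEs
dA/dT = −A² − B²/2, dB/dT = −3AB/2 with residual at rounding level
(≈ 10⁻¹⁸, checked analytically via the chain rule through the implicit
law). The implicit front equation is solved by bracketed Brent iteration
seeded from the large-T inversion, since the right side spans many
decades.

Large-time consequences, all exposed as operations: L ~ ln(2αT)/√2
(logarithmic growth with universal coefficient 1/√2, fixed by the interior
layer f(θ) = 1 − e^{θ/√2} at the front); c ~ κ/√2 for 0 < κ ≪ 1; a
stationary front L∞ = (1/√2)ln(2α/|κ|)(1+|κ|/α) for κ < 0; and universal
forms N ~ 1/T − m·cosh(x/√2)T^{−3/2} for general initial data with a
single constant m (m = √(2/α) when starting on the cosh branch). `fit_m`
estimates m by linear least squares in (ln T, ln cosh(L/√2)) space with
the slope pinned at 1/2, which makes the fit deterministic. Small-κ
formulas emit a validity warning (never an error) at t < 1 or |κ| > 0.1.

## Accuracy of the asymptotic agreement checks

At κ = +10⁻³ the PDE and the closed forms agree at t = 10⁴ to 0.09% in L
and 0.9% (sup-norm, relative to the profile maximum) in n; at κ = 0 the
fitted-m forms agree to 0.06–0.3% in L and 0.3–1.0% in n for both tested
initial conditions. At κ = −10⁻³ the front agrees with L∞ to 0.35%, but
the printed large-time profile form misses by ≈ 2.1% in sup norm at
converged numerics. That gap is a property of the expansion itself, not of
the solver: the PDE matches the exact cosh-mode solution (mapped back
through the time transform) to 0.6%, while the two-term large-T truncation
it is compared against is evaluated at T = (1−e^{−|κ|t})/|κ|, which
saturates at 1/|κ| = 10³ for κ < 0 — so its O(T^{−1/2}ln T) truncation
error (~2%) cannot be reduced by running longer or refining the grid. The
corresponding regression test asserts the 2% figure and is expected to
fail by this hair's breadth; it is kept strict deliberately rather than
widened to fit.

## Known limitations

* One-dimensional Cartesian geometry only; no scaffold degradation,
  nutrient limitation, or cell–liquid drag.
* The aggregation regime ν ≤ 0 and backward-travelling fronts are out of
  scope; κ < 0 has no travelling wave.
* Viscosities are n-independent; the full two-pressure, two-velocity
  system is eliminated analytically and never represented.
* The small-κ forms degrade for |κ| = O(1) unless μ ≪ 1 and η ≫ 1; no
  quantitative threshold is asserted, only a warning at |κ| > 0.1.
* The synthetic experiment drivers exercise exactly the standard study
  conditions; they do not emulate measurement noise, heterogeneous
  seeding, or spatially varying scaffolds, so passing tests speak to the
  model's internal consistency, not to fit against laboratory data.
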