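# Methods

## The integrator family

An autonomous system `y' = f(y)` with a steady state `y*` (`f(y*) = 0`)
whose Jacobian `Ω = (∂f/∂y)(y*)` has only eigenvalues with negative
real parts relaxes to `y*` from every nearby start. Writing the system
as `y' − Ωy = g(y)` with `g(y) = f(y) − Ωy = O(‖y − y*‖²)` (states
measured relative to `y*`), the variation-of-constants formula expresses
the exact flow as the matrix exponential of `Ω` acting on the state plus
an integral of `g` propagated by the same exponential. Discretizing that
integral with the quadrature weights of a classical Runge–Kutta tableau
`(c, A, b)` yields the exponential Runge–Kutta (expRK) scheme
implemented here: with `V = hΩ`,

    Y_i     = exp(c_i V) y_n + Σ_j a_ij exp((c_i − c_j) V) (h f(Y_j) − V Y_j)
    y_{n+1} = exp(V) y_n     + Σ_i b_i  exp((1 − c_i)  V) (h f(Y_i) − V Y_i).

Properties the test suite verifies rather than assumes:

* **Reduction.** For `Ω = 0` every factor is the identity and the scheme
  is the classical prototype, bit-for-bit up to rounding.
* **Linear exactness.** For `f(y) = Ωy` the remainder `h f(Y) − V Y`
  vanishes and `y_{n+1} = exp(hΩ) y_n` exactly; verified to 1e-10
  relative over 100 steps at `h = 1` on seeded random stable systems.
* **Fixed-point preservation.** `f(0) = 0` makes the origin (i.e. the
  steady state) a fixed point of the map; drift over 1000 steps started
  exactly at the steady state is below 1e-10 on all three benchmark
  models.
* **Order inheritance.** The expRK method has the algebraic order of its
  prototype (the exponential factors expand in powers of `h`); empirical
  orders fitted on the one-gene model are 1.0/2.1/4.1/3.9 for the
  exponential Euler/Heun/RK3/8/RK4 variants.

Systems with `z* ≠ 0` are handled by translating `y = z − z*` per step
(`exprk_step_shifted`); the stage right-hand side evaluates
`h ψ(Y + z*) − V Y`.

### Numerical choices

* **Matrix exponentials** via `scipy.linalg.expm` (scaling-and-squaring
  with Padé approximation). An eigendecomposition-based exponential is
  used only as a test oracle, since `Ω` may in principle be defective.
  Factors `exp((c_i − c_j)V)` with negative coefficient are computed as
  exponentials of the negated matrix, never as matrix inverses. Factors
  with coefficient exactly zero are the identity exactly.
* **Stage-exponential cache.** All factors depend only on
  `(tableau, h, Ω)` and are computed once per run — `2s + 1` matrices
  plus one per nonzero `a_ij`. This is what keeps the per-step cost at a
  handful of `d × d` matrix-vector products.
* **Implicit stages** (backward Euler, trapezoid, implicit midpoint) are
  solved by Newton iteration on the stacked `s·d` stage system using the
  analytic Jacobian of `f`, absolute residual tolerance 1e-12, at most
  50 iterations, initial guess `exp(c_i V) y_n` (the known linear part).
  Non-convergence raises an error naming the tableau, step size and
  iteration count.
* **Divergence handling.** A non-finite state entry, or a state norm
  beyond 1e12, truncates the trajectory and sets its `diverged` flag
  instead of raising, so that instability experiments (classical Euler
  on the stiff p53 model, classical RK4 at large steps) remain
  expressible; such runs score `+∞` in error tables and print as
  `unstable` in CSV output.
* **Step grids.** `t_end` need not be a multiple of `h`; a final partial
  step is truncated (the trajectory records the grid actually taken) and
  a truncated final step still counts as a completed run.

The general formulation with arbitrary matrix-valued coefficients
`a_ij(V)`, `b_i(V)` is exposed only through the step/cache interfaces;
no literature coefficient sets are bundled.

## Benchmark models

State ordering for the two transcription/translation circuits is
`(r_1..r_N, p_1..p_N)`; the rate matrix has the block form
`[[−Γ, F'(p*)], [K, −M]]` with diagonal degradation (`Γ`, `M`) and
translation (`K`) blocks.

**One-gene self-repression** (dimensionless rates): the protein
represses its own gene as a dimer, `F(p) = α/(1 + p²/θ²)`. Defaults
`α = 3, γ = 1, μ = 1.5, κ = 5, θ = 1`. The protein steady state is the
unique positive root of `p³/θ² + p − ακ/(γμ) = 0` (solved by
`numpy.roots` plus Newton polishing), giving `(r*, p*) = (0.6, 2)` and
`Ω = [[−1, −0.48], [5, −1.5]]` with spectrum −1.25 ± 1.5288i.

**Two-gene cross-regulation**: protein 2 activates gene 1 through
`H⁺(p; θ, n) = pⁿ/(θⁿ + pⁿ)`, protein 1 represses gene 2 through
`H⁻ = θⁿ/(θⁿ + pⁿ)`. Defaults: Hill coefficients 3, maximal
transcription rates 1.8, all degradation/translation rates 1,
thresholds 0.6542. The steady state reduces to one scalar equation for
`p1*` (damped Newton from `p1 = θ1` with step halving, bisection
fallback, tolerance 1e-14); the spectrum solves the quartic
`(λ+γ₁)(λ+γ₂)(λ+μ₁)(λ+μ₂) + D = 0`, where the coupling `D` is the
product of the two Hill slopes at the steady state times
`m₁m₂κ₁κ₂`. Stability is lost through a Hopf bifurcation at the
closed-form threshold `D_Hopf` (= 4 at the default rates); the default
parameters give `D ≈ 3.246 < 4`, hence two stable complex pairs placed
symmetrically about −1 (real parts −1.9491 and −0.0509). The quartic
roots and the eigendecomposition of `Ω` are two independent routes to
the same spectrum and agree to 1e-8 in the tests.

**p53–mdm2 module** (concentrations in nM, rates in 1/min): inactive
p53 `P_I`, its negative regulator mdm2 `M`, the p53–mdm2 complex `C`,
and stress-activated p53 `P_A`, with mdm2 synthesis saturating in p53
(`K_m = 100 nM`) and bilinear complex formation (`k_c = 4 /min/nM`).
With the stress input held at zero the active form simply decays, so
`P_A* = 0`; `M*` and `C*` have closed forms in `P_I*`, which solves a
scalar balance bracketed on `(0, s_p/d_p)` (Brent's method, xtol
1e-13). Defaults give `(9.42094, 0.0372868, 3.49529, 0)`. The Jacobian
is analytic (quotient rule on the saturating term) and cross-checked by
central finite differences to 1e-10; its spectrum is
{−38.626, −0.00432 ± 0.03300i, −0.2002}, the last value being exactly
`−(j_a + d_p)` from the decoupled `P_A` row. The ~1e4 separation
between the fast and slow modes is what makes this model stiff: at
`h = 1/16`, `h·|λ₁| ≈ 2.4` exceeds the real stability interval of
classical Euler, which diverges, while the exponential Euler method (a
fortiori exact on the fast linear mode) is unaffected. The activation
rate `k_a` is stored but idle while the stress input is zero.

Benchmark initial conditions and horizons: one-gene `(0.6, 0.8)` on
[0, 100]; two-gene `(0.6, 0.8, 0, 0)` on [0, 100]; p53
`(10, 0.1, 3, 0.8)` on [0, 50]. Note the slow modes set the physical
settling times: the two-gene transient is still ~3e-3 from the steady
state at t = 100, and the p53 oscillation (period ≈ 285 min, decay rate
0.0028/min) needs ~2000 min to die out — checks of "reached the steady
state" in the tests use horizons chosen accordingly.

## Error measurement

**Average error** = mean absolute deviation of *one* monitored
component from the reference over all points of the fixed-step grid on
`[0, t_end]`: protein `p` (one-gene), protein `p1` (two-gene), inactive
p53 `P_I`. A single component keeps the tables interpretable and
matches the component each model's dynamics is usually read through.

**Reference solutions** come from adaptive DOP853 at rtol 1e-12 / atol
1e-13 (dense output, evaluated on each step grid); halving the
tolerances moves the monitored component by < 1e-9, so errors down to
~1e-9 are trustworthy. Convergence-order fits exclude points at or
below a 1e-9 error floor and are made on step windows inside the
asymptotic regime (0.2·2⁻ᵏ for orders 1–2, 0.4·2⁻ᵏ for order 4 on the
one-gene model); with fewer than two usable points the report is
flagged inconclusive rather than fitted.

**Qualitative settling check**: a run settles if it reaches `t_end` and
`sup_{t ≥ t_end/2} ‖z(t) − z*‖ ≤ 1e-2`. At `h = 1.32` on the two-gene
model classical RK4 fails this check (it orbits ~0.15 from the steady
state) while expRK4 passes — the headline qualitative failure of
structure-blind integration.

**Random stable linear fixtures** for the exactness property are built
as orthogonal similarities of real block-Schur forms with eigenvalue
real parts drawn from a strictly negative range (default [−2, −0.1])
and imaginary parts up to 2, deterministic in the seed (default
20170119). They emulate only the *linear* part of a regulatory system
near its steady state — passing the exactness test says nothing about
nonlinear accuracy, which the benchmark-model experiments cover.

## Known discrepancies with published figures

Published values for these benchmark systems that this package's
computations do not reproduce, kept visible rather than patched:

* **One-gene spectrum.** A published imaginary part of ±2.9767 for the
  one-gene eigenvalues is inconsistent with the rate matrix
  `[[−1, −0.48], [5, −1.5]]`, whose spectrum is −1.25 ± 1.5288i
  (`imag = √(det − tr²/4)`). The real part agrees; the package reports
  what `Ω` gives.
* **Two-gene spectrum.** Our steady state reproduces the published
  14-digit values exactly, yet the published eigenvalue real parts
  (−1.94911366876016, −0.05088633123984) differ from ours
  (−1.949113892647, −0.050886107353) in the 7th decimal. Three
  independent internal routes (eigendecomposition, characteristic
  quartic, finite-difference Jacobian) agree with each other to 1e-12,
  so the published digits appear to carry less precision than printed.
* **p53 spectrum.** The published leading eigenvalue −38.4766 and slow
  pair −0.0028 ± 0.0220i differ from the FD-validated analytic
  Jacobian's −38.6265 and −0.00432 ± 0.03300i (0.4% and ~50%
  respectively), even though the steady state matches every printed
  digit; −0.2002 is exact. No plausible variant of the Jacobian
  reproduces the published pair.
* **Error-table contrasts.** Published table comparisons for these
  models show classical-method columns that plateau near 2e-2 as
  `h → 0`, which no convergent method measured against a convergent
  reference can do; against this package's tight reference the
  exponential variant beats its prototype at *every* tabulated step
  size, but the measured factor is pair-dependent (Euler ≈ 5× one-gene
  / 60–90× two-gene, Heun ≈ 6×/21×, RK3/8 ≈ 4–5×/5–7×, RK4 ≈ 2×/6–28×)
  and, being a ratio of error constants at equal order, is essentially
  step-size independent. Only orderings and these measured factors are
  asserted, never the published absolute cell values.

## Limitations

* Fixed-step only; no embedded pairs or step-size control.
* Dense `d × d` exponentials: intended for small ODE systems (here
  `d ≤ 4`), not for large sparse networks (no Krylov/φ-function
  machinery).
* The schemes target *nonstiff-to-mildly-stiff* systems with a stable
  steady state; no stiff order conditions are imposed, so accuracy (not
  stability) can degrade on strongly stiff problems.
* Implicit variants require an analytic Jacobian of the right-hand
  side.
* Delay, stochastic and SBML-imported models are out of scope.
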