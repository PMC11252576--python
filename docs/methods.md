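# Methods

## Model

The state Y = (R, Q, Aβ, Ip, Ia, S, D) collects seven brain-cell/fibril
populations (dimensionless counts); time is measured in years. The
vector field h(Y) = M Y is linear, with the 7×7 rate matrix M assembled
from seventeen non-negative rates (1/year): sixteen signed crosstalk
pathways λ₁..λ₁₆ between populations and the amyloid clearance rate
λ_r. The default rates are the published reference set (λ₁₅ = λ_r = 1,
the others 10⁻² to 10⁻⁵); the default initial populations are
(10³, 10⁵, 10³, 10³, 10⁵, 10⁴, 10²) and the default horizon is 20
years.

Three structural properties are treated as exact, not approximate:

* **Pairwise conservation.** The Q, Ia and D equations are the exact
  negatives of the R, Ip and S equations, so R+Q, Ip+Ia and S+D are
  invariants. The implementation builds the paired rows of M as bitwise
  negations and evaluates h as a single matrix product, so the paired
  components of every computed derivative are exact floating-point
  negations and the simulated pair totals drift only by the rounding of
  the final additions (observed ≤ 10⁻¹⁵ relative over 20 years).
* **Linearity.** No clamping is applied: populations may go negative
  (pro-inflammatory microglia do, around year 19 at integer order), and
  the solver emits one warning the first time any component crosses
  zero rather than altering the dynamics.
* **Units.** Rates 1/year, populations counts; the fractional operator
  is dimensionally consistent through the t^(q−1) and l^p factors.

One published-table ambiguity is worth flagging: the pathway label
printed for λ_r duplicates the label of λ₁₆. λ_r is implemented as the
amyloid self-clearance rate (the −λ_r Aβ term of the Aβ equation),
which is the only reading consistent with the model equations.

## Fractal-fractional operator and solver

The Caputo-sense fractal-fractional initial value problem of order
(p, q) ∈ (0, 1]² is solved in its equivalent Volterra form

Y(t) = Y₀ + (q/Γ(p)) ∫₀ᵗ s^(q−1) (t−s)^(p−1) h(s, Y(s)) ds.

On a uniform grid tₙ = n l, the function g(s) = s^(q−1) h(s, Y(s)) is
replaced on each panel [tₙ, tₙ₊₁] by the linear Lagrange interpolant
through (tₙ, gₙ) and (tₙ₋₁, gₙ₋₁); the product of a linear polynomial
with the kernel (t_{m+1}−s)^(p−1) integrates in closed form, giving the
explicit two-step product-integration update with prefactor
q lᵖ/Γ(p+2) and the weight pair

wA(m,n,p) = (m+p+2−n)(1+m−n)ᵖ − (m+2p+2−n)(m−n)ᵖ,
wB(m,n,p) = (m+1−n)^(p+1) − (m+1+p−n)(m−n)ᵖ.

Useful identities, all property-tested: at p = 1 the pair is (3, 1) for
every (m, n); at n = m it is (p+2, 1); and
wA − wB = (p+1)[(k+1)ᵖ − kᵖ] with k = m−n, whose telescoping sum makes
the scheme **exact for constant forcing at q = 1**
(Y(tₘ) = Y₀ + c tₘᵖ/Γ(p+1) to roundoff).

### Numerical choices

* **Origin regularization.** For q < 1 the factor t₀^(q−1) is infinite
  at t₀ = 0. The node-0 factor (and the factor of the virtual history
  node −1) is evaluated at the first positive node, g₀ := t₁^(q−1).
  This keeps all weights finite, is exactly inert at q = 1, and
  perturbs only the first panel (local error O(l^(p+q))).
* **History at the first step.** The n = 0 term references the off-grid
  point (t₋₁, Y₋₁); it is supplied by constant extrapolation
  (t₋₁, Y₋₁) := (t₀, Y₀), the standard two-step starter, which
  preserves the constant-forcing exactness above and reduces the first
  step to explicit Euler at p = q = 1.
* **0ᵖ = 0** for p > 0 wherever (m−n)ᵖ appears at n = m (the limit the
  weight derivation assumes; numpy's `0.0**p` already complies).
* **Cumulative accumulation.** Each Y_{m+1} is rebuilt from Y₀ by the
  full memory sum (O(N²) total work, N ≤ a few thousand at desk scale).
  This matches the scheme's closed form literally and avoids mixing
  incremental rounding into the memory terms.
* **Determinism.** No randomness anywhere; double precision; the memory
  sum always runs in increasing n, so identical inputs give
  bit-identical trajectories.
* **Defaults.** l = 0.05 years, horizon 20 years, overridable.
* **Failure handling.** A non-finite state aborts with the step index;
  negative populations only warn (once).

### Validation oracles

Each corner of the parameter square is checked against an independent
route (none shares code with the scheme):

| regime | oracle | observed agreement |
|---|---|---|
| p = q = 1, any linear system | matrix exponential exp(Mt) Y₀ (scipy `expm`) | endpoint error ~3×10⁻⁶ at l = 0.02, falling 4.0× when l halves (second order) |
| q = 1, scalar relaxation y' = −y | y = E_p(−tᵖ), Mittag–Leffler series | max deviation 2.4×10⁻⁶ on [0, 5] at l = 10⁻³, p = 0.9 |
| any (p, q), forcing c tᵃ | Beta closed form Y₀ + c (q/Γ(p)) B(q+a, p) t^(p+q+a−1) | ≤ 2×10⁻² relative at l = 0.01 over (p,q) ∈ {0.6, 0.8, 1}², a ∈ {0, 1}, improving under refinement |
| general (p, q), full model | fine-grid self-reference (8× refinement) | halving l from 0.02 to 0.01 shrinks the endpoint gap ~2.3× at (p,q) = (0.9, 0.9) — empirical order ≈ 1.2, below the smooth-case 2 because of the weakly singular kernel near t = 0 |

The Mittag–Leffler series E_p(z) = Σ zᵏ/Γ(pk+1) is summed in double
precision to a 10⁻¹⁴ stopping tolerance; for |z| > 30 the alternating
series cancels catastrophically, so evaluation escalates to mpmath with
a working precision sized to the peak term magnitude exp(|z|^(1/p))
(checked against the erfcx identity E_{1/2}(−x) = e^{x²} erfc(x)).
The self-convergence and grid-refinement studies use a 2-year window
rather than the full 20 so the O(N²) fine-grid reference stays small;
the convergence behavior is set by the kernel near t = 0 and is
insensitive to this choice.

## Ulam–Hyers stability constants

The solution space carries the norm ‖Y‖ = max_t Σᵢ |Yᵢ(t)|; the
consistent Lipschitz constant of the linear map is the maximum absolute
column sum of M, X_Θ = ‖M‖₁ (for the reference rates,
X_Θ = λ_r + 2(λ₈+λ₁₃) = λ₁₅ + 2(λ₆+λ₁₁) = 1.04, attained by both the
Aβ and S columns). Bounding the Volterra operator on [0, T] gives

Ξ = q X_Θ T^(p+q−1) B(p, q)/Γ(p),  C_{p,q} = Ξ|_{X_Θ=1},

and Ξ < 1 makes the solution map a contraction: uniqueness holds and
every ε-approximate solution lies within C_{p,q}/(1−Ξ) · ε of the exact
one. Γ(p) is used in the denominator throughout (the internally
consistent choice across the derivation; immaterial at p = q, which
covers every equal-order run). The interval-length symbol in the bound
is the horizon T. With the reference rates the certificate holds only
for T < 1/1.04 ≈ 0.96 years at p = q = 1; on the standard 20-year
window Ξ = 20.8 and the report states honestly that the (sufficient)
contraction condition fails rather than asserting stability.

## Sweep behavior and a known discrepancy

The equal-order preset runs p = q ∈ {0.80, 0.85, 0.90, 0.95, 1.00}; a
mixed preset exercises p ≠ q (the scheme is genuinely asymmetric in
(p, q): swapping 0.9/0.8 shifts the 20-year endpoint by ~10² counts).

Amyloid rises toward quasi-equilibrium ≈ (λ₁₅ S − λ₁₆ Ia)/λ_r ≈ 9×10³.
During the initial transient (t ≲ 1 year) the weakly singular kernel
t^(p+q−1) makes lower-order trajectories rise *faster*, so there Aβ
decreases as (p, q) → (1, 1). After the curves cross, fractional memory
slows relaxation (algebraic rather than exponential tails), and from
roughly year 1 onward the ordering is reversed: at the 20-year endpoint
Aβ *increases* monotonically with the common order (8533 → 8907 across
the preset). A qualitative description of the sweep as "amyloid
decreases as the orders approach unity" therefore holds only in the
early transient, not at late times; the late-time check in the
acceptance suite asserts the decreasing ordering and fails, and is left
failing deliberately — the solver is validated independently (table
above), so this is a property of the model, not a solver artifact.

## Limitations

* No spatial structure: dispersion of cells and fibrils is neglected by
  construction; compartments are well mixed.
* The model is linear with constant rates — no saturation, no carrying
  capacities, no age- or estrogen-dependent modulation of the rates.
* The contraction-based stability certificate is sufficient only; its
  failure on long horizons says nothing about instability.
* The scheme is explicit with uniform steps; no adaptive stepping, no
  corrector pass, and only the power-law (Caputo-sense) kernel is
  supported.
* The O(N²) memory sum is quadratic in the step count; at l = 10⁻³ over
  5 years (5000 steps) a run takes ~1 s, but much finer grids would
  want a sum-of-exponentials kernel compression that is out of scope.
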