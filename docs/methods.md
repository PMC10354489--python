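# Methods

## Model class and assumptions

`bgsens` treats a biochemical network as an energy-based (bond-graph)
mass-action model. Species store energy with potential ϕ = ln(Kx);
reactions dissipate it with flow f = κ(e^{Φf} − e^{Φr}). All quantities
are dimensionless: amounts, rate constants and time are assumed already
normalized, and `NormalizationScheme` is an explicit converter between
physical and dimensionless units (thermal energy μ₀ = RT, flow scale
v₀ = P₀/μ₀, amount scale x₀ = v₀t₀, and the Faraday view ϕ₀ = μ₀/F,
f₀ = Fv₀). It is never applied implicitly; the core pipeline is
unit-agnostic.

Assumptions inherited from this model class:

- deterministic ODE kinetics (no stochastic/SSA path);
- strictly positive amounts; the flux law is undefined at x ≤ 0;
- integer stoichiometry, κ > 0, K > 0 — which makes every closed network
  detailed-balanced (all flows vanish at equal potentials across each
  reaction);
- chemostats are species with fixed amounts; they open the system and
  generate trivial conserved "moieties" of their own.

The relation K = e^{μ⊘/RT}/x⊘ to a reference chemical potential is noted
but no μ⊘ → K conversion is offered: the package works with K directly, as
all worked parameter sets are stated in K.

## The sensitivity system

A multiplicative perturbation λ of a species constant K, a chemostat
amount, or a rate constant κ shifts a potential additively by ln λ:
species perturbations shift ϕᵢ, reaction perturbations shift both Φf and
Φr (equivalently scale the flow). The augmented stoichiometry stacks the
species blocks and a reaction-count identity,
Nsf = [Nf; Nf; I], Nsr = [Nr; Nr; I], with every sensitivity state a
chemostat of the augmented system. A chemostat-amount perturbation and a
K-perturbation of the same species are mathematically identical (both
shift ln(Kx)); the default target set therefore carries one λ per species
(amount-flavoured for chemostats, K-flavoured otherwise) plus one per
reaction, and requesting both flavours for one species is rejected as a
duplicate.

The sensitivity system is parameterized by λ directly; the chemostat
potential ln λ is internal. The linearization input is the deviation
λ̃ = λ − 1, which agrees with linearizing in ln λ to first order at the
nominal point λ = 1.

## Numerics

- **Integration** is in log-amounts z = ln x of the dynamic species
  (positivity is structural), with LSODA at rtol 1e-10 / atol 1e-12; the
  exponential flux law is stiff when κ values are disparate.
- **Steady states** are solved by Newton (scipy `root`, hybr) on the
  independent dynamic species after conserved-moiety elimination, so
  moiety totals of the guess are preserved exactly; long-time integration
  is the fallback. Multiple or unstable steady states are not detected —
  the root continued from the guess is returned.
- **Conserved moieties** are computed over exact rationals (row reduction
  of Nᵀ or Ncᵀ) and scaled to primitive integer vectors, avoiding
  floating-point rank decisions on integer matrices. For linearization,
  one species per moiety (the one with the largest amount, for
  conditioning) is expressed through the others, so the reduced
  realization has no uncontrollable/unobservable modes and transfer
  functions contain no cancelling pole/zero pairs.
- **Jacobians** of the flux law are closed-form (derivatives of
  exponentials of linear-in-log potentials); finite differences are used
  only as independent test oracles.
- **Transfer functions** come from `scipy.signal.ss2tf` per input; gains
  are g∞ = d − c a⁻¹ b (requires a Hurwitz) and g₀ = d.
- **Time constants**: a channel is instantaneous (τ = 0) when
  |g₀| > 1e-9 + 1e-6·|g∞|; otherwise the strictly proper SISO channel is
  reduced to order one by balanced truncation (controllability and
  observability Gramians from Lyapunov equations, square-root balancing)
  and τ = −1/pole. Identically zero channels (largest Hankel singular
  value below 1e-12) report τ = NaN — a timescale is meaningless there.
- **Response Hessians** H = (1/t_f)∫₀^{t_f} g gᵀ dt use the exact
  matrix-exponential step response on a uniform grid (default 2001 points)
  with composite Simpson quadrature; Simpson was chosen over the
  trapezoidal rule so that grid refinement changes H by well under 1e-8 at
  the default resolution. No default horizon t_f is imposed — it is an
  analysis choice the caller must make; t_f = ∞ selects H∞ = g∞ᵀg∞.
- **σ convention**: reported σ values are square roots of the Hessian
  eigenvalues (singular values of the response); the raw eigenvalues are
  exposed alongside. Eigenvectors are signed so their largest-magnitude
  component is positive. Significant-mode truncation operates on the
  reported σ spectrum — modes with σ below 1% of the largest σ are
  dropped — and zeroes eigenvector components below 10% of each vector's
  largest element, without renormalizing.
- **Linearization error** for a channel is ε = (g_N − g∞)/g∞ with
  g_N = Δf̄∞/Δλ from the Newton-continued perturbed steady state; it is
  undefined (raises) on zero-g∞ channels.

## Fixtures and what the tests show

`abc_chain` (open A⇆B⇆C, K = 1, κ = (1, 9), chemostats A at x = 2 and C at
x = 1) is the analytically tractable reference: its steady state
(x̄_B = 1.1, flows 0.9), single pole (−10), gain matrices, and the
closed-form finite-horizon Hessian of the r1-flow/rate-constant channels
are all known exactly, and the test suite pins the implementation to them.
`enzyme_module` is an enzyme-catalysed conversion with competitive
activation/inhibition: r1: A+E⇌C, r2: C⇌E+B, rm: E0+Act⇌E+Inh, all
parameters unity except the product amount x_B = 10⁻³ and the conserved
enzyme pool x_E + x_C + x_E0 = 10. The modulation topology is a plausible
reconstruction constrained by that conserved total and by antisymmetric
activator/inhibitor action, so its numbers are checked qualitatively
(saturating flow approaching V_max = e₀κ₂K_C, gains vanishing at
saturation except the catalytic channel, Act/Inh antisymmetry), not as
exact pins.

These fixtures are small, deterministic and desk-scale; passing tests
demonstrate correctness of the machinery, not that real metabolic models
(larger, stiffer, with uncertain parameters and measurement noise) are
well-conditioned for it. In particular, nothing here addresses parameter
*estimation*: the Hessian is a response-sensitivity object, not a Fisher
information with a noise model.

## Known limitations

- λ inputs are constant steps; time-varying perturbation schedules are out
  of scope.
- No global sensitivity sampling (Sobol/Morris); the nonlinear sensitivity
  system supports finite perturbations, but exploration of parameter space
  is the caller's loop.
- Stability is checked (a warning for non-Hurwitz linearizations) but
  bifurcation analysis and steady-state multiplicity are not handled.
- Cost contours are drawn for two-parameter Hessians only.
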