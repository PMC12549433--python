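# Methods

## Model class and standing assumptions

A model is a density-dependent family of Markov chains on S^(N) ⊆ ℤ₊^k:
from state x, the chain jumps by ℓ ∈ 𝓛 at rate N β_ℓ(x/N).  The continuous
state space S̃ is the nonnegative orthant or a box ∏[0, f_i]; for box
models N f_i is rounded to the nearest integer lattice bound and the
rounding is recorded.  The standing assumptions, checked by
`process.validate` (structurally and at sampled points):

1. 𝓛 is finite, symmetric (ℓ ∈ 𝓛 ⇒ −ℓ ∈ 𝓛) and spans ℝ^k;
2. β_ℓ(0) = 0 (the origin is absorbing);
3. β_ℓ(y) > 0 on S̃ \ {0} except exactly where the jump would exit S̃
   (y_i = 0 with ℓ_i < 0, or y_i = f_i with ℓ_i > 0), where it is 0 — this
   makes all nonzero states one communicating class;
4. β_ℓ continuous with finite one-sided derivatives at the origin;
5. the fluid limit dy/dt = Σ ℓ β_ℓ(y) has an unstable equilibrium at 0 and
   a unique stable interior equilibrium y* (verified spectrally after
   root-finding).

Existence of the quasistationary distribution on *infinite* state spaces is
not verified — it is genuinely hard analytically — and reports flag it as
unchecked; on finite boxes it is automatic.

## Reversibility criteria

All criteria are evaluated on a scrambled Sobol sample of the interior
(default 64 points, inset 1% from the boundary; unbounded coordinates are
sampled in [0, 2], around the unit scale of the built-in models), with
relative tolerance 1e-8 for a PASS.  Sampling is the practical surrogate
for "for all interior y"; the count and tolerance are configurable.

* The cycle condition is quantified over integer combinations
  Σ aᵢℓᵢ = 0.  We test an integer basis of the nullspace of the jump
  matrix (one representative per ±pair), computed exactly via sympy; this
  suffices because the log-ratio cycle sums are linear in the coefficients.
  An empty basis (e.g. any multitype birth–death jump set) reports VACUOUS.
* Consistency of the overdetermined systems for θ and θ⁰ is measured by
  the least-squares residual of the solve at each sample (the two views —
  cycle sums and solve residuals — are tested for equivalence).
* Irrotationality is symmetry of the numerically differentiated field
  matrix at each sample (central differences, relative tolerance 1e-6,
  points within 0.1% of the boundary skipped).
* For birth–death jump sets the origin conditions (positive per-capita
  death derivatives, a positive birth entry per row) and the equal-birth
  condition b_ij = b_ii are read off the one-sided derivative matrices.

## The action V, correction V₀, and QSD forms

θ(y) solves ℓᵀθ = ln(β₋ℓ/β_ℓ) by least squares through a precomputed
pseudoinverse of the representative jump matrix; V(y) = ∫ θ·dy' from y*.

* Scalar evaluations integrate along straight segments (S̃ is convex) with
  adaptive Gauss–Kronrod quadrature, absolute tolerance 1e-10.  Endpoints
  on the boundary have integrable logarithmic singularities; the adaptive
  rule never evaluates at the endpoints and resolves them, and a
  non-convergent estimate raises a divergent-action error.  Grid
  evaluations use fixed 128-node Gauss–Legendre vectorised over the batch
  (spectrally accurate for interior targets; agreement with the adaptive
  route is tested to 1e-9).
* The path to the origin for the extinction exponent A = V(0) is the
  straight ray from y*, along which the integrand has a finite limit for
  supercritical models.
* V₀(y) is the telescoping half-log of rate products over a jump
  decomposition of y − y*; the default is axis-aligned in coordinate order
  (unit jumps are present in all built-in families), and independence from
  the decomposition — including ones using non-axis jumps — is tested to
  1e-10.  V₀ diverges on the boundary by construction.
* Σ = ∂θ/∂y at y* by central differences, symmetrised after an asymmetry
  check (tolerance 1e-6 relative); det Σ > 0 is asserted, not assumed.
  Σ⁻¹ is verified against the Lyapunov equation J Σ⁻¹ + Σ⁻¹ Jᵀ + G = 0
  with G = Σ β_ℓ(y*) ℓℓᵀ.
* The WKB mass is M_N e^{−NV−V₀} with M_N = √(det Σ/(2πN)^k); the Gaussian
  approximation is the multivariate normal with mean N y* and variance
  N Σ⁻¹.  The WKB form is valid away from the boundary; the boundary-layer
  width is exposed as a configurable cutoff with default 10/N (ten lattice
  sites), capped at 10% of the shortest box side.  Outside that layer the
  WKB mass over a generous grid sums to 1 within 5% at N = 100; inside it
  V₀ → −∞ and the formula inflates, which is why mass and divergence
  comparisons exclude the layer.

## Near-origin matching and the τ prefactor

For birth–death models with equal birth rates, the linearised balance
equation near the origin has the explicit solution ũ_x (a multinomial
factor times a difference of death-rate products involving the root D of
Σ b_ii/(D+d_i) = 1, solved by bracketed Brent iteration).  All products and
factorials are computed in log space (log-gamma), and the difference of the
two d-products via expm1 on the log difference — direct evaluation
overflows near |x| ≈ 50 and cancels catastrophically beyond.  Matching ũ
against the WKB body fixes its normaliser Λ, and τ = 1/(ΛD).  The
partial-equilibrium evaluation points (0,…,0, y_i*,…,y_k*) follow
coordinate order; the formula's apparent asymmetry in the last coordinate
cancels, which the axis-relabelling invariance test guards (observed
invariance ~1e-10 relative).  One-sided derivatives at these boundary
points use the same inward-shifted finite-difference stencils as
elsewhere, or analytic gradients where registered (all built-ins carry
hand-coded gradients, so criteria checks and Σ are exact up to rounding;
finite differences remain the default for user models).

## Exact oracle

The transient class (all nonzero states, capped per coordinate) is
enumerated and the sub-generator Q assembled sparse.  Box models use their
natural bounds (no truncation error); unbounded models cap at
⌈c·N·y_i*⌉ with default c = 3, clipping outward jumps at the cap
(reflecting truncation — it preserves positivity of the eigenvector, and a
cap-doubling test bounds the bias).  The QSD is the positive left
eigenvector of Q for the eigenvalue −α of maximal real part, by inverse
power iteration on Qᵀ with a reused sparse LU factorisation.  α is
estimated from the solve normaliser (v = Q⁻ᵀu ⇒ α ≈ −1/Σv), **not** from a
Rayleigh quotient: forming Qv cancels catastrophically because α is
exponentially smaller than ‖Q‖.  For the same reason the decay rate is
recoverable in double precision only while α ≫ ε·‖Q‖; the eigen-vs-flux
cross-check (τ = 1/α against the flux identity
τ⁻¹ = N Σ u₋ℓ β_ℓ(−ℓ/N)) holds to 1e-8 at moderate N and degrades towards
that floor as N A grows — callers needing very large N should work with
the WKB asymptotics instead, which is the point of the package.

## Simulation pipeline

Two engines: a transparent event-by-event Gillespie implementation (the
reference; any model, any state), and a numba-compiled kernel driven by
per-state rate/target tables over a capped lattice (default cap 5·N·y*,
generous enough that trajectories essentially never touch it).  The two
are tested against each other statistically.  Randomness is counter-based:
one 31-bit substream per run attempt derived from the protocol seed, so
runs are reproducible and restarts use fresh randomness.

The estimation protocol mirrors empirical practice: runs start at
⌈N y*⌉, a burn-in t₀ (default 10) allows relaxation to quasistationarity
(the spectral gap of the fluid limit at y* makes this tens of relaxation
times for the models shipped), runs extinct before t₀ are discarded and
re-run (budget 100× the sample size), and extinction times measured from
t₀ are right-censored at t_max − t₀.  The MLE for exponential data with
Type-I censoring is τ̂ = (total time)/(events); the confidence interval is
the χ² pivot [2T/χ²_{1−a/2}(2d+2), 2T/χ²_{a/2}(2d)], whose ~95% coverage
is verified by Monte Carlo calibration (10⁴ synthetic samples, 30%
censoring).

The occupation-time QSD estimator credits each run its alive time between
t₀ and min(extinction, t_max).  A stricter `survivors` mode counts only
runs alive at t_max; the default uses all alive time, because discarding
runs that die after burn-in wastes most of the data and the estimator is
validated directly against the exact oracle (total variation ~2e-3 at the
tested sizes).

## Study conditions and what they show

Test and acceptance problem sizes are chosen so every comparison has an
exact ground truth: one-type models at N ∈ {20, 40, 80} (hundreds of
oracle states), the two-group model at N ≤ 100 (≤ 2·10⁴ states), 100
protocol repetitions of 100 runs for interval coverage, 5·10³ runs for the
occupation-time estimator.  The one-type convergence study is run at
λ = 3, μ = 1, κ = 4: the prefactor constant K = √(2πμκ)/(λ−μ)² ≈ 1.25
puts the maximum of the finite-N exponent gap |ln τ/N − A| below N = 20,
so the gap is monotone on the N-range studied, and A ≈ 0.225 keeps α(80)
(~1e-7) far above the double-precision eigenvalue floor discussed above.
Both constraints were derived a priori from the closed-form asymptotics
and then verified.

The built-in families have smooth closed-form rates and carry analytic
gradients; passing tests therefore demonstrate correctness of the
machinery on the model class it targets, not robustness to rate functions
violating the smoothness or boundary assumptions, which `validate`
rejects.  Two limitations surfaced by the exact oracle are worth noting:
(i) at weakly metastable parameter points (N·V(0) of order 1) the true QSD
retains a ridge of mass along the extinction path — at the two-group
illustration parameters and N = 100 its global maximum is the boundary
state (0,1), not the deterministic equilibrium — so mode-based summaries
of the QSD are unreliable there, and the package's tests compare whole
distributions instead; (ii) the WKB and Gaussian approximations carry no
boundary layer, so comparisons against them are restricted to the interior
region described above.

## Known limitations

* Models failing the reversibility criteria are reported, not solved: no
  numerical Hamilton–Jacobi integration by characteristics is attempted.
* The full τ prefactor requires the birth–death jump set with equal birth
  rates; for more general processes only the exponent A is produced.
* The truncated oracle and the lattice simulation tables require the
  capped state space to fit in memory (a guard rejects > 2·10⁶ states);
  both are validation tools for moderate N, not production solvers.
* Config-file model specification covers the built-in families (with
  polynomial factor functions for the separable families); arbitrary rate
  functions are registered programmatically.
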