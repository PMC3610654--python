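# Methods

## Scope and model

`totalnoise` treats a well-mixed reaction network as a Markov jump process
whose master equation is approximated by van Kampen's system-size
expansion. The expansion splits the dynamics into a macroscopic part — the
deterministic rate equations dφ/dt = S f(φ, θ) — and Gaussian fluctuations
around it whose covariance C obeys the linear matrix ODE
dC/dt = A C + C Aᵀ + B with drift A = ∂(S f)/∂φ evaluated along φ(t) and
diffusion B = S diag(f) Sᵀ. The pair (φ, C) approximates the first two
moments of the copy-number distribution. Key assumptions: fluctuations are
small relative to means (accuracy degrades below roughly tens of
molecules), rate laws are smooth in the species, and the network has a
single stable steady state when stationary quantities are requested. All
quantities are carried in molecule numbers (Ω = 1 by convention), which
makes moment-model output directly comparable to Gillespie simulation.

Extrinsic (cell-to-cell) variability is a static multivariate distribution
over kinetic parameters and initial-condition symbols: mean θ̄, covariance
Σ_θ, on a normal or log-normal scale. Time-varying extrinsic fluctuations
are out of scope. The output distribution is then a mixture of the
per-θ Gaussians; its first two moments are what the package computes:

* total mean = E_θ[φ(θ)],
* total covariance = E_θ[C(θ)] + Cov_θ[φ(θ)], the law of total variance,
  reported as the intrinsic and extrinsic components respectively.

The expectation over θ uses the scaled unscented transform (UT): sigma
points χ₀ = θ̄, χᵢ = θ̄ ± columns of √((L+λ)Σ_θ), weights
W₀ᵐ = λ/(L+λ), W₀ᶜ = W₀ᵐ + 1 − α² + β, Wᵢ = 1/(2(L+λ)),
λ = α²(L+κ) − L. The UT is exact for maps that are linear in θ and
second-order accurate otherwise, at 2L+1 moment-model evaluations — linear
in the number of extrinsic factors. Intrinsic covariances are averaged with
the mean weights Wᵐ (the natural reading of E_θ[C(θ)]); the scatter of the
per-point means uses the covariance weights Wᶜ.

## Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| k_R | transcription rate | 1.0 | molecules/s |
| k_P | translation rate | 1.0 | 1/s |
| γ_R / γ_M / γ_P | mRNA / miRNA / protein degradation | 0.1 / 0.1 / 0.01 | 1/s |
| k_b, k_u | miRNA–mRNA binding / unbinding | 0.01, 1.0 | 1/(molecule·s), 1/s |
| g_c | miRNA-induced mRNA degradation (complementarity proxy) | 0.1 | 1/s |
| k_M | miRNA transcription (separate-transcript modes) | 1.0 | molecules/s |
| D0 | gene copy number (constant multiplier, not a species) | 1.0 | molecules |
| α, β, κ | UT spread/weighting | 1, 2, 3−L | — |

The kinetic defaults put the no-feedback steady state at ~10 mRNA and
~1000 proteins — comfortably inside the validity regime of the linear
noise approximation while keeping stochastic-simulation oracles cheap.
They are repository conventions, not measured rates, and every constructor
accepts overrides. κ = 3 − L matches the fourth moment of a Gaussian
(L + λ = 3 for α = 1); for L ≥ 4 the central mean-weight goes negative,
which is standard for the scaled UT and harmless here at the moderate
nonlinearities involved, but it is the reason the intrinsic component is
only guaranteed positive semidefinite to tolerance.

Feedback strengths are stored as explicit rate-law parameters: s = 1/K for
Hill repression of transcription (s_fb) or translation (s_m), and the
binding rate k_b for the mechanistic miRNA circuit. Strength 0 then reduces
each circuit *exactly*, propensity by propensity, to its no-feedback
reference, which is what the relative measure CV²ᵣ divides by (same
remaining parameters, same extrinsic distribution — removing the feedback
changes the mean, intentionally). The two strength conventions are not
numerically comparable across topologies.

The Hill-function miRNA circuit co-produces mRNA and miRNA in a single
transcription event by default. This is the coarse-grained counterpart of
the same-transcript mechanistic design: the correlation between target and
repressor bursts is what makes it a self-repression loop. With independent
transcription of the two species (available as `transcript_mode=
"separate"`) the repressor is open-loop and can only add noise — relative
protein variability never falls below 1 — so the co-produced form is the
default for design screens.

## Numerical choices

* Rate laws are parsed with sympy into a restricted arithmetic grammar with
  one builtin, `hill_repress(x, K, n)`; unknown symbols are rejected by
  name. Propensity vectors and drift Jacobians are differentiated
  symbolically once per network and compiled with `lambdify`; a central
  finite-difference fallback (step 1e-6·max(1,|φ|)) covers points where the
  symbolic form is indeterminate (e.g. 0/0 at φ = 0 for fractional Hill
  exponents). Integer Hill coefficients are kept as integers so the
  symbolic derivative is regular at the origin.
* Moment integration: `scipy.integrate.solve_ivp` (LSODA), rtol 1e-8,
  atol 1e-10, covariance carried as the packed upper triangle and
  symmetrized at output. Initial covariance defaults to zero
  (deterministic initial counts).
* Steady states: the mean ODE is integrated over doubling horizons until
  ‖dφ/dt‖∞ < 1e-9·max(1,‖φ‖∞), polished with a Newton/hybrid root solve,
  the drift is verified Hurwitz-stable (all eigenvalues strictly in the
  left half-plane), and C solves the continuous Lyapunov equation
  A C + C Aᵀ + B = 0 (`scipy.linalg.solve_continuous_lyapunov`). Tight
  sampling loops use a warm-started Newton fast path that falls back to
  the robust route on any failure.
* UT matrix square root: the symmetric eigendecomposition root of
  (L+λ)Σ_θ, with negative round-off eigenvalues clipped. Unlike a Cholesky
  factor it is permutation-equivariant — reordering parameters reorders
  sigma-point coordinates without changing the point set or the
  reconstructed moments — and it handles semidefinite covariances without
  jitter.
* Log-normal mode: (θ̄, Σ_θ) are natural-scale moments, matched to a
  log-space Gaussian via S = log(1 + Σ_θ/θ̄θ̄ᵀ), m = log θ̄ − diag(S)/2;
  sigma points are built in log space and exponentiated, so they are
  strictly positive. Normal-scale sampling paths reject non-positive
  parameter draws and abort if the rejection rate exceeds 50%, pointing to
  the log-normal mode instead; sigma points with non-positive coordinates
  trigger a warning, never silent clipping.
* Nearest correlation matrix: Higham's alternating projections (PSD cone ∩
  unit-diagonal set) with Dykstra correction, tol 1e-8, max 1000
  iterations, plus a final eigenvalue-clip/renormalize polish at the
  tolerance scale. Sign-patterned draws are checked (not constrained):
  if projection flips a prescribed sign the flipped entries are named in a
  warning.
* SSA: the direct (exact) Gillespie method; ensemble kernels are generated
  as Python source with the network's propensities inlined and compiled
  with numba. Per-run seeds derive from the master seed via
  `numpy.random.SeedSequence`, so identical inputs give bitwise-identical
  summaries. Ensemble covariances use denominator n−1; the reported
  standard error of a variance is the normal-approximation
  s²√(2/(n−1)).
* Confidence ellipses: axes along the eigenvectors of the 2×2 covariance,
  half-lengths r√λᵢ; in confidence mode r² is the chi-square(2 dof)
  quantile, so the contour holds probability mass p. Default raw scale
  r = 1.

## What the validation does and does not show

The test battery validates against independent oracles at the repository
defaults: closed-form stationary laws (Poisson birth–death; the two-stage
Fano factor 1 + k_P/(γ_R+γ_P), cross-checked by an independent symbolic
Lyapunov solve at random parameter sets), exact Gillespie ensembles
(10,000 runs for fixed parameters, 100,000 θ-sampled runs for the mixture),
an SSA-free sampling oracle for the decomposition, and Monte-Carlo coverage
of the 95% ellipse. Design-principle screens are asserted qualitatively
(existence and ordering of suppression windows), since those statements —
cooperativity n ≥ 2 required at steady state, transient suppression where
stationary suppression fails, in-loop versus out-of-loop extrinsic noise,
complementarity and transcript-architecture effects, favourable correlation
patterns — are parameter-robust in a way exact curve shapes are not.

These checks exercise synthetic networks with mass-action and Hill
kinetics at moderate copy numbers under static, Gaussian-or-log-normal
extrinsic variability. They do not establish accuracy for very low copy
numbers (where the linear noise approximation itself degrades), for
heavy-tailed or multimodal parameter distributions (the UT matches two
moments only), for oscillatory or multistable networks (stationary
analysis refuses unstable fixed points rather than handling them), or for
time-varying extrinsic noise. Problem sizes in the shipped tests (run
counts, grid densities, sample sizes) were chosen as the smallest that
leave comfortable statistical margins for the assertions they feed.

## Known limitations

* Moment closure is exact only for affine propensities; for Hill-type
  feedback both the LNA and the UT are second-order approximations, and
  skewness of the true mixture is invisible to them.
* The steady-state path requires a unique stable fixed point reachable
  from the initial condition.
* `mixture_sample` draws species values from the conditional Gaussians, so
  it can produce (rare) negative values at small means; it is a moment
  oracle, not a trajectory simulator.
* The sign-pattern presets are defined over the four shared kinetic rates
  (k_R, k_P, γ_R, γ_P); screening other parameter subsets requires
  explicit distributions.
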