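# Methods

## Model

Patients `j = 1..n_h` are clustered in hospitals `h = 1..H`. Each row
carries a binary outcome `Y_hj` (1 = death), patient covariates `X_hj`,
optionally zero-inflation covariates `T_hj`, and each hospital one
attribute `V_h`. The mortality model is

    logit(π_hj) = b_h + f(V_h) + X_hjᵀ β,

with no free global intercept: the location of the random-effect density
plays that role. The two model families are

* **plain** (`model="hcam"`): `Y_hj ~ Bernoulli(π_hj)`;
* **zero-inflated** (`model="zib"`): a latent at-risk indicator `S_hj`
  with `logit(ρ_hj) = T_hjᵀ θ` gates the outcome, `P(Y=1) = ρ π`. The
  inflation part is a pure fixed-effect logistic layer (no random effect in
  `ρ`); `S` is never observed, so the per-patient likelihood marginalizes
  it: `log P(Y=1) = log ρ + log π` and `log P(Y=0) = log(1 − ρπ)`, both
  evaluated through numerically safe `logaddexp` forms.

### Random-effect density

`b_h = a + σ z_h` where `z_h` has density `P_K(z)² φ(z)` with
`P_K(z) = Σ_j ξ_j z^j`. Normalization requires `ξᵀ A ξ = 1` where
`A[i,j] = E[Z^{i+j}]` is the Gaussian raw-moment (Hankel) matrix, computed
with exact integer double factorials. The constraint surface is charted by
hyperspherical angles: `ξ = A^{−1/2} c(φ_1..φ_K)` with `c` a unit vector,
`A^{1/2}` the symmetric PSD square root, each angle in `(−π/2, π/2]`, and
the sign fixed by `ξ_0 ≥ 0` (ξ and −ξ give the same density). Moments of
`b` follow in closed form from Gaussian raw moments; sampling inverts a
10,001-point grid CDF over `a ± 10σ` (truncated tail mass < 1e−15 for any
practical K).

### Fixed-effect spline

The attribute is affinely mapped from its observed range to `[0, 1]`;
interior knots are equally spaced there (a quantile option exists for
skewed attributes such as raw volume). The degree-`d` basis with `q`
interior knots has `m_n = q + d + 1` functions; each is centered by its
mean over the H build hospitals, which enforces the identifiability
constraint `E[f(V_h)] = 0` exactly and, because the uncentered basis is a
partition of unity, leaves a column space of dimension `q + d` (one
coefficient direction is flat; it moves neither `f` nor the likelihood,
and the information-criterion parameter count uses `m_n − 1`
accordingly). Out-of-range evaluation clamps to the domain boundary rather
than extrapolating a cubic polynomial — relevant for bootstrap resamples.

### Likelihood and optimization

Each cluster contributes `log ∫ exp(Σ_j ℓ_hj(b)) g_K(b) db`. The integral
uses adaptive Gauss–Hermite quadrature (21 nodes by default): nodes are
recentered at the mode and rescaled by the curvature of the *Gaussian-base*
log-integrand (cluster log-likelihood plus `log N(b; a, σ²)`), found by a
vectorized damped Newton iteration across all clusters at once; the squared
polynomial is folded into the node weights and the sum is assembled by
log-sum-exp. Adapting on the Gaussian base rather than the full integrand
keeps the mode search concave for the plain model and avoids the
polynomial's zeros; a 15-vs-41-node invariance test guards the accuracy.

The score is computed analytically as the posterior expectation of the
complete-data score on the same nodes (node positions treated as fixed;
the neglected dependence is the derivative of the quadrature error, far
below the optimizer's tolerance at 21 adaptive nodes). A unit test checks
every component against central differences. Optimization is L-BFGS-B over
`(β, γ, a, log σ, angles, θ)` — `σ` on the log scale to stay positive,
angles box-bounded — with relative function tolerance 1e−8, gradient
tolerance 1e−5, at most 500 iterations.

Fits traverse the `K` grid in ascending order. `K = 0` starts from a
no-random-effect logistic regression (its intercept seeds `a`, scale
starts at 1; the inflation coefficients start at 0 so that layer begins
away from its saturated, vanishing-gradient regime). Each larger `K`
starts from the previous optimal polynomial padded with a zero leading
coefficient — an exact continuation, since the moment matrices are nested.
That continuation point is, however, a genuine stationary point whenever
the previous solution is the Gaussian ML fit: degree ≤ 2 polynomial
perturbations of the density are spanned by the location/scale scores
there. The fitter therefore also launches perturbed restarts of the angles
(±0.5, and an alternating pattern for K ≥ 2) and keeps the best final
likelihood; because the continuation start is always included, the fitted
likelihood is nondecreasing in `K`.

`K` is selected by BIC by default (ties to the smaller `K`), with `N` =
total patients in the `log N` penalty. BIC's penalty is appropriate at
registry scale, but in small studies it can exceed any attainable
likelihood gain — at H=100 clusters of 30 the flexible density typically
improves the likelihood by only 2–6 nats while `log N ≈ 8` — which would
collapse every model comparison onto the Gaussian. `fit(selection="aic")`
is provided for such scaled-down studies and is the default in the
replicate harness; at H=500, n_h=50 BIC itself picks `K = 2` on bimodal
truths (gains of ~55 nats).

Per-hospital effects are summarized by the posterior mode of `b_h` under
the fitted density (grid search over `a ± 8σ` with two refinement passes —
the polynomial can make the posterior multimodal, so a pure
gradient search is unsafe); a quadrature posterior mean is available.

## Standardized rates

With `p_𝓗(x)` the predicted mortality of covariates `x` at hospital `𝓗`
(its posterior-mode effect and spline value; times the patient's own
`ρ(T)` in the zero-inflated model):

* `P_h` — mean of `p_h` over hospital h's own patients;
* `E_h` — for each of h's patients, the (weighted) mean of `p_𝓗` over all
  hospitals, then averaged over h's patients; weights are uniform (`1/H`)
  or volume (`n_𝓗/N`), and any explicit vector summing to 1 is accepted;
* indirect `P_h^IS = (P_h/E_h) · OR` with `OR` the overall observed rate —
  a ratio that may exceed 1 and is reported unclipped;
* direct `P_h^DS` — mean of `p_h` over **all** N patients' covariates, so
  every hospital is judged against the same fixed patient population.

Ranks ascend in the rate (1 = lowest = best); quartile labels 1–4 follow
rank position, so group sizes differ by at most one. Uncertainty intervals
subsample `m` patient cases *without* replacement `B` times (defaults
2000/2000), keep the fitted parameters fixed, recompute the rates on each
subsample and take percentile intervals; a classical with-replacement
bootstrap is available as an option. Refitting inside each replicate is exposed behind
the API (fit once, recompute rates) but is not the default: thousands of
ML refits are not a desk-scale operation, and the case-mix resampling is
what the interval is meant to capture.

## Synthetic-data generator

The generator reproduces the benchmark study conditions and is the test
bed for everything above. Patient covariates are `X ~ N(0, I₃)` with
`β = (3, 0.5, −5)`; the attribute is `V ~ Uniform(−1, 1)`; outcomes are
Bernoulli at the model probabilities. Scenario A draws `b_h` from one of
seven standardized (mean-0, variance-1) shapes: normal; uniform
`(−√3, √3)`; `Exp(1) − 1`; `LogN(0, 0.6937) − 1.2720` (the scale solves
`(e^{σ²}−1)e^{σ²} = 1`, making `e^{σ²}` the golden ratio); the symmetric
mixture `0.5 N(∓0.96, 0.28²)` (component mean `√(1 − 0.28²)`); the
asymmetric mixture `(2/3) N(−2/3, (1/3)²) + (1/3) N(4/3, (1/3)²)`; and the
two-point `±1` distribution. Its fixed effect is the damped sine
`f₄(V) = e^{−2V} sin(6V) − 0.5748`. Scenario B varies the fixed effect
over `f₁ = 2V`, `f₂ = (V−0.5)² − 0.5833`, `f₃ = V cos³(3V)` and `f₄`, with
`b_h` from the raw bimodal mixture `0.7 N(−1.5, 0.7²) + 0.3 N(2, 0.7²)`
(mean −0.45, variance 3.0625); a standardized variant is a separate
distribution id, and the ZIB scenario uses it by default (the source
design is ambiguous about which variant scenario B itself used; both are
exposed).

The printed centering constants are kept verbatim in the function
definitions; note the damped-sine constant is a rounding of the exact mean
0.574920, so the population mean of `f₄` is ~1.2e−4 rather than 0 — the
tests budget 5e−4 for it.

The zero-inflated scenario draws a separate at-risk covariate
`X* ~ N(1, 1.5²)`, sets `logit P(S=1) = θ X*` (θ = ±2 giving event rates
of roughly 36% and 14% here), and exposes it to the fitter as
`T = [1, X*]`. A `share_s_covariate` switch implements the alternative
reading in which `X*` also replaces the first mortality covariate. Setting
`theta=None` saturates `ρ ≡ 1`, which reduces the generator (and the
model) to the plain scenario exactly — a tested identity. Train/test
splits halve each cluster. All randomness flows from one seed through six
named substreams (effects, attributes, covariates, statuses, outcomes,
split), so components are independently reproducible.

What the generator does **not** emulate about real registries: informative
cluster sizes (all `n_h` equal), covariate correlation and non-normality,
missingness, hospitals with zero events (a loader flag reproduces the
usual exclusion), and attribute distributions with mass points. Passing
recovery tests therefore demonstrates correctness of the estimator under
the stated designs, not performance on any particular registry.

## Evaluation metrics

`ISE = H^{-1} Σ_h (f̂(V_h) − f(V_h))²` over the build attributes;
`RD = ‖β̂ − β‖/‖β‖`; AUC from midranks with a DeLong-structure variance
for its CI; accuracy, F1 and PPV at the training observed rate as the
classification threshold (the natural prevalence threshold for rare-event
data). Because the centered spline cannot carry the sample mean of the
true curve (it is absorbed by the random-effect location), ISE contains an
irreducible `Var(f)/H` term; at H=100 with the damped-sine curve this is
~0.034, and measured ISE at H=100, n_h=30 is ~0.11–0.16 (an independent
mixed-model implementation reproduces the same value on identical data).
ISE reaches the few-percent range only at several hundred clusters.

## Study sizes used in tests and the acceptance script

Unit tests run on clusters of tens of rows. The recovery study runs the
seven distributions at H=100, n_h=30 with 10 replicates each and the grid
`K ∈ {0, 2}` (AIC selection, as motivated above); the zero-inflated
comparison runs 10 split replicates at the same size with θ = −2, the
stronger-inflation condition. The acceptance script repeats these at 10/8
replicates for two representative distributions and adds one
standardization pass at H=60, n_h=40. The full-scale design (H=500,
n_h=50–100, 200 replications) is supported by the same API — pass the
larger sizes to `ScenarioSpec`/`replicate` — and was spot-checked during
development.

## Known limitations

* One-dimensional random effect and a single hospital attribute; no
  multi-attribute additive or varying-coefficient terms.
* No standard errors for fixed effects (no sandwich/observed-information
  machinery); uncertainty is provided only for standardized rates via
  subsampling.
* The inflation layer is fixed-effects-only, exactly as specified by the
  two-status formulation.
* Quadrature adapts per cluster but uses a common node count; clusters
  with thousands of rows and extreme separation may need `n_quad` raised.
* The angle chart of the coefficient constraint has coordinate
  singularities at `±π/2`; optima near the boundary are handled by box
  bounds, not by re-charting.
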