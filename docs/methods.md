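# Methods

## Model and estimators

All three analysis routes fit the same log-link working model for a binary
outcome, `log P(Y=1|X,Z) = α + βX + γᵀZ`, by maximizing the per-subject
averaged Poisson working log-likelihood
`l(θ) = (1/n) Σ_j [y_j η_j − exp(η_j)]`, `η_j = x_jᵀθ` (the `log y!` term is
zero for 0/1 outcomes). `exp(β)` is the adjusted relative risk. Fitted
risks `exp(η)` may exceed 1; that is intrinsic to the working model and no
projection is applied. Inference always uses the robust sandwich covariance
`B⁻¹MB⁻¹/n`, with bread `B = −(1/n)Σ exp(η_j)x_jx_jᵀ` and meat
`M = (1/n)Σ s_js_jᵀ`, `s_j = x_j(y_j − exp(η_j))`. The meat is the average
of *per-subject* score outer products: the outer product of the averaged
gradient is essentially zero at any (near-)stationary point and would
degenerate, so the standard per-subject form is used throughout, including
for the one-shot estimator.

* **Pooled** — the gold standard: concatenate all rows, fit once.
* **Meta** — two-step meta-analysis: fit each site, combine componentwise
  by fixed-effect inverse-variance weights taken from each site's sandwich
  diagonal. Fixed-effect (not random-effects) matches the homogeneity
  assumption that a single θ governs all sites. Sites whose local fit fails
  or carries a non-positive variance are dropped with a recorded reason.
* **One-shot distributed (ODAP-B)** — the lead site maximizes the surrogate
  `ls(θ) = l₁(θ) + (ḡ − g₁)ᵀθ + ½(θ−θ̄)ᵀ(H̄ − H₁)(θ−θ̄)` built from every
  site's average score `g_k` and Hessian `H_k` at a shared initial value θ̄
  (the meta-estimate by default, a single site's estimate on request).

### Gradient aggregation weighting

Site gradients are 1/n_k averages, so two aggregations are meaningful:
`sample_size` (default) computes `ḡ = Σ (n_k/N) g_k`, which makes
`∇ls(θ̄)` equal the pooled-data score *exactly* for any θ̄ and any site
sizes (an algebraic identity tested to 1e−10); `paper` computes the
unweighted `(1/K) Σ g_k`, which coincides with the former when all sites
have equal size — as in every simulated scenario here. The default was
chosen so that the first-order matching property survives unequal sites.

### One-shot variance

`Var(θ̃) = B₁⁻¹ M₁ B₁⁻¹ / N` with the lead site's average bread and meat
evaluated at the solution and N the total sample size — the federated
analogue of the single-site sandwich, computable without further
communication. An optional `aggregated` mode replaces the bread with the
cross-site average Hessian re-evaluated at θ̃; it costs one extra gradient
round and is off by default to preserve the one-shot budget. 95% CIs are
Wald intervals with critical value 1.959964, exponentiated onto the RR
scale (hence always positive and order-preserving); no multiplicity
adjustment is applied.

## Numerical choices

* **Optimizer:** full Newton–Raphson with step halving (≤50 halvings),
  convergence at max-abs average score ≤ 1e−8, ≤100 iterations. The working
  likelihood is globally concave, so Newton with a monotone line search is
  reliable; a step is accepted when the objective does not decrease —
  strict improvement would stall once gains underflow double resolution.
* **Initialization:** intercept `log(max(mean(y), 1/(2n)))`, slopes 0; the
  surrogate solve starts from θ̄ itself (the correction is centered there).
* **Overflow guard:** |η| > 700 raises a diagnostic error from score and
  Hessian evaluations (silent clipping corrupts gradients);
  `log_likelihood` returns −inf, the correct limit, so line searches can
  back off through overflowing trial points.
* **Degenerate inputs:** all-zero outcomes raise (the MLE diverges);
  rank-deficient designs and singular Hessians raise; sites with a
  zero-event exposure arm converge numerically to an extreme coefficient
  with an enormous sandwich variance and are thereby ~zero-weighted in the
  meta combination — this is deliberately left intact, since downweighting
  sparse sites is exactly where the one-shot estimator's advantage over
  meta-analysis comes from (such sites still contribute full-strength
  gradients to the surrogate).

## Synthetic-data generator

`odapb.simulate` emulates a clinical-research-network design: K ∈ {5, 50}
equal sites of 500 subjects; exposure X1 ~ Bern(0.3); covariates
Z1 ~ Bern(0.6), Z2 ~ Bern(0.5), and a continuous Z3; outcome drawn with
risk `exp(α + β₁X1 + γᵀZ)` with γ = (−0.1, −0.1, −0.1); intercept α = −2
(common disease) or −5 (rare), exposure log-RR β₁ = −0.25 or −1; 1000
replications by default. Z3 stands in for an age covariate whose real
source distribution is unavailable; the default is standard normal
(mean 0, SD 1), configurable to uniform or an empirical sample. A
mean-zero, scale-1 choice keeps the marginal event rate close to the
`exp(α)`-driven design values: analytically ≈11.4% at α = −2 and ≈0.57% at
α = −5 (with β₁ = −0.25), which bracket the nominal ~12% / ~0.7% design
descriptions depending on how much covariate attenuation is included.
Risks above 1 are clipped and counted (impossible in the design scenarios,
where all coefficients are negative); a clip rate above 1% raises a
warning. Every draw is a pure function of (base_seed, replication, site
index), so datasets replay exactly.

What the generator does *not* emulate: covariate shift or effect
heterogeneity across sites, unequal site sizes, confounding structure
between exposure and covariates (all predictors are independent), or
real-world covariates such as race/ethnicity or care-setting categories.
Passing simulation tests therefore demonstrates protocol correctness and
the sparse-event behaviour of the estimators under homogeneous sites, not
robustness to between-site heterogeneity.

## Replication engine

Per replication the engine fits pooled, meta and one-shot (lead = site 1,
meta initialization) and records the relative bias of β₁ to the pooled fit,
`(β̂₁,method − β̂₁,pooled)/|β̂₁,pooled|`; summaries report mean and median
(the per-replication median is the headline, as the mean is ratio-unstable
in sparse scenarios). Fit failures are recorded, not fatal; a scenario
aborts if >20% of pooled fits fail. The type-I error study sets β₁ = 0 and
reports each method's Wald rejection rate at a nominal level with its
binomial Monte-Carlo SE. Default scaled-down sizes used by the test suite:
100 replications for relative-bias orderings, 500 for type-I error; the
full 1000 is available through the scenario configuration.

## Known limitations

* The relative-bias floor between meta and pooled at the common-disease
  setting (α = −2, β₁ = −0.25, K = 5 × 500) is ≈8–10% in median absolute
  terms: the componentwise inverse-variance combination differs from the
  pooled MLE by sampling noise of order 0.02 on a denominator of only
  0.25. The one-shot estimator sits orders of magnitude closer (median
  ≈0.01%). This floor is a property of the estimators at these sample
  sizes, not of the implementation (which matches an independent per-site
  GLM + HC0 oracle to 1e−9).
* In very sparse replicates (a handful of events network-wide) the
  surrogate solve can fail to converge; such results carry a NaN covariance
  and a convergence flag rather than silent output.
* Homogeneous effects are assumed throughout; random-effects combination,
  site-specific effects and small-sample bias corrections (e.g. Firth-type
  penalties) are out of scope.
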