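# Methods

## Observed-data model

The unit of analysis is a pair of log-scale treatment-effect estimates
(log hazard ratios in the shipped examples) for two disjoint subgroups,

```
(μ̂_B, μ̂_C) | (μ_B, μ_C) ~ N((μ_B, μ_C), Σ),
```

with Σ fixed and known.  This is a normal approximation to whatever model
produced the estimates (Cox regressions per subgroup in the examples); it
is adequate unless the trial is small.  When the subgroups are analysed
separately, different patients contribute to each estimate and
`Cov(μ̂_B, μ̂_C) = 0`; a nonzero covariance (covariate-adjusted joint
models) is accepted as user input but never inferred — the package has no
patient-level fitting.

Published summaries are converted via `estimate = log(hr)` and
`se = (log(ci_hi) − log(ci_lo)) / (2 × 1.96)`.  The 1.96 multiplier is
hard-wired for the default 95% level (so that standard errors derived from
printed intervals reproduce the conventional arithmetic digit-for-digit);
any other level uses the exact normal quantile.

The three parameters μ_B, μ_C, δ = μ_B − μ_C are linearly dependent, so a
joint prior is specified for exactly two.  Priors on (μ_C, δ) induce
Cov(μ_B, μ_C) = Var(μ_C) > 0 a priori — benefit in one subgroup makes
benefit in the other more plausible — and allow shrinkage through an
informative δ prior.  Priors on (μ_B, μ_C) directly avoid the asymmetry
that Var(μ_B) = Var(μ_C) + Var(δ) under the first parameterization.

## Prior families and their parameters

* **Normal** `N(a, b²)` per component, vague default `a = 0, b = 10`
  (variance 100, large relative to any realistic Var(μ̂)).  `b = 0` is a
  point mass (e.g. δ ≡ 0 pools the subgroups).
* **Truncation** (upper bound only, e.g. μ_C < log 0.8): density
  renormalized over the allowed region; sampling by inverse CDF rather
  than rejection — exact and O(1) however deep the bound sits in the tail.
* **Power prior**: an informative `N(a, b²)` discounted to `N(a, b²/k)`,
  `k ∈ (0, 1]`.  `k = 1` is full borrowing (a fixed-effect pooling of the
  historical estimate); `k → 0` recovers the vague analysis.  Discounting
  is multiplicative: k₁ then k₂ equals k₁k₂.
* **Discrete**: candidate values `d_j` with elicited masses `p_j`,
  implemented through a latent category M with δ = d_M.  Kept discrete
  end-to-end (the posterior over M is reported); conversion to a
  continuous prior is the elicitation module's concern.
* **Spike-and-slab**: δ = δ_R with spike δ₀ ~ N(0, 0.0001) (sd stored as
  0.01), slab δ₁ ~ N(0, τ²), R | P ~ Bernoulli(P), P ~ Uniform(0, 1)
  (prior inclusion probability 1/2 marginally).  A warning is emitted if
  τ ≤ 10 × spike sd (poorly separated components).  In the collapsed
  single-estimate setting the posterior slab weight is the
  marginal-likelihood ratio
  `w = p φ(δ̂; 0, τ²+v) / [p φ(δ̂; 0, τ²+v) + (1−p) φ(δ̂; 0, s²+v)]`,
  which tends to 0 as τ² → ∞ — a vague slab is always dominated by the
  spike, so τ must be chosen on subject-matter grounds and varied in
  sensitivity analysis.  This closed form is the oracle for the sampler's
  slab-inclusion rate.
* **Bivariate normal** on (μ_B, μ_C); the vague version has variance 100
  and correlation 0.5, which gives μ_B, μ_C and δ identical vague
  marginals.
* **Right-rectified-normal joint prior**: μ_C ~ RN(a, b²) where
  RN(μ, σ²) = min(0, N(μ, σ²)) — continuous on the negatives with an atom
  at zero of mass 1 − Φ(−a/b) — and conditionally
  μ_B | μ_C ~ RN(c μ_C, max(d² + e μ_C, 0)).  Encodes "harm is
  implausible" (no support above 0), "no effect is genuinely possible"
  (atoms at 0), and a conditional mean/variance that depend on μ_C.  When
  the conditional variance hits zero the conditional collapses to a point
  mass at min(0, c μ_C), the continuous limit of the family.

## Posterior computation

For normal (possibly degenerate) priors the posterior is available in
closed form as a standard linear-Gaussian update: with θ = (μ_C, δ) and
design X = [[1, 1], [1, 0]], the posterior is
N((P₀ + XᵀΣ⁻¹X)⁻¹(P₀m₀ + XᵀΣ⁻¹y), (P₀ + XᵀΣ⁻¹X)⁻¹).  The update was
verified against brute-force two-dimensional quadrature before being
adopted as the sampler oracle (the quadrature check is part of the test
suite).  The joint-normal prior case is the same update with identity
design, re-expressed in (μ_C, δ).

All other families use a bespoke sampler rather than a
probabilistic-programming dependency, because every conditional here is
closed-form or one-dimensional and the conjugate oracle makes the sampler
directly testable:

* normal/truncated components: Gibbs with exact conditional normals
  (truncated sampling by inverse CDF);
* discrete δ: M from its categorical conditional ∝ p_j × likelihood at
  δ = d_j (Gumbel-max sampling of the log weights);
* spike-and-slab: R by a *collapsed* update — δ is integrated out
  analytically so the marginal likelihood of each component is compared
  directly — then δ | R conjugate, P | R ~ Beta(1+R, 2−R).  The collapsed
  update avoids the mixing pathology of naive samplers at large τ, where
  the chain must otherwise wait for δ to wander near zero before the
  spike can be entered;
* rectified joint prior: random-walk Metropolis on the *latent
  unrectified* variables (Y_C, Y_B) with μ = min(0, Y); proposal sds
  0.25/0.35, giving acceptance rates near 0.35 on the shipped examples.
  Positive latent values carry flat likelihood (μ = 0), which is what
  makes the atom reachable;
* discrete joint grid: the posterior over cells is categorical with
  constant weights, so draws are independent.

Defaults mirror a conventional desk-scale run: 2 chains × 50,000
iterations, burn-in 20,000, thinning 2 (15,000 retained per chain); the
test suite uses reduced settings (typically 2 × 6,000, burn-in 1,000)
which keep Monte-Carlo error well inside the tested tolerances.  Thinning
applies after burn-in removal; chains are pooled for summaries.  Split-R̂
and bulk ESS (arviz) are attached to every run, with a warning — never a
silent failure — above R̂ = 1.01.

Every retained draw satisfies δ = μ_B − μ_C *exactly* in floating point:
the container recomputes δ from the stored μ_B and μ_C at construction
(for the (μ_C, δ) samplers μ_B := μ_C + δ is formed first, so the stored
δ can differ from the sampled one by an ulp — the identity wins, which is
why the discrete-prior δ draws are only ulp-equal to the grid values; the
category trace M carries the exact labels).

Summaries are posterior means, standard deviations, equal-tailed 95%
credible intervals (the conventional MCMC-summary choice; not HPD) and
sign probabilities P(· < 0).  The overall effect μ_A = π μ_B + (1−π) μ_C
is computed per draw for any population proportion π; it is exact for
collapsible effect measures and an approximation for hazard ratios.

## Elicitation

Beliefs are elicited as a discrete joint table: a marginal over candidate
μ_C values and conditionals for μ_B given each, multiplied into a joint
grid (probabilities renormalized with a warning if they miss 1 by more
than 1e-6).  Two continuous conversions:

* **Moment matching**: bivariate normal with exactly the grid's mean
  vector and covariance matrix.  (Whether "consistent with the grid"
  should mean moment matching or another criterion is a genuinely open
  choice; moment matching is assumed and reported as such.)
* **Rectified fit**: the axis is partitioned at breakpoints (default
  log 0.55 … log 0.95, six intervals, 36 rectangular regions).  Observed
  region probabilities O_i aggregate the grid cells; expected
  probabilities E_i multiply the marginal rectified-CDF interval masses
  (the atom at 0 falling in the interval containing 0 — the last,
  unbounded one under the default partition) by conditional interval
  masses evaluated at a representative μ_C per interval.  Representatives
  are the grid's values falling in the interval, averaged with weights
  proportional to their marginal probabilities when there are several
  (an unweighted average is available behind a flag; with the default
  six-value grid each interval holds exactly one value and the choice is
  moot).  An interval with no grid value falls back to its midpoint, with
  a log entry.  The five constants (a, b, c, d, e) minimize Σ(O_i − E_i)²
  by multistart Nelder-Mead (20 starts by default) from randomized
  perturbations of moment-based initial guesses, with b and d
  log-parameterized to stay positive.  A derivative-free simplex is used
  because the objective is non-smooth (atom terms and the max(·) in the
  conditional variance).

## Trial design

Expected events per subgroup analysis are `n_subgroup × ½ × rate` summed
over arms (½ from 1:1 stratified randomization); fractional counts are
carried as reals, never rounded.  Each log-HR variance is `4 / events`
(the standard approximation for a 1:1 randomized survival comparison).
The all-comer variance uses 4 / (total events) by default; the delta-method
alternative π²σ_B² + (1−π)²σ_C² is available behind a flag for sensitivity
analysis.  Predictive draws add `N(0, σ²)` noise to each posterior draw,
so Var(μ̂_new) = posterior Var(μ) + σ² by total variance.  Significance is
`Z < −1.96` (two-sided 5% with a directional claim, benefit = negative);
the critical value is configurable for hierarchical procedures, and no
multiplicity adjustment is imposed — the gated conditional power simply
conditions the predictive draws on a user-specified gate.

## Synthetic scenarios

`generate_scenario` draws replicate datasets from exactly the observation
model at chosen true effects — the same normal approximation the analysis
assumes, with the covariance treated as known.  It therefore validates
*internal* consistency (calibration of credible intervals under matched
priors, parameter recovery as variances shrink) and deliberately does not
emulate features of real data that the model itself ignores:
non-normality of small-sample log-HR estimates, uncertainty in the
variance estimates, non-proportional hazards, or patient-level structure.
Passing calibration tests show the Bayesian machinery is self-consistent,
not that the normal approximation holds for any particular trial.
Variances of exactly zero are floored at 1e-12 to keep noiseless
scenarios representable.

## Numerical choices and degenerate inputs

* z-multiplier exactly 1.96 at the 95% level (see above); `ci_lo = ci_hi`
  is rejected as a zero-variance interval.
* Σ must be non-singular for the likelihood; |cov| = √(var_B var_C) is a
  valid covariance for storage but rejected at density evaluation.
* Truncated-normal draws guard the uniform variate away from exactly 0 to
  avoid −∞ quantiles at extreme bounds.
* Spike-and-slab P is clipped to (1e-12, 1 − 1e-12) before the logit.
* Rectified conditional variance ≤ 0 yields −∞ log-posterior in the MH
  step (proposals into the degenerate region are rejected); with the
  shipped fitted constants the variance stays strictly positive over the
  support.
* `summarize` requires ≥ 1000 retained draws; an interval failing
  ci_lo ≤ mean ≤ ci_hi (possible under extreme multimodality) sets a
  `flagged` field rather than raising.
* Point-mass priors (sd = 0) are handled exactly in the conjugate path
  and by skipping the corresponding Gibbs update.

## Problem sizes

The shipped analyses are deliberately small: two estimates per dataset,
36 elicitation regions, 30,000 retained draws at default settings.  The
test suite runs the samplers at 2 × 6,000 iterations and the calibration
study at 500 replicates through the conjugate closed form; the
reproduction script runs the full default settings throughout and
completes in well under a minute on one CPU.

## Known limitations

* No patient-level modelling: Cov(μ̂_B, μ̂_C) cannot be estimated, only
  supplied.
* μ_A is a weighted-average approximation; hazard ratios are not
  collapsible, so it is not exactly the all-comer log HR.
* Exactly two subgroups; extending the prior menu to several (possibly
  overlapping) subgroups is non-trivial.
* The spike-and-slab posterior is sensitive to τ by construction; it is
  best used to gauge evidence for *any* interaction, rarely for
  estimation.
* No formal family-wise error control for sequential testing strategies;
  the design module reports predictive probabilities for user-specified
  gates only.
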