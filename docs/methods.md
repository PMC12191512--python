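# Methods

This note records the models implemented, the conventions adopted where
a definition is genuinely ambiguous, the numerical choices, and what
the simulation harnesses do and do not demonstrate.

## Evidence calculus

For a discrete prior/posterior pair on a common finite support the
relative belief ratio is the pointwise mass ratio; it is undefined
(flagged, not zero) where the prior puts no mass, and the constructor
rejects posterior mass appearing where the prior has none.  The
identity `Σ_ψ π(ψ)·RB(ψ|x) = 1` holds to machine precision and is
property-tested.

Direction of evidence uses the cut-off 1 with a neutrality tolerance:
`|RB − 1| ≤ 1e-9` counts as "no evidence either way".  Discrete exact
arithmetic is unaffected; continuous pipelines never hit 1 exactly, so
some tolerance is required, and 1e-9 is far below any content or
endpoint reported at display precision.  Region membership is strict
(`RB > 1`), and the relative belief estimate breaks ties toward the
smallest support index / leftmost grid point; both choices are
conventions, as the defining inequalities are silent about ties.

In the continuous case the RB function is either a closed-form density
ratio or a user-supplied callable (e.g. a weighted combination).  The
unit crossings are bracketed on a uniform grid (default 4001 points
spanning ±6 posterior standard deviations) and refined by bisection to
absolute tolerance 1e-9; plausible regions are reported as unions of
intervals (a single interval in every unimodal example).  Contents use
exact cdfs when available and adaptive quadrature otherwise.

## Pooling

The power-mean pool with exponent t interpolates between the pointwise
minimum (t = −∞), the weighted geometric mean (t = 0), the arithmetic
mixture (t = 1), and the pointwise maximum (t = +∞).  Zeros follow the
power-mean limits: for t = 0 the pool vanishes wherever any component
with positive weight vanishes; for t < 0 a zero component forces a
zero pool.  A pool that is identically zero (e.g. the geometric pool
of disjoint-support priors) raises rather than renormalizing garbage.
For t > 1 on a continuous grid the normalizing integral is checked for
finiteness and failure raises a specific error.  Normalizing constants
on grids use trapezoid quadrature at relative tolerance 1e-8.

Only the t = 1 pool is used for combining *evidence*.  The reason is
structural: every pooled RB is a constant multiple of the linear-pool
RB, so the estimate and the strength event are shared across t, but
only the linear pool preserves a consensus of evidence directions.
The geometric pool fails this as soon as one analyst is categorical
(prior probability 1 on a value): that analyst's RB is 1 — data cannot
move a categorical belief — yet the geometric pool forces the combined
RB to 1 even when every other analyst reports evidence against, which
the audit operation flags as a consensus violation.

The combined profile in the common-model case is computed as the
mixture ratio (mixture posterior over α-mixture prior).  This equals
the weighted component-RB sum wherever all components are defined —
the identity is tested, not assumed — and extends it to values that
some component prior misses but the mixture covers.

One bound often quoted for the combined plausible region required
correction.  The intersection of the component plausible regions is
always contained in the combined one (verified on all fixtures).  But
the combined posterior content of the combined region is the
weight-mixture of the *component contents of that same region*; it
need not lie between the component contents of their *own* regions,
and random search over small discrete fixtures produced explicit
counterexamples to the latter, superficially plausible, version.  The
tests assert the provable same-region form.

## Combination weights

In the common-model context the weight of base i is
`αᵢ mᵢ(x)/Σⱼ αⱼ mⱼ(x)`: the posterior probability of "analyst i" when
α is read as a prior over analysts.  Default α is uniform — absent
knowledge about the proposers, only the data should drive the relative
weighting.  Predictive values may be supplied on the log scale and are
then normalized by subtracting the maximum before exponentiating, so
large-sample weights cannot underflow.

When the sampling models differ (including prediction, where the
conditional models for the data given the future value differ across
priors), the weighted RB sum is retained but flagged: it is no longer
literally a posterior/prior ratio.  The mixture posterior is justified
by Jeffrey conditionalization and coincides with Bayesian model
averaging; combined continuous posteriors are always carried as
explicit mixtures, never re-fitted to a single family.

Differing models raise a comparability problem: a model can earn
weight merely by predicting features of the data that carry no
information about the quantity of interest.  Conditioning the
predictive on an ancillary statistic (the residual configuration in
location and regression models) removes that reward.  The declaration
that `x ↔ (L(x), A(x))` and that A is ancillary is the caller's
responsibility — ancillarity is not mechanically checkable — and the
module validates dimensions only.  With a finite ancillary partition
whose cell probabilities are parameter-free per model, pre-dividing
the weights by each model's multinomial ancillary pmf
(`αᵢ ∝ αᵢ*/fᵢ(counts)`) achieves the same end; the simulation harness
shows the adjusted weights converging to `αᵢ*·πᵢ(θ_true)` proportions
over the bases whose *conditional* structure contains the truth, while
the unadjusted weights degenerate against a model whose only defect is
its ancillary distribution.

## Model library

**Normal location.**  Known sampling variance σ₀², prior `N(μᵢ, τᵢ²)`:
posterior and prior predictive (`N(μᵢ, σ₀²/n + τᵢ²)` at the observed
mean) are closed form, cross-checked against quadrature.  Prediction
of a future `y ~ N(μ, σ₀²)` uses prior predictive `N(μᵢ, σ₀² + τᵢ²)`
and posterior predictive with variance *posterior variance + σ₀²* —
the variance of a future observation is the posterior uncertainty
about μ plus fresh sampling noise.  (An alternative bookkeeping that
adds τᵢ² instead of σ₀² is inconsistent with the prior-predictive
variance and with the reported interval contents; it is not used.)

**Heavy-tailed location.**  A Cauchy location model is matched to the
normal bases by rescaling: η₀ = σ₀/tan(0.1827π), so that σ₀ keeps a
comparable interpretation across families.  The constant is
implemented exactly in this form; note that reading the matching
condition as "(−σ₀, σ₀) holds probability 0.6827 under the scaled
Cauchy" would instead give tan(0.34135π) — the two disagree, the
package exposes `cauchy_eta0` so either can be substituted, and the
default keeps the form above.  The conditional predictive of the mean
given the residuals is a ratio of a 1-D to a 2-D integral, computed
with Gauss–Legendre panels over the location and adaptive quadrature
over the mean, relative tolerance 1e-6; running a normal family
through the same path reproduces the closed form to ~1e-14, which the
tests use as the oracle.

**Regression.**  Design rows `(1, xᵢ)` with the predictor centered and
scaled to unit norm (idempotent, tested); the response for the shipped
income/investment data (20 years of US per-capita series) is centered
on the raw scale by `income − 340 − 3·investment`, which brings it
near zero as the conjugate zero-mean prior expects.  Error families:
standard normal, or Student t_λ scaled by √((λ−2)/λ) so that σ² is
the error variance for every λ > 2.  With `b` the least-squares
coefficients, `s` the residual norm and `a = resid/s`, the conditional
density of `(b, s)` given `a` at fixed (β, σ) is the kernel
`s^{n−3} σ^{−n} Π f((b₁−β₁)/σ + (b₂−β₂)xᵢ/σ + s aᵢ/σ)`, whose
normalizing constant over (b, s) is free of (β, σ) by
translation/scale invariance.  The model weight integrates the kernel
against the prior by importance sampling from the normal-error
conjugate posterior (default 10⁵ draws; a seed is mandatory; effective
sample size below 100 raises), divides by the constant (closed form
for normal errors, a shared-draw ratio estimate otherwise), and
reports delta-method standard errors per weight.  The normal-error
conditional predictive is cross-checked against an independent 1-D
quadrature oracle to 2%.

Observed behavior on the shipped data: the normal-vs-t weights favor
the normal model increasingly as λ falls (≈0.51 at λ=100 up to ≈0.95
at λ=3 under equal prior weights).  The residual direction of this
data set has near-normal kurtosis, which caps how decisively any
conditional-predictive weighting can separate variance-matched t
errors from normal errors; a sharper separation would require
residual-direction kurtosis below the geometric minimum attainable
here, so substantially more extreme weights are not reproducible from
these inputs by this estimator.

**Elicitation.**  Given γ (virtual certainty), a bound m₀ on the
regression function over the standardized predictor range, and bounds
`s₁ < s₂` on the half-length of the γ-credible response interval:
τ₀ = m₀/(s₂ζ₀) with ζ₀² = 1 + max x², and (α₁, α₂) solve

    G(α₁, 1, α₂ q / s₁²) = (1+γ)/2,   G(α₁, 1, α₂ q / s₂²) = (1−γ)/2

by the stated iteration (outer bisection on α₁ — the residual of the
second equation is monotone decreasing in α₁ — with the inner gamma
quantile giving α₂), to 1e-6 on both equations.  The squared-threshold
constant q admits two readings that differ materially: the literal
square of the normal quantile `z²_{(1+γ)/2}` (6.635 at γ=0.99) or the
χ²₁ quantile at (1+γ)/2 (7.879).  Both are implemented; the χ² reading
is the default because it is the convention under which the
widely-circulated worked-example hyperparameters (α₁ ≈ 4.05,
α₂ ≈ 140.4 at γ=0.99, s₁=10, s₂=40) are the exact solution, and the
solver verifies its own equations on exit either way.

## Robustness and consistency harnesses

The Dirichlet sweep draws weight vectors from parameters
`1 + c·α₀` — the parameterization whose mode is exactly α₀ — reruns
the configured combination per draw, and reports the proportion of
draws whose conclusion (evidence direction at the hypothesized value)
matches the α₀ conclusion, with quartile summaries of estimates and
contents.  The concentration c is a required input with no endorsed
default: how tight a sweep is informative depends entirely on how the
weights were arrived at.

The consistency simulator works on finite categorical models, where
the sufficient statistic is the count vector and exact log-predictive
arithmetic is cheap at any sample size.  It tracks, along a strictly
increasing sample-size ladder, the data-updated (optionally
star-adjusted) weights, the combined RB and strength at a hypothesized
value, and the plausible region, against the theoretical limits:
strength → 1 at the true value and → 0 elsewhere, region → the truth
singleton, weights → prior-mass-at-truth proportions over the
correctly-specified bases.  Convergence assertions in the tests use
fixed seeds, n = 10⁴, and thresholds (0.9/0.1 for strength, 0.02 for
weights) chosen once; all outputs are pure functions of the
specification and the seed.

What the synthetic fixtures emulate — and what they do not: the
discrete fixtures exercise the exact algebra of the combination rules,
and the conjugate fixtures the continuous embodiment with known
ground truth; neither exhibits model misspecification beyond the
finite families studied, prior–data conflict (assumed checked and
absent upstream), nor the multi-dataset setting, which the package
deliberately refuses to handle (`combine_multi_dataset` raises).

## Known limitations

* Whether power means with 0 < t < 1 preserve consensus is open; the
  audit reports, it does not assume.  No case of an outright consensus
  *reversal* by any power mean has been observed in the randomized
  searches, consistent with the conjecture that none exists.
* Interest parameters are assumed scalar (or finite-label) throughout
  the continuous machinery; regression supports the two-column
  standardized design only.
* Combination across distinct data sets with distinct models is out of
  scope and raises `NotImplementedError`.
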