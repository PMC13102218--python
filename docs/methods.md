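# Methods

`grmsim` is a simulation engine for asking a design question that comes up
whenever a questionnaire or rating scale is calibrated with item response
theory: *how large a sample, how many items, and how many response
categories are needed for the graded response model (GRM) to recover its
parameters accurately?* The package simulates finite populations of ordinal
responses with known truth, re-estimates the model from samples, and
summarizes recovery over a (sample size `n`, item count `J`, category count
`K`) design grid.

## Generative model

Respondent *i* has a latent trait θ_i ~ N(0, 1). Item *j* has a
discrimination a_j ~ U(0.5, 2.5) and K−1 category locations b_j1 ≤ … ≤
b_j,K−1, drawn U(−2, 2) and sorted. Intercepts are constructed as

    d_jk = −D · a_j · b_jk,   D = 1.701.

The probability of responding in category k or above is logistic in θ with
slope and intercept (a1_j, d_jk); category probabilities are adjacent
differences of these boundary curves (Samejima's graded model).

**Slope-scaling convention.** There are two self-consistent ways to combine
the draws above with the response model, and they differ materially:

* *unrescaled* (default, `slope_rescaled=False`): the boundary logit is
  `a_j·θ + d_jk = a_j·(θ − D·b_jk)`. The slope enters the model exactly as
  drawn and D effectively stretches the thresholds to D·b ∈ (−3.4, 3.4).
  This is what the common simulation route in IRT software does when handed
  `(a, d)` pairs directly, and the recovery levels it produces match the
  reference results this package reproduces (mean discrimination RMSE near
  0.23 at n = 500, J = 10, K = 5).
* *rescaled* (`slope_rescaled=True`): the logit is `D·a_j·(θ − b_jk)`, so
  boundaries sit exactly at θ = b and D acts as a pure slope rescaling.
  Estimation errors on the classic a-scale are then smaller by roughly a
  factor of D (mean RMSE near 0.12 in the same cell).

Both conventions are implemented; the default is the unrescaled one because
it reproduces the benchmark recovery levels. Estimates are always reported
on the scale directly comparable with the generated a_j.

## Finite population and sampling

Each condition cell builds one fixed population: N_pop = ⌈n / 0.001⌉ latent
traits (the sampling fraction is exactly 0.001) and one item bank shared by
all replications. A replication draws n respondents *without replacement* —
which is what makes the finite-population correction of the θ-RMSE
meaningful — and generates fresh responses for the drawn respondents only.
Population-wide response matrices are never materialized: storage is
O(N_pop) for the trait pool plus O(n·J) per sample (about 12 MB at the
largest cell, n = 1500).

The "one population per condition" reading (rather than one per
replication) follows from samples having to share a common (θ, a, b)
structure; it makes every condition-level mean conditional on its single
random item bank. That bank effect is large for the discrimination RMSE:
across bank seeds at (J=10, K=5) we observed condition means ranging
roughly 0.19–0.29 at n = 500, and occasionally heavy-tailed values at
n = 1500 when a stretched threshold leaves an extreme category nearly
unobserved. Single-cell benchmark values should be interpreted with this
bank-level variability in mind.

## Seeding

Every random stream is a `numpy` `SeedSequence` keyed by
`(base_seed, n, J, K)` for the population and `(base_seed, n, J, K, rep)`
for replication `rep`. The default base seed is 123. This hierarchical
scheme is collision-resistant and makes results independent of execution
order, so parallel and serial grid runs are bit-identical.

## Estimation

The GRM is fitted by marginal maximum likelihood via EM, with the latent
density fixed at N(0, 1) for identification (matching the generating
prior; no mean/variance re-estimation).

* **Quadrature**: 61 equally spaced nodes on [−6, 6], weights proportional
  to the standard-normal density and renormalized. Dense enough that the
  discrete prior's variance is 1 to within 10⁻³ and EAP scores agree with a
  10,001-node grid to better than 10⁻³.
* **E-step**: each respondent's posterior mass over nodes under current
  parameters, accumulated into per-item expected category counts per node.
* **M-step**: per item, the expected complete-data log-likelihood is
  maximized over (log a1, d_1, log of the successive negative gaps of d) —
  a parametrization in which the intercepts are strictly descending (and
  the implied locations strictly ascending) *by construction*. Because the
  objective is separable across items, all J per-item problems are stacked
  into one L-BFGS-B call with analytic gradients; this is the same
  maximizer as J independent optimizations but costs one optimizer call
  per cycle. Boundary probabilities are clipped to [10⁻¹², 1 − 10⁻¹²]
  inside this objective so gradients stay finite when the line search
  probes extreme parameters.
* **Start values**: slopes at classic a = 1; intercepts from inverse-logits
  of the observed cumulative category proportions (clipped away from 0/1,
  forced strictly descending).
* **Bounds**: log a1 ∈ [log 10⁻³, log 10³]; |d_1| ≤ 30; gap sizes in
  [10⁻⁶, 60]. Intercepts beyond |d| = 30 indicate an effectively
  unobserved boundary; they are clipped and a warning recorded. Items with
  unobserved categories are still fitted with all K categories so the
  parameter dimension never changes across replications.
* **Convergence**: maximum absolute change over all (a1, d) parameters
  below 10⁻⁴, capped at 500 cycles; hitting the cap returns a model flagged
  `converged=False` rather than raising. The marginal log-likelihood is
  recorded every cycle and is nondecreasing (EM ascent), which the test
  suite checks on randomized instances.
* An item whose sampled responses are constant has an unidentified slope
  and raises a `DegenerateItemError` naming the item; a grid run records
  the replication as failed and continues.

**EAP scoring.** Latent traits are estimated by the posterior mean over the
same quadrature grid, with pattern likelihoods evaluated in log space so
posterior mass never underflows; the posterior SD is returned alongside.
EAP estimates are shrunken toward the prior mean, so their sample variance
is below that of the true traits on every replication.

## Metrics

Per replication: RMSE between true and estimated discriminations (root mean
square over the J items, on the classic a scale); the same for thetas over
the n sampled respondents; the standardized discrimination RMSE (divided by the
observed range of the estimates); the Pearson correlation between true and
EAP thetas; and finite-population-corrected versions. The FPC factors
default to the square-root forms √(J/(J−1)) and √(1 − n/N_pop) — the
conventional definitions, which keep corrected values on the RMSE scale —
with the raw-ratio variants behind `sqrt=False`. At the study's sampling
fraction of 0.001 the θ-FPC changes the RMSE only in the third decimal.

Condition-level aggregation: arithmetic means for all RMSE metrics;
correlations are averaged on the Fisher-z scale (tanh of the mean artanh)
and reported with a Cohen-style agreement band (> 0.70 high, 0.50–0.70
moderate — boundary values read as moderate — below 0.50 low). Failed
replications are counted and excluded from means; non-converged ones are
retained but flagged, to avoid survivorship bias.

The θ-RMSE reference point 0.30 used in reports corresponds to one error SD
under a centered-normal error model: P(−1 < Z < 1) ≈ 0.6827, i.e. about
68% of estimation errors within ±0.30.

The item-count saturation summary reports, per (n, K), the first J at which
the improvement of a chosen metric mean over the previous J drops below a
tolerance (default 0.01) — the "diminishing returns" point.

## What the generator does and does not emulate

The generator reproduces idealized calibration data: complete responses,
a unidimensional trait, locally independent items, uniform parameter
distributions and a correctly specified fitting model. Passing tests
therefore demonstrate *internal* recovery behavior of the estimator, not
robustness to the features of real scale data — multidimensionality,
skewed discrimination distributions clustered below 1, missing responses,
or local dependence — all of which tend to inflate error beyond the levels
simulated here.

## Problem sizes used for verification

The full reference design (440 cells × 100 replications) is available as
the default `StudyConfig`, but the shipped verification runs use reduced
replication counts chosen to keep a desk-scale run practical while leaving
Monte Carlo error well inside the tolerances being checked: R = 20 for
single-cell benchmark checks (R = 40 in the acceptance script's RMSE
cells), R = 10 for the multi-cell agreement-benchmark grid, and R = 8 for
the qualitative trend grid (n ∈ {500, 1500} × J ∈ {10, 30, 50} × K = 4).
A `desk` preset (corner subset of the grid, R = 20) ships for interactive
use.

## Known limitations

* Absolute RMSE levels depend on the slope-scaling convention (see above)
  and, per condition, on the realized item bank; single-cell comparisons
  across studies are only meaningful to within that variability.
* The discrimination-RMSE distribution is heavy-tailed in cells where
  stretched thresholds make extreme categories very rare; occasional
  replications contribute large slope errors, and means across R
  replications inherit that tail.
* No standard errors for item parameters, no alternative scorers (ML, WLE,
  MAP), no multidimensional or partial-credit variants, no missing-data
  handling.
* The observed Fisher-mean correlation between true and EAP thetas falls
  well below 0.98 in low-information corners (e.g. about 0.78 at n = 500,
  J = 5, K = 4 under the default convention): with five items the posterior
  is simply too diffuse for near-perfect ordinal agreement, although the
  0.70 "high agreement" benchmark is still cleared.
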