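# Methods

## Model

A two-tier item factor model with M primary dimensions η ~ N(μ, Σ)
(correlations allowed) and N specific dimensions ξ_n, mutually
independent of each other and of η, each N(mean, var) with the standard
normal as default. Item i in cluster n responds through the logistic
item response function T_i(1 | η, ξ_n) = logistic(c_i + a_i⁰·η + a_iⁿ ξ_n);
an item may instead load on no specific dimension (cluster 0), in which
case its response depends on η only. Item parameters are treated as
known and fixed, as in operational scoring after a calibration study;
propagating calibration uncertainty (e.g., by multiple imputation) is
out of scope. Items are dichotomous; the polytomous "pseudo-items" that
arise when clusters are convolved are handled natively, but polytomous
*source* items are not.

## Quadrature

All integrals use rectangular quadrature: Q equally spaced points per
dimension, weights proportional to the prior density ordinate at each
point and normalized to sum to one. For M ≥ 2 the grid is the direct
product of the per-dimension point sets and the weights are normalized
multivariate-normal ordinates, so a correlated prior is handled without
any factorization assumption. Defaults: Q = 49 on [−6, 6] per dimension,
a range that covers ±6 prior SD for standard-normal priors; both are
configurable, and the six-item demonstration uses Q = 5 on [−2, 2] only
because the published hand-worked tables do. Quadrature moments on the
demonstration grid agree with a Q = 201 re-integration to about 5e−3,
which is the scale of discretization error users should expect from the
coarse grid; at Q = 49 the error is far below reporting precision.

## Recursions and numerical behavior

Stage I initializes the within-cluster table with the first item's two
response probabilities and folds in each further item with the standard
two-term recursion; Stage II convolves cluster tables (each a polytomous
pseudo-item with I_n + 1 categories). Rest-score likelihoods for focal
cluster n reuse the same convolution with cluster n omitted. Both the
(η, ξ_n)-conditioned and the marginalized table are retained per
cluster, because the combination posteriors need the former.

Accumulation is in plain linear arithmetic. No log-scaling is needed:
every table is a conditional probability distribution over a partition
of the response space, so its values sum to exactly one at each grid
node after every step — the table as a whole cannot underflow, and an
individual entry that underflows to zero is genuinely negligible
(≲ 1e−300). This holds at any test length.

Combination posteriors place the unnormalized product
P_n(s_n | η, ξ_n) · R_n(s₍ₙ₎ | η) · W_n(ξ_n) · W(η) on the
(η, ξ_n) product grid; its sum is p(s_n, s₍ₙ₎) and all moments (μ₀, μ_n,
σ₀₀, σ₀ₙ, σₙₙ) are computed from the normalized discrete posterior —
never from the normal approximation, which is provided only as a
downstream convenience for band and region probabilities. A combination
with numerically zero probability keeps its row with p = 0 and NaN
moments so table shapes stay predictable.

## Applications

**Region classification.** The probability of each achievement region is
the marginal-posterior mass between consecutive cut scores. Two modes:
(default) summing the quadrature marginal's weights, with a grid node
assigned to the region containing it; or closed-form normal CDF
differences on the normal approximation. With a fine grid the two agree
to about the node spacing times the marginal density at the cut; on the
49-point grid the normal mode is smoother near a cut that falls between
nodes, and the published two-band example is reproduced in that mode.

**Conditional percentiles.** From the combination probability table,
percentile of score `a` on one side given a fixed score on the other.
Three conventions are exposed: P(≤ a) (default, so the maximum score
maps to 100), P(< a) (`rule="lt"`, percent scoring strictly below — the
reading under which the two-band example's printed percentile is
recovered), and the midpoint rule. The choice matters by the conditional
mass at `a` itself, here several percentile points; reports should state
the convention.

**Subscore screening.** The specific-dimension estimate μ_n of each
combination is regressed on the primary estimate μ₀, weighted by
p(s_n, s₍ₙ₎) (weights scaled to sum to the number of combinations). The
prediction band at level ℓ is μ̂(x) ± z₍(1+ℓ)/2₎ · √(s²(1 + h(x))) with
s² the weighted residual variance (df = n − 2) and h(x) the WLS leverage
of a new unit-weight point; a normal rather than t quantile, consistent
with the normal posterior approximation used for the volumes. Each
combination's volume proportion is the mass of its bivariate normal
approximation between the band lines, integrated by a midpoint rule on a
201 × 201 box spanning ±6 posterior SDs (deterministic; agrees with
Monte Carlo to ~1e−3). Small proportions flag combinations whose
subscore is poorly predicted by the overall score and hence worth
reporting.

**HDR aberrance detection.** Combination probabilities are sorted in
descending order (ties broken lexicographically by (s_n, s₍ₙ₎) for
deterministic output) and accumulated until coverage reaches α; the
crossing combination is included and nothing after it, making the region
a minimal top-probability set — so removing its last member drops
coverage below α, and HDR(α₁) ⊆ HDR(α₂) for α₁ < α₂. Combinations
outside HDR(.95)/HDR(.99) are flagged tiers for follow-up.

## Synthetic model generator

`synth_model` draws item parameters uniformly: slopes in [0.5, 2.5]
(positive, keeping response functions monotone and spanning the
magnitudes of the built-in calibrated sets), intercepts in [−2, 2], with
a seeded generator for reproducibility. It emulates a calibrated
parameter table only — not response data, raters, missingness, local
dependence beyond the cluster structure, or parameter uncertainty — so
tests passing on synthetic models certify the arithmetic of the
recursions and posteriors, not the fit of any real assessment.

## Verification strategy

The recursion path is checked against an independent brute-force oracle
that enumerates all 2^I response patterns, integrates each pattern's
likelihood over the same grids, and groups by score combination;
agreement is at 1e−10 in probabilities and 1e−8 in moments for seeded
random models up to 12 items. Structural invariants (tables summing to
one at every node, order invariance, the decomposition
p(s) = Σ p(s_n, s₍ₙ₎) over pairs with s_n + s₍ₙ₎ = s, HDR
nesting/minimality, percentile monotonicity) run under property-based
testing. The six-item demonstration tables and the two-band application
numbers are asserted at the precision they are reported at.

## Known limitations

* The two-band application's upper-band region probabilities differ from
  the published ones by up to .03: the printed values imply an
  upper-band posterior SD of ≈ .24 for combination (13, 18), whereas the
  printed item and population parameters yield .206 under every
  convention implemented here. The lower-band regions, the score-13
  population share, and the conditional percentile all reproduce.
* No weighted or non-integer item scores; no missing-data handling; no
  3PL/guessing parameters; no parameter estimation.
* Rectangular quadrature needs the grid to cover the posterior bulk: for
  extreme score combinations under long tests, widen the range before
  increasing Q.
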