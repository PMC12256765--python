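# Methods

## Model

`hnbseq` fits, per gene, a hierarchical count model in which a sample's
exon counts are conditionally independent Poisson draws whose common
multiplicative part combines a known exposure, fixed effects, a gamma
frailty and lognormal random effects:

    y_isj | γ_is, b_i, b_is ~ Poisson( T_isj γ_is e^{x_is'β + b_i + b_is} )
    γ_is ~ Gamma(φ, 1/φ),   b_i ~ N(0, σ_I²),   b_is ~ N(0, σ_S²)

Key structural assumptions:

- **One frailty per sample, shared across exons.**  Integrating γ out
  yields a multivariate negative-binomial (MVNB) joint pmf for the
  sample's count vector and is the source of within-sample correlation.
  A per-exon frailty would make exon counts conditionally independent NB
  and destroy that correlation; the simulator therefore also draws one
  γ per sample.
- **Sample-level covariates.**  All exons of a sample share one covariate
  vector x (e.g. visit indicators).  `GeneData` rejects covariates that
  vary within a sample rather than silently averaging them.  A useful
  consequence: the linear predictor is constant across a sample's exons,
  so the pmf depends on the data only through per-sample totals — the
  likelihood code exploits this.
- **Exposure as an offset.**  T = exon length × raw library size enters
  the rate linearly.  Normalization alternatives (TMM, median-of-ratios)
  are accepted only as precomputed library-size substitutes; the package
  does not estimate normalization factors.
- The gamma frailty uses shape = φ, scale = 1/φ (mean 1, variance 1/φ);
  the NB "size" equals φ.  Some software uses the reciprocal convention —
  comparisons should check this first.

The MVNB pmf is computed entirely in log space via log-gamma functions
(counts in real data reach 10⁴).  The normalization constant treats the
product of count factorials exon-wise (Σ_j log y_j!), the only reading
under which the pmf sums to one — verified by exhaustive enumeration in
the tests.

Marginal moments: E = T e^{x'β} e^{v/2} and
Var = E{1 + e^v(1/φ + 1 − e^{−v})E}, with v the total normal-effect
variance (σ² or σ_I²+σ_S²).  Because the moment and correlation formulas
depend on the normal effects only through v, the two- and three-level
calculators coincide exactly whenever σ² = σ_I² + σ_S² — an identity the
test suite asserts and which makes two-level fits of clustered data
interpretable: the single σ² absorbs the sum of both variances.

## Likelihood and quadrature

The marginal likelihood factorizes over clusters: each sample contributes
log ∫ P_MVNB(y_s | b) N(b; 0, σ²) db in the two-level model; each
individual contributes an outer integral over b_i of the product of inner
per-sample integrals over b_is in the three-level model.  All integrals
are one-dimensional.

Quadrature rules use the probabilists' standardization (nodes/weights
against the standard normal kernel; weights sum to 1), eliminating √π
bookkeeping.  Adaptive rules recentre at the integrand's mode b* and
rescale by (−h''(b*))^{−1/2}; a one-node adaptive rule **is** the Laplace
approximation, and the implementation makes that an exact code-path
identity rather than an approximation.

Numerical choices:

- **Mode search.**  The per-sample log-integrand is strictly log-concave
  in b; the production path uses safeguarded Newton with *analytic*
  first/second derivatives of the simplified (totals-based) pmf,
  vectorized across samples.  The generic `adapt_rule`, which accepts
  arbitrary callables, uses central numeric differences with step
  1e-3·max(1, |b|): a much smaller step makes the second difference
  cancellation-noise-bound (~ε/step²) and visibly corrupts the Laplace
  scale, while truncation error at 1e-3 is negligible for these smooth
  kernels.  Newton tolerance 1e-8 on |h'|, at most 50 iterations,
  step-halving safeguard; if no point of negative curvature is found the
  rule falls back, flagged, to the start point with a caller-supplied
  scale.
- **Node count.**  Default 10 (configurable 1–75).  On data of this
  design the log-likelihood changes by <1e-4 between 10 and 75 nodes, and
  fitted parameters by <1e-3, so extra nodes buy runtime, not accuracy.
  Strongly skewed kernels are the exception: the Poisson-loglink test
  kernel needs ~50 nodes for 1e-8 absolute accuracy.
- **Nested adaptivity (three-level).**  Inner integrals are evaluated by
  their own adaptive rules at every outer evaluation point; the outer
  mode/curvature are found numerically on that profile log-integrand.
  This keeps everything 1-D at the cost of recomputing inner rules per
  outer node — correctness over speed, and the three-level likelihood is
  only ever evaluated per gene, not per genome.
- **Degenerate SDs.**  σ = 0 (or σ_I = 0) is handled as the exact point
  mass / exact collapse to the two-level model, not as an ε floor:
  boundary maxima occur in real genes and an ε floor would bias them.
- All node sums use log-sum-exp; the likelihood is finite for any
  admissible parameters.

## Estimation

Working parameters are β (unconstrained) and log φ, log σ (log σ_I),
maximized by L-BFGS-B with central-difference ('3-point') numeric
gradients, gradient tolerance 1e-6, relative f tolerance 5e-15, at most
500 iterations, within generous box bounds.  The unusually tight f
tolerance is deliberate: |loglik| is O(10³–10⁴), and the optimizer would
otherwise terminate on relative f-change while still ~1e-4 away from the
optimum along nearly flat variance-parameter ridges, which is exactly
where reproducibility across quadrature settings is needed.  A
line-search abort at the precision floor is still classified as converged
when the projected gradient is negligible (<1e-3).

Starting values: β from a Poisson log-linear GLM with offset log T (≤25
IRLS iterations); φ by matching the GLM's Pearson overdispersion to the
marginal variance formula at the σ start, clipped to [0.01, 100]; SDs
start at 0.3.  An optional 3-start strategy (σ ∈ {0.1, 0.3, 1.0}) keeps
the best likelihood; in testing it never improved on the single start,
but optimizers for this ridge-shaped likelihood can in principle land in
different local optima.

Standard errors come from inverting the central-difference observed
information (step 1e-3·max(1, |θ|)) at the optimum; SEs for φ and the SDs
are delta-method transforms to the natural scale.  Fits are classified
`converged`, `non_convergence`, `vcov_non_estimable` or
`vcov_not_positive_definite` (eigenvalue threshold 1e-10 × largest);
failures are recorded statuses, never exceptions, so batches continue.

**Boundary handling.**  An SD whose optimum lies below 1e-3 on the
natural scale is reported as exactly 0 with SE 0 and is profiled out of
the information matrix.  The likelihood is flat in a variance component
at the boundary, so including it would flag every such fit as
non-positive-definite even though the remaining parameters are perfectly
well determined.  The reported log-likelihood is always re-evaluated at
the reported (possibly zeroed) estimates.

**Identifiability caveat.**  γ and e^{b} are both sample-level
multiplicative effects; φ and σ are separated only by the *shape* of the
mixing distribution.  At the default study size (~100 samples) their
joint likelihood has a long curved ridge: σ̂ piles at 0 in roughly a
third of replicates while φ̂ compensates, so σ̂ is strongly
right-skewed and its *mean* underestimates σ even though σ̂² is close to
unbiased and both estimators are consistent (verified at 5× and 15× the
design).  Single-gene variance components should be read with this in
mind; β estimates are essentially unaffected.

## Inference

Wald statistics W = (Cβ̂)'(C V C')⁻¹(Cβ̂) with the β block of the
observed-information covariance, referred to χ² with rank(C) degrees of
freedom: 3 for the joint visit test (H0123), 1 for the single-visit tests
(H01, H03).  No small-sample correction is applied; at the default design
the 3-df test runs slightly liberal (~7% empirical at nominal 5% in the
calibration test).  Non-converged fits are refused — recorded as missing,
never as p = 1.  BH adjustment runs per hypothesis family across genes;
genes with failed fits are excluded from the test count m by default,
with an option to keep them in m as intended-but-missing tests.

## Simulator

`simulate_gene` draws from the exact generative hierarchy at the
defaults of the motivating longitudinal study: 29 patients × 3 visits +
13 single-sample controls, 11 exons with lengths log-uniform on
[76, 1705] nt, library sizes uniform on [1.7e6, 3.5e6] reads, visit
indicator covariates (controls all zero), optional random thinning of
patient samples.  A root seed spawns independent substreams per gene;
the individual-level normals are always drawn and scaled by σ_I (zero in
the two-level model), so the two hierarchies produce bitwise-identical
data at σ_I = 0 and the same seed.

What it does *not* emulate: read-level sequencing noise, mapping bias,
exon-length-dependent coverage profiles beyond the exposure term, or
between-gene dependence.  Passing recovery/calibration tests on this
simulator therefore validates the estimator under the model's own
assumptions — not robustness to their violation on real data.

Where no study value exists, per-gene parameters for multi-gene datasets
default to φ log-uniform on [0.1, 10], σ uniform on [0, 0.6] (σ_I uniform
on [0, 0.4] for three-level data), baseline β0 = −15.4, and non-null
genes draw visit effects iid N(0, 0.75²) — choices documented here as the
package's own.

## Problem sizes used in the checks

The validation suite uses 50 replicate genes for parameter recovery, 500
for Wald calibration, 5 for quadrature-point stability, 100 random small
instances for the pmf oracle, and 10⁵–10⁶ draws for simulator moment
checks — sizes at which Monte-Carlo bands are tight enough to be
informative while the whole suite stays desk-scale.

## Known limitations

- No crossed or >2-level normal random effects, random slopes,
  zero-inflation, or alternative frailty distributions.
- Numeric (not automatic) differentiation throughout.
- The Wald/χ² inference is asymptotic; for small designs a bootstrap
  would be preferable and is out of scope.
- Exon/gene identifiers are opaque strings; no genomic coordinates are
  parsed.
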