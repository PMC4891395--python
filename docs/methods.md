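# Methods

## Model and reduced likelihood

The data model is a bivariate normal with five parameters: the two means,
the two variances, and the correlation ρ, the only parameter of interest.
The location/scale parameters are removed analytically, leaving the exact
sampling density of the sample correlation r given (ρ, n):

    p(r | ρ, n) = (n−2) Γ(n−1) / (√(2π) Γ(n−½))
                  · (1−ρ²)^{(n−1)/2} (1−r²)^{(n−4)/2} (1−ρr)^{−(n−3/2)}
                  · ₂F₁(½, ½; n−½; (1+ρr)/2)

All hypothesis tests consume the data only through (n, r). Two remarks on
this choice:

* Alternative reductions — integrating the nuisance parameters under
  reference priors yields a ρ-kernel with an even/odd pair of
  hypergeometric terms, and dropping the slowly varying ₂F₁ factor gives
  the classical large-n approximation. We verified numerically that all
  three kernels produce Bayes factors identical to ~0.1% for n ≥ ~40, so
  the exact sampling density is used as primary and the approximation is
  shipped only as a labelled cross-check
  (`likelihood.log_r_density_jeffreys_approx`).
* The ₂F₁ argument (1+ρr)/2 lies in (0, 1), where scipy's implementation
  is convergent (c − a − b = n − 3/2 > 0); evaluation is in log space, so
  the density is stable for every n and |ρ|, |r| < 1 encountered.

Minimum n is 4 (integrability of the (1−r²) exponent). Summaries with
n < 10 trigger a warning that the Bayes factor is prior-dominated. |r| = 1
is rejected, not clamped: every downstream integral degenerates there.

## Priors and tests

* Default two-sided: H₁: ρ ~ U(−1, 1). BF₀₁ = p(r|0,n) / ∫ p(r|ρ,n)·½ dρ.
* One-sided: H₊: ρ ~ U(0, 1); same construction on the half interval.
  For symmetric priors a sign restriction can favour the alternative at
  most two-fold (BF₀₊ ≥ BF₀₁/2), asserted as a permanent property test.
* Sensitivity: ρ′ = (ρ+1)/2 ~ beta(α, α) with width γ = 1/α ∈ (0, 1].
  γ = 1 reproduces the uniform default; as γ → 0 the alternative collapses
  onto the null and log BF₀₁ → 0. The user-facing γ range keeps α ≥ 1, so
  no endpoint singularity arises; α < 1 is accepted by the class and its
  truncation masses are integrated under a ρ = sin(θ) change of variable.
* Interval null: H₀′: ρ ~ U(−c, c) against the uniform alternative; the
  Bayes factor is the ratio of the two marginal likelihoods. With
  c = 0.01 it is numerically indistinguishable from the point-null test
  (|Δ log BF| < 0.05 on the packaged fixtures), which is why the point
  null is a harmless mathematical convenience.
* Replication: Hᵣ: ρ ~ posterior of the original study. The prior density
  is evaluated analytically as base-prior × reduced likelihood divided by
  the base marginal likelihood of the original study — exact, rather than
  an interpolated grid, which we found strictly dominates a tabulated
  representation in both accuracy and simplicity. The base prior defaults
  to U(−1, 1) and is configurable (e.g. one-sided); with the packaged
  originals the one-sided base moves results by well under 5% because the
  original posteriors carry almost no mass below 0.
* Sequential updating: BF(E1,E2) = BF(E1) × BF(E2|E1), the second factor
  integrating the second study's likelihood over the first study's
  posterior. At summary level this is defined on the joint density of the
  two r statistics given a shared ρ (independent studies); pooling raw
  data would differ infinitesimally, but raw data are not part of the
  summary interface. The chain-rule identity is verified to 1e−6
  relative. The *naive* product of unconditional Bayes factors uses the
  prior once per study and overstates the evidence — the pooled fixtures
  demonstrate a near two-order-of-magnitude discrepancy.

## Quadrature and numerical policy

Marginal likelihoods are computed by adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, requested relative tolerance 1e−10, break points
at the likelihood mode r and, for replication priors, the original r).
Integrands are evaluated in log space and shifted by their maximum over
the break-point set before exponentiation. The achieved relative error is
propagated into every `BayesFactorResult.numeric_error`; a warning fires
above 1e−6. Bayes factors beyond 1e4 carry a warning that input rounding,
not numerics, limits their precision (see below).

Posteriors are tabulated on a deterministic grid of 4001 nodes spaced
uniformly in arctanh(ρ) (denser near ±1), with ρ = 0 forced to be a node
so the Savage–Dickey height needs no interpolation. Trapezoid
normalization at this size is within 1e−6 of exact on all fixtures, and
doubling the grid moves the height at zero by < 1e−4 relative. Credible
intervals are central (equal-tailed), by linear inversion of the
trapezoid CDF after collapsing zero-mass flat stretches; highest-density
intervals are a possible extension but were rejected for determinism and
simplicity. The Savage–Dickey route (grid) and the marginal-likelihood
route (adaptive quadrature) share no normalization code; their agreement
within 1% on every fixture is asserted permanently.

## Synthetic data generator

`simulate` draws (x, y) from the bivariate normal via the Cholesky factor
of the 2×2 correlation matrix; defaults are means 0 and scales 1 because
r — and therefore every Bayes factor — is invariant under affine
rescaling (asserted by test). Streams are `numpy.random.default_rng([seed,
rep])`, one generator per replicate, so replicates are order-independent
and bit-reproducible. The generator emulates exactly the model the tests
assume; it does not emulate non-normal margins, outliers, nonlinear
(e.g. U-shaped) relations, or measurement-level discreteness of rating
scales, so passing calibration here demonstrates correctness of the
machinery under the model, not robustness to model violation on real
data.

Calibration experiments and their sizes (chosen as the package's own
defaults): evidence accumulation under the null uses 200 replicates at
n ∈ {50, 200, 800}; credible-interval coverage uses 500 replicates at
n = 100, ρ = 0.3, asserting empirical coverage of the 95% interval within
[0.93, 0.97]; distributional agreement of the generator with the reduced
likelihood uses 1e5 replicates at n = 20, ρ = 0.5 (Kolmogorov distance
< 0.01); posterior-mean recovery uses 100 replicates at n = 500.

## Input precision and reference values

The packaged fixtures carry r rounded to two decimals, while the
reference analysis that produced the accompanying printed Bayes factors
ran on raw data. The log Bayes factor is steep in r at large n
(d log BF/dr ≈ n·r near small r), so a half-ulp (0.005) perturbation of a
printed r moves some factors by 5–15%. We verified that every printed
value is recovered exactly for an r inside its printed rounding band
(e.g. the pooled n = 1920 row at r* = 0.0133, which rounds to the printed
0.01). The regression suite therefore asserts the envelope property —
each printed value lies within the range our implementation produces as
r sweeps its rounding band — while the end-to-end reproduction tests
compare at an input-precision ladder: 5% relative for BFs below 100, 15%
in [100, 1e4], 35% above 1e4 (extreme tail ratios are the most
rounding-sensitive). A handful of printed values remain outside even
this ladder when recomputed from rounded summaries; the corresponding
tests are left failing deliberately rather than loosened, since they
measure input precision, not implementation error.

## Known limitations

* Summaries only: analyses beyond (n, r) (partial correlations, rank
  correlations, unequal-tailed priors beta(a, b) with a ≠ b) are out of
  scope.
* Replication Bayes factors above ~1e4 are reported but flagged: their
  exact magnitude is not meaningful at two-decimal input precision.
* Posterior quantities are deterministic quadrature/tabulation; there is
  no sampling backend, hence no Monte-Carlo error but also no direct
  extension to hierarchical variants.
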