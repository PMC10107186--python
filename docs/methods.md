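# Methods

`nichemix` quantifies individual diet specialisation in three linked
coordinate systems — isotope space, prey-proportion space, and macronutrient
space — for consumers sampled through serially accreted, metabolically inert
tissue (the motivating system is juvenile white-shark tooth files: 12
individuals, 5 sequential teeth each, three isotopes d13C/d15N/d34S, six
pooled prey sources). This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Collagen quality control

Atomic C:N in 3.0–3.3 passes; 2.9–3.0 is retained uncorrected (the lower
bound is conservative); below 2.9 is excluded; above 3.3 indicates residual
lipid or non-collagenous protein that biases d13C. When the sample set shows
a significantly negative OLS slope of d13C on C:N (two-sided p < 0.05),
values above the 3.3 threshold are de-trended with an anchored linear
offset, `d13C − slope·(C:N − 3.3)`, so the correction vanishes at the
threshold and grows with the C:N excess. The published scaled-offset
equations in the tooth-collagen literature are not uniquely specified; the
anchored-linear form is the simplest member of that family and is isolated
behind `correct_d13c` so an alternative can be swapped in. With fewer than
three usable samples no relationship can be fitted and the correction is
skipped.

## Isotope-space variance partitioning

The trivariate random-intercept model

    y_it = mu + b_i + e_it,  b_i ~ N3(0, G),  e_it ~ N3(0, R)

is fitted by Gibbs sampling with conjugate updates (multivariate-normal
conditionals for `mu` and the `b_i`; inverse-Wishart conditionals for G and
R). G is the between-individual component (BIC), R the within-individual
component (WIC), and TNW = G + R; the trace ratio WIC:TNW falls as
individual specialisation rises. Point estimates are posterior means.

**Priors.** `mu` is flat; G and R carry inverse-Wishart(nu, 0.01·I) priors.
The default `nu = 2.01` sits just above the properness bound (p − 1 = 2).
This matters at the study's size: with only ~a dozen individuals the
between-individual likelihood carries ~11 degrees of freedom per matrix,
and heavier inverse-Wishart priors (e.g. nu = p + 1) concentrate enough
mass near |G| = 0 to bias the posterior-mean WIC:TNW upward by 0.05–0.15 at
true ratios of 0.5–0.8 — verified by comparison against a brute-force
collapsed-posterior grid in one dimension and against the method-of-moments
decomposition in three. With the near-bound default, the mean absolute
recovery error over 45 simulated 12×5 datasets at true ratios
{0.2, 0.5, 0.8} is ≈ 0.065. `nu` remains a parameter for sensitivity
analysis; the bias direction under heavier priors is asserted in the tests.

**Convergence.** The Gelman–Rubin potential-scale-reduction statistic is
computed across chains on the trace of G and R (and, in the mixing model,
on the population's log-ratio coordinates). The raw statistic is floored at
1.0; values above ~1.1 indicate non-convergence.

**Per-individual indices.** The s-index is trace(cov of the individual's
samples)/trace(TNW). The o-index is the Monte-Carlo overlap volume between
the individual's standard ellipsoid and the population (TNW) ellipsoid, as
a fraction of the population ellipsoid's volume (default 1e5 points sampled
uniformly inside the population ellipsoid via a uniform-ball draw and an
affine map). "Standard ellipsoid" means the Mahalanobis ball containing a
fixed coverage fraction of a trivariate normal; the two-dimensional
standard-ellipse convention (1-sigma, 39.35% coverage) has no unique 3-D
analogue, so coverage is an explicit parameter with default 0.40, giving
squared radius chi2.ppf(0.40, 3) ≈ 1.869.

## Concentration-dependent mixing model

For diet proportions p on the K-simplex, the expected signature on isotope
axis e is the concentration-weighted mixture

    w_k = p_k c_ke / Σ_j p_j c_je,
    mean_e = Σ_k w_k (s_ke + Δ_e),   var_e = Σ_k w_k² (σ_ke² + σ_Δe²),

with c_ke the source's mass concentration of the element on axis e and
Δ_e ± σ_Δe the trophic enrichment factor (TEF). Concentrations can be
measured weight-% or derived from atomic C:N and C:S ratios anchored at a
carbon mass fraction (default 0.45, typical of dried tissue). For cetacean
sources consumed whole, muscle and blubber are combined with body-mass ×
element-concentration weights (default mass fractions: midpoints of the
published 26–37% muscle and 21–26% blubber ranges, renormalised); d34S
comes from muscle alone when blubber carries no measurable sulfur.

**Hierarchy.** Population proportions carry a Dirichlet(1,…,1) prior
(uniform on the simplex, expressed in isometric log-ratio (ILR) coordinates
with the exact Jacobian). Individual diets deviate from the population in
ILR space by normal random effects with per-coordinate half-Cauchy(0,1)
scales; each isotope axis adds a residual variance with a half-Cauchy(0,1)
prior on the SD. The ILR basis is a fixed Helmert-type contrast in source
order; results are basis-independent because the normal random-effect
family is rotation-invariant in ILR space.

**Sampling** is adaptive Metropolis-within-Gibbs: a vector random-walk for
the population coordinates, independent per-individual row proposals
(vectorised across individuals, which are conditionally independent),
and coordinate-wise updates for the log scales; proposal scales adapt
toward 25%/44% acceptance during burn-in only. Desk default: 3 chains ×
50,000 iterations, 25,000 burn-in, thin 10. The published "extreme"
setting (3 × 3,000,000 / 1,500,000 / 500 → 9,000 retained vectors) is
available as a preset. Draws are paired across entities by chain and
iteration, as the similarity indices require.

**Mixing-region check.** Whether a consumer is attainable as a mixture is
assessed by simulation: each iteration redraws every TEF-adjusted source
mean from its combined source + TEF uncertainty and tests membership of
the consumer in the convex hull of the drawn points, via a feasibility
linear program over the combination weights with per-axis slack (1e-8 for
full-dimensional hulls; 0.1 permil when K ≤ 3 points cannot span 3-D).
Membership at the 95% level means the inside fraction is at least 0.05.

**Indices.** Individual-vs-population contrasts use (a) the per-source
probability that the individual's proportion is below the population's
across paired draws, with ties counted 0.5 and flags outside (0.05, 0.95);
and (b) the c-index, the mean paired cosine similarity of proportion
vectors, in [0, 1].

## Nutrient space

Each posterior diet vector is pushed through fixed per-source macronutrient
compositions (%protein, %lipid, %water wet mass, renormalised to close at
100; carbohydrate is negligible in marine prey): %Y_diet = Σ_t %Y_t · p_t.
Uncertainty therefore propagates only through the proportion posterior;
compositions are literature means treated as constants (a per-source SD
hook exists, off by default). The P:L ratio is summarised per draw, not as
a ratio of means. Right-angled mixture-triangle coordinates put %P on x,
%L on y, with %W implicit toward the origin.

Because attainable diet compositions are confined to the convex hull of
the source compositions, raw cosine similarities are compressed toward 1;
the nutritional c-index is rescaled as (raw − c_min)/(1 − c_min) where
c_min is the minimum cosine similarity between attainable compositions.
Cosine similarity is quasi-concave along segments within the positive
orthant, so the minimum over hull × hull is attained at a vertex pair and
found by exhaustive pair search (verified against a random-grid oracle in
the tests). If all sources share one composition, the index is defined
as 1 (no nutritional contrast is possible).

## Cross-cutting statistics

Effects of sex and size class on any index in (0, 1) are modelled by
maximum-likelihood beta regression (logit mean link, constant precision;
statsmodels' `BetaModel` backs the fit, checked against an independent
numerical ML oracle). Boundary responses are compressed with
(y(n−1)+0.5)/n. Model selection over {null, sex, size, sex+size} uses
AICc with the precision parameter counted in k. Source-grouping decisions
are screened with pairwise two-group PERMANOVA: per pair, axes are
z-scored over the pooled samples, the pseudo-F comes from the
distance-based sum-of-squares decomposition, the p-value is
(1 + #{F_perm ≥ F_obs})/(n_perm + 1) under label permutation (default
9,999), and Benjamini–Hochberg correction is applied across pairs.
Per-pair (rather than global) normalisation is the default reading of
"normalised Euclidean distances"; the statistic is cross-checked against
scikit-bio's PERMANOVA in the tests.

## Synthetic data

`source_fixture()` carries the six published source groups (isotope
means/SDs, sample sizes, atomic ratios → concentrations anchored at 45% C)
and `tef_scenarios()` the three TEF candidates; TEF_C (4.4±1.0, 0.9±0.7,
0.0±0.5) is the default for simulation, and TEF_A is excluded from
defaults because most consumers fall outside its 95% mixing region. The
per-group macronutrient compositions are synthetic stand-ins (the source
publications' supplementary values are not redistributed here), chosen to
respect the published attainable ranges (42.6–82.4 %W, 12.3–20.6 %P,
1.3–45.0 %L) and to yield a population intake near 71/19/10 with P:L ≈ 1.9
under the default population diet.

`simulate_dataset` draws individual diets around the published population
composition — ILR-normal by default (matching the fitted family), or
Dirichlet to probe misspecification — then generates each tooth from the
concentration-weighted mixture mean under the chosen TEF plus noise.
Defaults: `individual_sd_ilr = 0.75` and per-tooth residual SDs
(0.3, 0.3, 0.4) permil at the analytical-precision scale, calibrated by
moment matching so the implied isotope-space partition reproduces the
strong individual specialisation reported for the motivating system
(BIC:TNW ≈ 0.77) and per-axis total SDs near 0.7 permil. A tooth
integrates diet over months, so its scatter reflects measurement error and
short-term diet variation rather than the full prey-to-prey spread;
setting `propagate_source_variance=True` instead draws each tooth from the
mixing model's full predictive variance, giving a world in which the
mixing model is exactly correctly specified.

The two regimes validate different stages, and no single regime can do
both: with analytical-scale tooth noise the mixing likelihood — which, as
in standard concentration-dependent mixing software, carries the full
per-datum source + TEF variance — systematically favours
variance-minimising compositions (the likelihood scales as V(p)^(−n/2)
when residual scatter is tiny), tilting population estimates toward the
lowest-variance source by up to ~10 points; with full predictive noise
the isotope-space BIC:TNW cannot exceed ~0.5 however heterogeneous the
diets, because per-tooth noise floors the within-individual component.
The acceptance script therefore reports the variance partition from the
tooth-calibrated regime and the diet/nutrient estimates from the
model-consistent regime, averaged over four replicate datasets each to
reduce the Monte-Carlo noise of a single 12-individual realisation.

**What passing tests show — and don't.** Recovery tests demonstrate that
the samplers target the correct posteriors and that population-level
quantities, credible-interval coverage, and the nutrient transformation
behave as designed under the generator's assumptions. They do not show
that real tooth series satisfy those assumptions: real data add temporal
autocorrelation along the tooth file, baseline (habitat) isotopic
variation, TEF misspecification, and prey compositions that vary within
source groups. Individual-level diet recovery is intrinsically limited for
sources that are isotopically similar: with five teeth per individual, the
rank correlation between true and estimated individual use reaches ~0.9
for an isotopically distinct source but plateaus near 0.6 for the three
mutually confusable mid-trophic groups — an identifiability ceiling, not a
sampler deficiency.

## Numerical choices and degenerate inputs

- Seeds: every stochastic operation takes an explicit seed; pipeline stage
  seeds derive from the run seed by hashing, and the run manifest records
  them, so a configuration reproduces its outputs bit-for-bit.
- Pooled source SDs are full-sample SDs (within + between members via the
  total sum-of-squares decomposition over n−1), matching how multi-species
  group rows are summarised from species rows.
- Simplex draws are validated (non-negativity, sums within 1e-9) on
  construction of every posterior container.
- Ties in probabilistic comparisons count 0.5, so identical posteriors land
  at probability 0.5 with no significance flag.
- The beta-regression candidate table flags failed fits and ranks the rest;
  an all-identical response or n ≤ k+1 raises instead of silently fitting.
- MCMC problem sizes in the test-suite and acceptance script (thousands to
  tens of thousands of iterations, 21–45 replicate fits) were chosen as the
  smallest sizes at which posterior-mean Monte-Carlo error is well below
  the effect sizes being asserted; the desk presets are larger, and the
  published "extreme" preset is exposed for full-scale runs.

## Known limitations

- No temporal autocorrelation or fixed effects in the isotope-space model;
  no covariate effects on diet in the mixing model; informative (e.g.
  stomach-content) priors are deliberately not supported.
- The exact error decomposition used by other concentration-dependent
  mixing implementations ("process × residual" variants) is approximated
  by one additive residual variance per isotope, isolated behind the
  likelihood-variance function.
- Full-data reproduction of the motivating study requires its archived
  raw dataset and the extreme MCMC preset; the repository validates the
  machinery on synthetic data only.
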