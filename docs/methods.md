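# Methods

`samgap` measures and decomposes rural–urban inequality in severe acute
malnutrition (SAM) among under-five children using survey-weighted,
cluster-sampled data of the kind produced by national household surveys.
This note records the models, the conventions chosen where several are
defensible, the synthetic data used to validate everything, and the known
limits of that validation.

## Outcome: SAM from weight-for-height

A child's weight-for-height z-score (WHZ) is computed by the LMS method
against a sex- and height-indexed reference of Box–Cox power `L`, median
`M` (kg) and coefficient of variation `S`:

    z = ((w / M)^L − 1) / (L·S),     z = ln(w / M) / S  as L → 0.

The logarithmic form is used when |L| < 1e−8, making the map continuous in
L. Reference rows are linearly interpolated in height within sex (the grid
is dense at 0.5 cm, so higher-order interpolation would change nothing
material); heights outside the grid are out of range and excluded. SAM is
WHZ **strictly** below −3, or recorded nutritional oedema. |WHZ| > 5 flags
a biologically implausible measurement; such records are excluded from
analysis and counted. Oedema defaults to absent because most surveys do
not record it.

The package ships no clinical growth standard. `generate_lms_fixture`
builds a smooth synthetic LMS table (strictly increasing quadratic median,
S in (0.05, 0.15), L in (−2, 1)) for tests and examples only; analyses of
real children must supply a real reference as a `sex,height_cm,L,M,S` CSV.

## Neighbourhood disadvantage index

Clusters (primary sampling units, the operational "neighbourhoods") are
profiled by the unweighted within-cluster proportions of respondents who
are illiterate, poor and unemployed. The disadvantage score is the first
principal component of the **correlation** matrix of the standardized
proportions — standardization because the three proportions have unequal
variances, as is standard for composite indices. The eigenvector sign is
fixed so loadings sum positive: the score rises with every disadvantage
indicator. Quintiles are cut on the child-count-weighted ECDF (smallest
score whose cumulative weight reaches 20/40/60/80%), boundary ties falling
to the lower quintile; quintile 5 is the most disadvantaged. The index is
computed per country by default (pooled as an option), since mixing
countries would let between-country level differences dominate the
component.

## Inequality metrics

Group prevalences are survey-weighted, with the Kish design effect
`deff = n·Σw²/(Σw)²` converting each group to an effective sample size
`n_eff = n/deff`. The inequality measure is the risk difference

    RD = (p_rural − p_urban) × 1000,

with variance `p_r(1−p_r)/n_eff,r + p_u(1−p_u)/n_eff,u` and a Wald CI.
Positive RD with CI above zero is **pro-rural** inequality, negative with
CI below zero **pro-urban**, otherwise none (α = 0.05 default). The Kish
effective-n variance accounts for weight heterogeneity but not for
intra-cluster outcome correlation; a cluster-level correction, when
needed, comes from the bootstrap machinery in the decomposition module.
Under the generator's null worlds (outcomes independent given covariates)
the classifier's significant-call rate is verified at the nominal 5%.

Odds-ratio homogeneity across strata is tested with the Breslow–Day
statistic with Tarone's correction against the Mantel–Haenszel common OR
(via `statsmodels.StratifiedTable`); strata containing a zero cell get
0.5 added to every cell, logged. Country RDs are pooled with the
DerSimonian–Laird random-effects moment estimator (`tau² = max(0,
(Q − df)/C)`, `C = Σw − Σw²/Σw` on fixed-effect weights), Wald CI, and
percent study weights on the random-effects scale — the forest-plot
analogue. REML alternatives were considered and not implemented; DL is
the convention for this design and is exactly testable by hand.

## Two-fold non-linear decomposition

For a binary outcome the group mean is `E[y | g] = mean_i F(x_i'β_g)` with
F the logistic CDF, so the classic linear Blinder–Oaxaca split is
generalised on the probability scale:

    gap         = Σ_R ŵ F(x'β̂_R) − Σ_U ŵ F(x'β̂_U)   (= difference in weighted
                                                       observed prevalences, by
                                                       the weighted-MLE score identity)
    explained   = Σ_R ŵ F(x'β̂*) − Σ_U ŵ F(x'β̂*)
    unexplained = gap − explained

Sign convention: rural minus urban throughout, so positive components
widen pro-rural inequality, matching the RD convention.

**Reference coefficients β̂*.** Default is a pooled weighted logit over
both groups including a *centered* group indicator (+½ rural, −½ urban),
the indicator's coefficient being excluded from β̂* so the pure group
effect lands in the unexplained part. Centering is deliberate: with a 0/1
indicator the explained term is evaluated at one group's baseline and
exchanging the group labels would *not* exactly negate the components;
with the centered indicator label-swap antisymmetry holds to machine
precision. Rural- or urban-coefficient references are available and make
the usual index-number arbitrariness explicit.

**Detailed contributions.** The explained component is apportioned with
Yun's linear-index weights,

    W_k = (x̄_Rk − x̄_Uk)·β̂*_k / Σ_j (x̄_Rj − x̄_Uj)·β̂*_j ,

which are deterministic, sum to one, and make detailed contributions sum
exactly to the explained component. Dummy columns of one categorical are
aggregated into a single term; aggregated term contributions are invariant
to the base-category choice (re-basing shifts the term's linear index by a
constant that cancels in the R−U difference), and deviation-contrast
coding (default) additionally makes the individual columns symmetric. A
zero linear-index gap leaves the weights undefined and raises an error
suggesting the Fairlie alternative; the one exception is the fully
degenerate identical-composition case, where all contributions are exact
zeros. The Fairlie sequential-substitution method is provided as the
randomized alternative: the larger group is weight-proportionally
subsampled to the smaller, both sides rank-matched on predicted
probability, covariates switched urban→rural one term at a time in random
order, averaged over seeded replications with Monte-Carlo SEs. Its
contributions sum to the explained component up to matching noise; pair
means are unweighted, so with heterogeneous weights it is an approximation
to the weighted explained term.

**Fitting.** The weighted logistic pseudo-likelihood is maximised by
Newton/IRLS: relative log-likelihood tolerance 1e−10, at most 100
iterations, separation reported (never silently absorbed) either when the
coefficient norm diverges past 1e4 or when the likelihood plateaus with
max |x'β̂| > 30 (fitted probabilities numerically at 0/1). Coefficient
covariance is a sandwich clustered at the PSU with a G/(G−1) small-sample
factor, heteroskedasticity-robust when no clusters are given. The fitter
is cross-checked against `statsmodels` GLM in the test suite. An identity
link (weighted least squares) is supported solely so the decomposition can
be driven into its linear limit, where every component must match the
classic closed form — this is one of the package's standing oracles.

**Inference.** Percentile CIs from a cluster bootstrap: PSUs are resampled
with replacement within each residence group, the full decomposition is
recomputed per replicate on prebuilt design arrays (one pooled fit per
replicate under the default reference), and failed replicates (separation)
are skipped and counted. B ≥ 100 is enforced; B = 200 at the default 95%
level gives empirical coverage of the explained component of ~0.93 in the
validation worlds below.

## Synthetic worlds and the ground-truth oracle

The generator emulates the design features the estimators rely on, not any
particular country: clusters assigned wholly rural or urban
(Bernoulli(urban_fraction)); shifted-Poisson cluster sizes (minimum one
child; survey cluster sizes vary and no standard law exists); a latent
neighbourhood SES ~ N(shift·urban, 1) loading on child covariates; binary,
threshold-ordinal and Gaussian covariates with group-specific parameters
(endowment gaps); Bernoulli outcomes from group-specific logits
(structural gaps); and log-normal mean-one sampling weights independent of
the outcome given covariates (any positive heterogeneity exercises the
weighted estimators; real weight mechanisms are design-driven and
unknowable here). Ordinal covariates threshold a latent normal so they
stay monotone in SES.

`compute_ground_truth` defines the estimands: Monte-Carlo population means
of `F(Xβ)` per group, with each MC child drawing an independent SES value
(same marginal law as the cluster-nested generator, hence identical
population moments). For rural/urban references the true β* is the
configured vector; for the pooled reference it is the probability limit of
the pooled fit, realised by fitting at large n_mc with the same centered
indicator — so recovery tests compare like with like. Per-covariate truths
use Yun weights at population moments; unexplained is the exact residual,
and reported MC standard errors treat β* as fixed.

Two named configurations fix the study conditions. `default_config` is a
DHS-like world (~4–5% SAM, modest gaps of a few per 1,000, ~50/50
compositional split, with a `null=True` switch that removes every
rural–urban difference for calibration runs). `recovery_config` is a
deliberately strong-signal world (rural ~11%, urban ~4%, gap ~80 per
1,000, explained share ~0.44) used for recovery and coverage validation:
the explained *share* of a small gap is intrinsically ill-determined —
its sampling error is dominated by the Bernoulli noise of the gap itself —
so validating share recovery to ±0.05 requires a gap well clear of that
noise floor at the problem sizes used (50,000 children in 1,000 clusters
for recovery; 200 datasets of ~5,000 children, B = 200, for coverage).

What passing these tests does **not** show: the generator draws outcomes
independently given covariates (no residual cluster random effect), drops
out missingness mechanisms, informative weights, measurement error in
anthropometry, and real surveys' stratification — so calibration results
here are necessary, not sufficient, for real-data validity. The Kish-based
RD interval in particular will undercover when outcomes are
intra-cluster-correlated beyond covariates.

## Pipeline

The six stages — pool records, derive SAM (implausible WHZ excluded and
counted), per-country weighted prevalences, RD classification, DL pooling,
decomposition of the significantly unequal countries — are composed in
`run_full_pipeline`, which writes tidy CSVs and a JSON manifest recording
seeds, exclusions and selections. Countries lacking a residence group are
skipped with a warning rather than aborting multi-country batches. RD- and
OR-based significance can disagree; screening is on the RD classification,
and `decompose_all=True` forces decomposition everywhere. All randomness
(bootstrap seeds per country) derives from one pipeline seed.

## Numerical details, degenerate inputs

- Decomposition identities (`explained + unexplained = gap`, Yun
  additivity, weights summing to 1) hold to 1e−10 by construction and are
  asserted across randomized worlds.
- Quintile assignment needs ≥5 distinct scores; the PCA needs ≥3 clusters
  and at least one non-constant indicator (numerically-constant columns
  are dropped with a warning; all-constant input is an error).
- A categorical level present in only one residence group makes the
  counterfactual means ill-posed; this is an error naming the level, not a
  silent drop.
- Zero cells in homogeneity strata: +0.5 to all cells of affected strata.
- Missing data: complete-case with logged exclusion counts at every stage;
  manifest row accounting satisfies input = analysed + excluded.
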