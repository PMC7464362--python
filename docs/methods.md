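# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `milemet`.

## Growth model and milestone extraction

Longitudinal BMI is modelled as

    bmi_ij = β₀ + β_sex · male_i + N(t_ij)ᵀ(β + male_i · γ) + u_i0 +
             N(t_ij)ᵀ u_i + ε_ij

where N(t) is a natural cubic spline basis of age in months, β/γ are fixed
spline and sex-interaction coefficients, u_i are subject-level random
coefficients and ε is homoscedastic residual noise. The fit uses REML via
`statsmodels.MixedLM`.

**Spline basis.** The basis is built from cubic B-splines with the two
natural constraints (zero second derivative at the boundary knots) imposed
through a locality-preserving null-space transform, so every basis
function keeps compact support. Locality matters for the random effects: a
subject-level deviation late in childhood then perturbs only the
late-childhood coefficients instead of leaking into the infancy fit, which
is what happens with the global truncated-power construction. The first
derivative is available in closed form from the B-spline derivative
(piecewise quadratic), which makes stationary-point search cheap and
robust.

**Defaults.** Interior knots at 3, 8, 14, 22, 34, 48 months with boundary
knots 0.25 and 61 months — dense through infancy and the rebound region.
Sparser infancy knots were deliberately preferred over denser ones: the
infancy peak of a BMI curve is shallow, and extra knots there let the
fitted curve wiggle on the 2–3-month scale under measurement noise, which
skews the located peak. Random effects: a random intercept plus a random
coefficient on every basis term with a diagonal covariance
(`SplineConfig.random_structure`); an unstructured covariance over a
leading subset is available via `n_random_basis` for smaller models.

**Milestones.** For each subject the fitted curve (fixed part for the
subject's sex plus the subject's predicted random deviations) is scanned
on a 0.1-month grid within the infancy window [0.5, 20] months and the
childhood window [24, 110] months, both intersected with the observed age
support (the model refuses extrapolation). Derivative sign changes are
refined by bisection to 10⁻³ months. Multiple roots are tie-broken by the
largest fitted BMI (peak) or smallest (rebound). A window without an
interior sign change yields a flagged, non-identified milestone — not an
error — and propagates as a missing exposure downstream. When the fixed
design interpolates the data exactly (zero residual variance), REML is
degenerate and the model falls back to the exact least-squares solution
with zero subject deviations.

**Exposure scaling.** The four milestone exposures are divided by their
within-sex sample SD on the analysis sample; effect estimates are reported
per +1 SD, and the SDs are reported alongside.

## Synthetic cohort

The generator exists so that every stage can be tested against exact
ground truth.

**Trajectories.** Each child's latent curve is the quartic whose
derivative is b′(t) = k(t − t_p)(t − t_r)(t + c) with k > 0, c > 0: exactly
one interior maximum (the infancy peak, age t_p) and one interior minimum
(the rebound, age t_r). k and the integration constant are solved so the
peak magnitude and the peak-to-rebound drop match their drawn values, so
ground-truth milestones are exact and analytic. Observed BMI adds Gaussian
noise (default SD 0.3 kg/m²) at a fixed 12-visit schedule from 2 weeks to
60 months.

This family has two structural quirks worth knowing. First, the pre-peak
rise is geometrically capped at ≈0.1–0.19 × drop (it approaches the upper
value as c grows), so the generated infancy peak is far shallower than a
real child's BMI curve, which climbs several kg/m² from birth; c defaults
to 90 months to sit near the favourable end. Second, the curve steepens
rapidly beyond ≈1.5 × t_r, so the default schedule ends at 60 months and
the rebound-age distribution is kept moderately tight
(N(42, 5²) months, truncated to [34, 53]). Real cohorts show rebound ages
centred near 5 years with SDs around 20 months; that regime is not
representable in this family without absurd late-childhood BMI values, so
milestone-recovery results on the synthetic cohort speak to the
estimator's behaviour under these compressed conditions, not to every real
cohort. Peak age is N(8.4, 1.5²) months (truncated [5, 12.5]), peak
magnitude N(18.1, 1.35²) kg/m², drop N(2.5, 0.5²) kg/m² (truncated
[1.2, 4.0]); invalid draws (t_r ≤ t_p + 10) are redrawn up to 100 times.

**Metabolome.** Module m has a latent factor f_m ~ N(0, 1) per subject;
member log-abundance = λ f_m + √(1 − λ²) ε with default loading λ = 0.8;
background metabolites are independent noise. Raw abundance is
10^(location + 0.3 × log-abundance) with per-metabolite locations
U(2.5, 5.5). Left-censoring at the per-metabolite `lod_censor_fraction`
quantile (default 10%) emulates a limit of detection, matching the
half-minimum imputation downstream. A configurable fraction of background
metabolites is flagged non-endogenous (module members stay endogenous so
planted module sizes survive the filter exactly). Defaults: five modules
of 30 plus 60 background metabolites.

**Planted effects.** `effect_map` entries (exposure, target, β, stratum)
plant linear paths. Milestone→module effects enter the factor as
f = (Σ β_e z_e + ε)/√(1 + Σ β_e²) so factors keep unit variance per
stratum; the realized regression coefficient β_e/√(1 + Σ β²) is stored in
the ground truth. Module→component effects add β f to the component
z-signal directly ('composite' targets all five components with HDL
negated). The default plants the path the screen is designed to find:
earlier rebound → higher module-2 factor → higher MetS z, in boys.

**Outcomes and references.** Component raw values are mean(sex, age,
height) + SD × z with marginal models loosely matched to published
adolescent distributions (e.g. waist 73 ± 11 cm, SBP ~107 ± 9 mmHg,
HDL 56 ± 13 mg/dL, triglycerides ~69 ± 30, HOMA-IR ~2.8 ± 1.2). All
component marginals are Gaussian so planted effects stay exactly linear
on the raw scale; the HOMA-IR SD is kept below the published spread of
that (right-skewed) biomarker because a wider Gaussian would be truncated
at the positivity floor for ~10% of draws, distorting the planted linear
effects. Insulin is back-computed from the drawn HOMA-IR and glucose so
that the score module's HOMA-IR formula reproduces the planted value. Reference tables
are mean/SD per sex × age bin (1-year bins to 14, then [14, 16); height
bins added for SBP) from an independently simulated null population of
20,000. Standardizing that population against its own tables gives
per-stratum z means of 0 and SDs of 1 by construction.

**What the generator does not emulate.** Batch effects, longitudinal
metabolomics, realistic metabolite annotation, skewed component
distributions (standardization here is exactly Gaussian), informative
missingness beyond left-censoring, and the steep infancy rise of real BMI
curves. Tests passing on this generator show the pipeline recovers planted
structure under clean factor-model assumptions; they do not certify
behaviour under real-data pathologies.

## Metabolite preprocessing

Fixed order: endogenous filter → half-minimum imputation (per metabolite,
missing ← ½ × minimum detected value) → log10 → Pareto scaling
((x − mean)/√SD, SD with n−1 denominator). The output matrix is flagged
and a second pass is refused, because the transform is not idempotent.
Fully-missing or constant metabolites raise with the metabolite named.

## Consensus networks

- **Correlation.** Spearman with average ranks for ties (half-minimum
  imputation creates many ties; average ranks handle them consistently).
- **Adjacency.** Signed: a_ij = ((1 + ρ_ij)/2)^β, β = 10 fixed (a
  scale-free-fit diagnostic table per power is produced for QC, but the
  power is not auto-selected).
- **TOM.** ω_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
  l = ΣA·A off-diagonal, computed with matrix products and verified
  against a literal triple loop.
- **Consensus.** Per-stratum TOMs are rescaled so each stratum's 0.95
  off-diagonal quantile matches the across-strata mean of those quantiles,
  then combined by element-wise minimum (calibration can be disabled, in
  which case identical strata reproduce the single-stratum result
  exactly).
- **Outlier samples.** Before network construction, each sample's
  connectivity is the mean |r| over its strongest decile of partner
  samples in the sample–sample correlation network; samples with
  standardized connectivity Z < −2.5 are removed. Total (signed or
  squared) connectivity was rejected because on column-centred data it
  cannot distinguish a corrupted profile from a genuinely low-factor-score
  sample; the tail mean can.
- **Module detection.** Average-linkage clustering of 1 − TOM. The
  dendrogram is cut at the largest gap between consecutive sorted merge
  heights (searched in the upper half of the merge order); branches are
  recursively decomposed the same way. A branch is accepted as a module
  when it has ≥ 20 members and its *cohesion* — median within-branch TOM
  over mean branch-to-rest TOM — is at least 3. The two choices were made
  for robustness: a fixed-quantile cut attaches loosely-correlated
  background metabolites to genuine module branches (their attachment
  heights are numerically indistinguishable from between-module merge
  heights near 1), and a mean-based cohesion lets a small tight core carry
  a padded branch. Branches assembled from pure noise reach cohesion ≈ 2
  by linkage selection alone while factor-driven modules exceed ≈ 4 even
  at weak loadings, so 3 separates the regimes; under the null, ≥ 80% of
  metabolites land in the unassigned label 0. A fixed-quantile cut is
  available via `cut_method='quantile'`. Known limitation: modules at very
  different tightness scales compete for one global gap, so a much weaker
  module alongside a much tighter one can be missed.
- **Eigengenes.** Per stratum and module: columns z-scored, SVD, first
  left-singular component rescaled to a per-sample z-score, sign oriented
  so mean member kME > 0 ("higher score = higher member abundance");
  variance explained = σ₁²/Σσ². kME is the correlation of every metabolite
  with every eigengene. Unassigned metabolites (label 0) get no eigengene
  and are excluded from downstream models. The membership report ranks
  metabolites by own-module kME (top-10 plus everything above |kME| 0.6).

Note on scale: eigengenes here are z-scores across samples, so step-3
effect estimates are per +1 SD of the network score. Analyses that keep
the raw unit-norm singular vector report numerically much larger "per
1 unit" coefficients for the same association; only the scale differs.

## MetS z-score

HOMA-IR = glucose × insulin / 405 (mg/dL, µIU/mL). SBP is the mean of the
available readings (nominally five; fewer triggers a logged warning).
External standardization resolves (component, sex, age[, height]) against
closed-open bins [lo, hi) — closed-open avoids double membership at bin
edges — and errors naming the component and keys when no bin covers a
subject. The composite is the mean of the five z-scores with HDL negated;
any missing component is an error (exclusion is an upstream decision).
Triglycerides and HOMA-IR are standardized on the raw scale; a log-scale
flag is not provided because the reference-table interface already accepts
tables built on any scale the user chooses.

## Association screen

OLS throughout (statsmodels), complete-case per model, categorical
covariates expanded to indicator contrasts, 95% CIs from the t
distribution, rank-deficient designs refused with aliased terms named.
Covariate tiers are nested: Model 1 (age at the adolescent visit,
race/ethnicity), Model 2 (+ ordinal puberty score), Model 3 (+ maternal
education, pre-pregnancy BMI, 3-level smoking). The BH-FDR family in
step 2 is, per sex, all carried milestones × all module eigengenes jointly
(the most conservative of the defensible groupings; per-milestone families
are available via `ScreenConfig.fdr_family`). Step-3 component follow-up
is run only for eigengenes significant under Model 1 and is deliberately
uncorrected: the five components are correlated facets of one construct.
The sensitivity analysis refits step-2 models with the contemporaneous
milestone (age↔magnitude) added, reporting both estimates and the percent
change; |r| > 0.99 between siblings is refused as collinear.

## Benchmark problem sizes

The packaged benchmarks (`scripts/acceptance.py`, `tests/test_acceptance.py`)
use: three independent default cohorts (300 subjects each) for milestone
recovery — averaging tightens the Monte-Carlo error of the bias estimate,
whose seed-to-seed SD on one cohort is ≈0.4 months for the shallow infancy
peak; 50 random matrices (≤ 40 nodes) for TOM oracle equivalence; 5 × 30
planted blocks at 200 samples/stratum for module recovery; n = 500 for
eigengene fidelity; 500 replicates × 26 tests per sex for the null-screen
FDR; and 200 scaled-down replicate cohorts (250 subjects, 3 × 25
metabolites, loading 0.9) for end-to-end path recovery, using the planted
true milestones as exposures so the replicate loop measures the screen
itself (milestone-estimation error is benchmarked separately) and the
network is rebuilt from data in every replicate. CI coverage is pooled
over the two planted coefficients (~400 intervals) and is scored against
the fixed-design estimands on each replicate's realized scales: module
eigengenes are z-scored per replicate, so the planted milestone→module
coefficient maps to β′/sd(f) when the eigengene is the outcome, and the
module→MetS coefficient maps to β·cov(f, ME) when it is the regressor;
comparing with the fixed per-unit-factor constants would count the
replicate-level normalization drift (~6% of the effect) as CI misses and
make 95% intervals appear miscalibrated for any implementation. The
step-2 interval is scored on every replicate (not only carried ones),
because conditioning on selection removes precisely the replicates whose
noise pushed the estimate toward zero and inflates apparent coverage.

## Numerical choices

- Spline basis columns are rescaled to unit range for conditioning; the
  derivative uses the same scales.
- Root refinement: bisection to 10⁻³ months on the analytic derivative.
- Mixed-model optimizer: L-BFGS with a Powell fallback; non-convergence is
  flagged on the fit, never silent.
- TOM/adjacency are clipped to [0, 1] against floating-point drift;
  dissimilarity diagonals are exactly 0.
- BH step-up uses a stable mergesort argsort so tied p-values resolve
  deterministically.
- All randomness flows from one `numpy` Generator per run; replicate seeds
  are spawned via `SeedSequence` and kept below 2³¹.

## Known limitations

- The trajectory family cannot express realistic infancy rises or wide
  rebound-age spreads (above); milestone benchmarks are conditional on the
  compressed geometry.
- Module detection assumes modules of broadly comparable tightness.
- The mixed model assumes homoscedastic residuals; the quartic tail makes
  late-visit residuals heavier, slightly inflating the residual variance
  estimate.
- The screen is associational; no mediation analysis is attempted.
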