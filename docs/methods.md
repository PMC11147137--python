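# Methods

## Model and procedure

The pipeline treats maternal 25(OH)D as a continuous exposure **y** and the
log-transformed, autoscaled metabolome as the predictor block **X**
(samples × metabolites). The central model is orthogonal projections to
latent structures (OPLS) with a single predictive component, fitted by
orthogonal deflation: the predictive weight is w ∝ Xᵀy (unit norm); each
orthogonal component takes the current X-loading p = Xᵀt/(tᵀt), removes its
projection on w (w_o ∝ p − (wᵀp)w), and deflates X by the corresponding
score–loading product. Every orthogonal score satisfies t_oᵀy = 0 exactly,
and the y-predictions of OPLS with one predictive plus k orthogonal
components coincide with a (k+1)-component NIPALS PLS regression — the
test suite verifies this against scikit-learn's PLS as an independent
oracle. OPLS-DA encodes a two-arm randomization as a centred ±1 dummy and
reuses the regression fit.

Key metabolites are those with VIP > 2 toward the predictive component.
With one predictive component VIP_j = √p·|w_j|, hence mean VIP² = 1; the
threshold of 2 therefore selects variables carrying at least 4× the average
squared contribution. The selection feeds (a) a PCA whose PC1/PC2 scores
summarize the vitamin-D-related profile, (b) an OPLS refit on the selection,
and (c) sub-pathway over-representation analysis.

### Cross-validation and permutation

Q² = 1 − PRESS/SS is computed by double cross-validation: 10 outer folds;
within each outer training set an inner 7-fold CV evaluates 0…5 orthogonal
components and keeps the count maximizing inner Q² (ties toward fewer
components); the outer fold is then predicted once at that count. SS is
taken about the training-fold mean of y. Significance uses permutation of
y (default 1000 draws) with the identical fold partition — exchangeable
under the null and variance-reducing — and
p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), so p is never zero and equals
1/(n_perm+1) when no permutation reaches the observed Q².

Because the fit is linear algebra in y for fixed X, permuted targets are
processed as columns of a matrix through batched deflation, and the nested
structure of the orthogonal components lets one pass per training fold
serve every component count. This keeps a 200-permutation double-CV test
on a 400 × 300 matrix in the tens of seconds on one core.

### Enrichment

For a selection of n metabolites from a universe of N (all metabolites
surviving QC — the set selection actually happened in), a sub-pathway with
K universe members and k selected members gets the one-sided
hypergeometric tail P[X ≥ k], the enriched factor (k/n)/(K/N), and a
Benjamini–Hochberg q-value across the tested sub-pathways. Sub-pathways
with no universe member are excluded from the family. The hypergeometric
choice (vs Fisher/binomial) is recorded here as the package's reading of
"pathway enrichment"; the test suite pins the tail to exhaustive subset
enumeration for all N ≤ 15.

### Association battery

One exposure (PC score, single metabolite z-score, or calibrated 25(OH)D)
per outcome per model: Cox proportional hazards with Efron tie handling
(lifelines) for age-at-onset outcomes; quasi-Poisson — Poisson GLM with
dispersion φ = Pearson χ²/df and φ-scaled Wald intervals (statsmodels) —
for episode counts; logistic GLM for binary outcomes; OLS on the z-scored
outcome for continuous ones, so linear effects are per SD. Ratio-scale
CIs are Wald constructions exp(coef ± z₀.₉₇₅·SE). Default adjustment set
for outcome models: PUFA arm, third-trimester smoking, breast-feeding
days, child sex, day-care start age, birth season. Stratified analyses
pool the 17q21 rs12936231 carriers (CG/CC) against the low-risk GG group;
degenerate strata are flagged and returned rather than aborting the run.

Exposure calibration residualizes 25(OH)D by OLS on the vitamin-D arm,
the PUFA arm, smoking, child sex, and birth season (four-level indicator,
winter reference), recentred at the grand mean; including the vitamin-D
arm follows the model description attached to the score plots, which is
more specific than the shorter covariate list in the analysis text.
Missing covariates are handled by complete-case deletion, logged.

## Synthetic cohort generator

`SimConfig`/`generate_cohort` emulate a randomized prenatal vitamin-D
trial with untargeted maternal metabolomics:

* latent axis L ~ N(0,1) per mother — the "vitamin-D-related metabolic
  profile";
* 25(OH)D (nmol/L) = 88 + 33·arm + 15·L + 10·cos(2π(month−7)/12) − 8·smoking
  + 15·ε, anchored to the target cohort's printed distribution (mean ≈ 88,
  SD ≈ 36, high-dose shift ≈ 33 nmol/L); the seasonal sinusoid gives the
  calibration step real work;
* metabolite intensities are log-normal; a signal block (default 46 of
  753, all in one designated sub-pathway) gains `exposure_loading`·L on the
  log scale (default 0.5 SD per SD), other metabolites are pure noise with
  `noise_sd` = 1;
* outcomes: exponential event times with hazard h₀·exp(loghazard·L)
  (h₀ set for ≈30% cumulative incidence by the 3-year administrative
  censoring horizon), Poisson episode counts with log-rate
  `count_lograte`·L, Bernoulli sensitization and Gaussian lung-function
  z-scores with analogous per-SD effects; protective defaults mirror an
  exposure that lowers respiratory risk;
* covariates: 1:1 randomization for both arms, 8% smoking, HWE genotype
  frequencies with P(G) = 0.65 at 17q21, uniform birth months;
* completely-at-random missingness (default 5%); identical seeds produce
  bit-identical cohorts and files.

Defaults follow the cohort the pipeline targets (672 mothers, 753
metabolites in 9 super-pathways, 46 signal metabolites); the total
sub-pathway count is not published, and 60 is used as typical for an
untargeted panel of this size. No published effect sizes link 25(OH)D to
individual metabolites, so the loadings are free parameters of the
simulation, not estimates of any real cohort. The generator does not
emulate LC-MS peak-level artifacts, batch effects, non-random missingness,
correlated metabolite blocks outside the signal set, or
genotype–metabolome interactions — so passing tests demonstrate
correctness of the statistical machinery under the stated generative
model, not robustness to those real-data complications.

## Numerical choices

* z-scoring uses the population SD (divisor n); constant columns are
  dropped with a warning.
* QC keeps metabolites with ≤ 20% missing (convention; configurable);
  half-minimum imputation is the floor-value convention for
  below-detection intensities.
* Component orientation: each score/loading pair is flipped so the
  largest-magnitude loading entry is positive, removing sign ambiguity
  (consequence: OPLS-DA predictive scores are orientation-invariant under
  label swap; the decision values negate).
* Inner-CV ties break toward fewer orthogonal components; the search range
  0–5 rarely binds at these problem sizes.
* Wald z is Φ⁻¹(0.975); permutation p uses the add-one formula above.
* Degenerate inputs (constant y, no events, all-zero counts, single-class
  outcomes, aliased designs, zero marginals) raise errors naming the
  offender rather than propagating NaNs.

## Verification problem sizes

The test and acceptance suites size their simulations to run on one core
in a few minutes while keeping each check well-powered: null calibration
of the permutation machinery uses 50 replicates of 80 × 40 null matrices
with 200 permutations each (inner 5-fold, ≤ 3 orthogonal components);
planted-recovery uses 20 cohorts of 400 mothers × 300 metabolites with 30
signal metabolites at loading 0.5; association-model recovery and null
coverage use 100 replicates of n = 1000 (n = 2000 for ratio effects needing
tighter brackets). The null Cox coverage check uses uncensored exponential
survival with an independent exposure and no covariates.

## Known limitations

* Single predictive component only (one continuous y or two classes); no
  multi-class OPLS-DA, O2PLS, kernel or sparse variants.
* Quasi-Poisson and logistic inference is Wald-based; no profile
  likelihood or exact small-sample intervals.
* The validation-cohort workflow refits PCA within the validation cohort
  (rather than projecting discovery loadings), matching the replication
  design it mirrors; both cohorts must share metabolite identifiers.
* Enrichment is annotation-partition-based over-representation; no
  topology-aware or rank-based (GSEA-style) analysis.
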