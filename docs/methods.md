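# Methods

`panclock` implements the statistical machinery of multi-species DNA
methylation age clocks and the screening analyses that surround them.
This note describes the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the tests demonstrate.

## Age transformations

Clock regressions are fit on a transformed age scale chosen per clock:

- **identity** — transformed age equals age in years (single-species
  pan-tissue clocks).
- **sqrt_offset** — `sqrt(age + 1)`. The 1-year offset keeps fetal
  samples, coded with negative ages down to one gestation length, inside
  the domain. The square-root link also turns additively learned
  per-species intercepts into multiplicative slope differences after
  back-transformation (`(a_s + g)^2` scales the common component `g` by
  `2 a_s`), which is what lets one linear model track absolute age in
  species whose lifespans differ by an order of magnitude.
- **loglinear** — `log(age+1) − log(m+1)` for ages up to the species'
  age of sexual maturity `m`, and `(age − m)/(m+1)` afterwards.
  Continuous, zero at `m`, with matching one-sided derivatives
  `1/(m+1)`. Per-species maturities are supplied as a map; a single
  shared constant is the degenerate one-entry map.
- **relative** — `age / maxLifespan`, making species with very different
  longevities comparable on a common [0, 1] scale. Predictions are *not*
  clamped to [0, 1]; raw values are reported.

Each transform has an exact inverse used to express predictions in years
(round-trip identity holds to 1e-9 over the whole domain). One numerical
guard: a fitted linear score can dip below `sqrt(0)` for fetal samples,
so `predict_age` clamps the score at 0 before inverting `sqrt_offset`;
the raw score is still reported in `y_transformed`.

## Elastic-net clocks

Clocks are penalized linear regressions of transformed age on beta
values with mixing parameter `alpha = 0.5` (midway between ridge and
lasso; conventional for methylation clocks and not treated as a tuning
knob). The regularization strength is selected by an internal tenfold
cross-validation minimizing mean squared error over a 50-point penalty
path (`sklearn.ElasticNetCV`); folds are seeded explicitly so fits are
reproducible. Predictors are standardized internally but coefficients
are reported on the raw beta scale, so the serialized coefficient table
(`Intercept` row plus `cpg_id,coefficient` rows under a commented YAML
header) can be applied directly to a beta matrix, like published clock
tables. Missing betas are mean-imputed from the training set and the
per-CpG training means of selected CpGs are stored in the model for
reuse at prediction time. All-constant columns are dropped with a
warning; fits require at least 20 samples.

## Cross-validation and accuracy

Two schemes produce out-of-fold predictions: LOOCV and **LOFO10**, a
tenfold scheme balanced by species — within each species, samples are
shuffled (seeded) and dealt round-robin from a random starting fold, so
per-species fold counts differ by at most one. The penalty is re-selected
inside every training fold; no sample is ever predicted by a model that
saw it. Accuracy is summarized as the Pearson correlation R between
predicted and chronological age and the median absolute error in years,
overall and per species/tissue.

**Age acceleration** is reported under two definitions: `delta`
(DNAmAge − age) and `residual` (residual of DNAmAge regressed on age).
Residual is the default: it is zero-mean, exactly uncorrelated with age,
and invariant to calibration offsets. In the acceleration table the
residual regression is computed within each tissue so tissue-level
calibration differences do not masquerade as shared biology when
correlating accelerations across tissues of the same animals (pairs with
fewer than 3 shared animals are reported missing).

## EWAS of age and meta-analysis

Within one species-tissue stratum each CpG is screened by the Pearson
correlation of beta with age: `t = r sqrt(n−2)/sqrt(1−r^2)`, two-sided p
from the t distribution with n−2 df, and the signed normal quantile
`Z = sign(r) · Φ⁻¹(1 − p/2)`, standard normal under the null. Positive Z
is age-related gain of methylation. Sample sizes are pairwise-complete
per CpG (mappability masks create species-wide missingness);
zero-variance CpGs are emitted with p=1, Z=0 and a flag; p-values below
1e-320 saturate Z at ±Φ⁻¹(1 − 0.5e-320) ≈ ±38.3 with a `saturated` flag.
BH q-values are computed within the stratum only, because per-species
mappability makes a pooled FDR ill-defined.

Strata are combined by the **unweighted Stouffer** method
`Z = Σz/√k` in two stages: tissues within species, then across species.
Strata under 10 samples are excluded. Species too sparse to analyze
individually can be pooled into one pseudo-species before stage 1; a
species assigned to two pools is a configuration error. A CpG absent
from a stratum contributes nothing there and `k` records the strata that
did contribute; a single-stratum tree reduces to the identity.

Top CpG lists take up to 500 CpGs per direction at nominal p < 1e-4,
ordered by p with ties broken by larger |Z| then lexicographic cpg_id
(determinism for testing). List overlaps are scored against the
hypergeometric tail for the shared CpG universe.

## Sex analysis

Within each model cell (species × tissue × age category; default
categories split at 1 year, as neonates behave differently) each CpG is
fit by OLS `beta ~ 1 + age + female`, females coded 1 so
female-hypermethylation is a positive coefficient; the age covariate is
dropped in single-age cells. CpGs with BH q < 0.05 for the sex term are
sex-associated methylation positions (SMPs), counted per model split by
autosome/X/Y and direction; consensus SMPs are significant in at least a
chosen number of models. The pooled sex EWAS runs the same regression
ignoring species and tissue; its default significance threshold (1e-300)
is appropriate for consortium-scale n and must be lowered for desk-scale
data (tests use 1e-8).

The sex predictor is a binomial elastic-net (saga solver, l1_ratio 0.5,
internal stratified CV for the inverse penalty) on the female indicator.
Probabilities come from the logistic link; labels threshold at 0.5 with
an exact tie labeled `unknown`. When the planted signal is X-linked the
selected CpGs concentrate on the X chromosome through selection alone;
an `x_only` mask is available but not required.

## Enrichment

For each region class (promoter, 5'UTR, exon, 3'UTR, intron,
intergenic) the top set is tested against the full array background by a
two-sided Fisher exact test on the 2×2 table {in set vs not} × {in class
vs not}. The odds ratio is the sample cross-product; a Haldane–Anscombe
0.5 correction is applied, and flagged, only when a cell is zero — the
exact p is never corrected. Region classes can be derived from BED-like
gene models (0-based half-open; the TSS of a minus-strand gene is the
interval end) with precedence promoter > 5'UTR > exon > 3'UTR > intron >
intergenic and a configurable strand-aware promoter window defaulting to
5 kb upstream / 1 kb downstream of the TSS.

## The synthetic cohort generator

No public multi-species methylation dataset accompanies this package, so
every analysis is exercised on simulated cohorts whose structure matches
the analyses' assumptions. The generative model is deliberately simple
and fully recorded in the cohort's `truth` record:

- Each CpG has a baseline beta ~ U(0.1, 0.9), perturbed by per-species
  and per-tissue Gaussian logit offsets (defaults 0.5 and 0.3). Real
  cohorts cluster strongly by species and tissue; these signatures are
  what allow a single cross-species elastic net to learn per-species
  intercepts. Without them, a purely relative-age signal makes absolute
  age unidentifiable across species (a pooled linear model is capped
  near R ≈ 0.6 no matter the sample size).
- Age signal is injected on the logit scale as
  `direction × effect_size × effective_age / maxLifespan`, i.e. CpGs
  track *relative* age, shared across tissues or tissue-specific, half
  gaining and half losing methylation. `effective_age` is chronological
  age plus optional animal-level ("fast ager", shared across the
  animal's tissues) and sample-level offsets in years, which create a
  known intraclass correlation of age acceleration across tissues.
- Gaussian logit noise (default sd 0.3) is added before the inverse-link;
  betas are clamped to [0.001, 0.999]. Because the logistic link
  saturates, the beta-scale |r| of planted CpGs rises with effect size
  only up to the operating range (≈3 at this noise level) and declines
  beyond it.
- Sex CpGs (X-linked plus a few autosomal) receive a beta-scale offset
  `±sex_delta` in females; a designated chimeric species has this signal
  erased while keeping its recorded sexes, mimicking species whose blood
  is a cross-sex chimera and whose sex is unpredictable from
  methylation.
- Each animal contributes one sample per tissue at a single age; a
  configurable fraction of animals are fetal with ages uniform on
  (−gestation, 0). Per-species mappability is missing-at-random dropout
  per (CpG, species) (default 5%), realized as NaN betas for that
  species.
- The default species table spans lifespans 16.5–122.5 years with
  anAge-style maturity and gestation constants; defaults elsewhere
  (2000 CpGs, 100 shared age CpGs, effect 3, noise 0.3, 20 animals per
  species across 3 tissues, n = 300) are the recovery conditions used
  throughout the tests.

What the generator does **not** emulate: probe chemistry and
normalization artifacts, batch effects, realistic linkage between
neighboring CpGs, nonlinear age trajectories, or phylogenetic structure
among species. Passing recovery tests therefore demonstrates that the
estimators recover the signal they model, under noise of realistic
magnitude — not that real tissues satisfy the model.

## Problem sizes and numerical choices

Simulations are sized for interactive runs on one core: recovery
cohorts of 300 samples × 2000 CpGs, 100-replicate null calibrations at
100 × 2000, and tenfold sex-predictor CV at n = 200 × 1000. The
elastic-net path uses 50 penalties (5 inverse-penalties × stratified CV
for the classifier); fold seeds derive from explicit seed arguments
everywhere. Ties, degenerate inputs (constant columns, single-sex
strata, zero-variance CpGs, empty top sets) and p-value underflow all
have defined, flagged behavior rather than exceptions wherever a row can
be meaningfully reported.

Known limitations: the relative-age clock reports raw (possibly
out-of-range) relative ages; cross-stratum FDR is deliberately not
offered; the two-stage meta-analysis treats strata as independent, which
ignores that tissues come from the same animals (as unweighted Stouffer
does by construction); and the ANOVA-based intraclass check in the
acceptance tests estimates variance components from the acceleration
table because the clock's own error variance is not known a priori.
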