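# panclock

Multi-species DNA methylation age clocks and the analyses around them:
species-balanced cross-validation, EWAS of age with two-stage Stouffer
meta-analysis, sex-associated methylation analysis and sex prediction,
and gene-region enrichment — with a synthetic-cohort generator so the
entire pipeline runs and is tested without access to consortium data.

## Who this is for

Groups building epigenetic clocks across species (comparative aging,
primate models of anti-aging interventions) need the same small toolbox
again and again: fit an elastic net on transformed age, cross-validate
it without leaking the penalty choice, screen CpGs for age and sex
effects per stratum, combine strata, and test where the top CpGs land in
the genome. `panclock` packages those steps behind one cohort container
(beta matrix + sample sheet + species table + BED-like CpG annotation
with per-species mappability).

## The model

A clock is a sparse linear model on CpG beta values

    F(age) = b0 + Σ_j w_j · beta_j,

fit by elastic net (alpha = 0.5, penalty chosen by internal tenfold CV)
on a transformed age scale `F`: identity, `sqrt(age+1)` (the 1-year
offset admits fetal samples with negative ages), the piecewise
log-linear calibration `log(age+1) − log(m+1)` / `(a−m)/(m+1)` around
the age of sexual maturity `m`, or relative age `age/maxLifespan`.
Accuracy is estimated only out-of-fold, by LOOCV or LOFO10 (tenfold,
every fold containing the same proportion of each species), and
summarized as Pearson R and median absolute error in years. Epigenetic
age acceleration is the residual of DNAm age on age (or the plain
difference), correlated across tissues of the same animals.

The EWAS of age screens each CpG by the Pearson correlation with age per
species-tissue stratum (`t = r√(n−2)/√(1−r²)`, signed
`Z = sign(r)·Φ⁻¹(1−p/2)`), then combines strata with at least 10
samples by the unweighted Stouffer method `Z = Σz/√k` — tissues within
species first, then across species, with sparse species poolable into
one pseudo-class. Sex effects are fit per stratum by OLS
`beta ~ age + female` at 5% FDR; the sex predictor is a binomial
elastic net. Top CpG sets (up to 500 per direction at p < 1e-4) are
tested per gene-region class by two-sided Fisher exact tests against the
array background.

See `docs/methods.md` for assumptions, defaults, and what the synthetic
generator does and does not emulate.

## Worked example

```python
import numpy as np
from panclock import CohortConfig, TransformSpec, run_cv, simulate_cohort

# 5 primate species (lifespans 16.5-122.5 y), 3 tissues from the same
# animals, 100 shared age CpGs, 50 X-linked sex CpGs - the defaults.
cohort = simulate_cohort(CohortConfig(seed=0), n_samples_per_species_tissue=20)

preds, metrics = run_cv(cohort, TransformSpec(kind="sqrt_offset"),
                        scheme="LOFO10", seed=0)
print(metrics[metrics.grouping != "tissue"].to_string(index=False))
```

```
grouping      key   n  pearson_r      mae
 overall      all 300   0.994159 1.498637
 species   baboon  60   0.984090 1.124654
 species    human  60   0.991754 4.052315
 species  macaque  60   0.984187 1.596940
 species marmoset  60   0.966781 0.694086
 species   vervet  60   0.973501 1.384219
```

Every number is an out-of-fold prediction: the overall R of 0.994 says
the species-balanced tenfold CV of the `sqrt(age+1)` clock tracks
chronological age across all five species at once, and the per-species
rows show the same model holds within each species, with the median
absolute error scaling with lifespan (4.1 years for the 122.5-year
human, 0.7 for the 16.5-year marmoset).

The same cohort drives the rest of the pipeline, e.g.:

```python
from panclock import correlation_ewas, select_top_cpgs, two_stage_meta

tables = [correlation_ewas(cohort, species_id=sp, tissue=t)
          for sp in cohort.species_ids()
          for t in ("blood", "cortex", "liver")]
meta = two_stage_meta(tables)                      # N >= 10 strata, Stouffer twice
gains = select_top_cpgs(meta, "gain", max_k=500)   # p < 1e-4, sign(Z) > 0
```

A command-line interface mirrors the library one stage per subcommand
(`panclock simulate | fit-clock | predict | cv | ewas-age | meta |
ewas-sex | fit-sex | enrich | pipeline`); run `panclock --help`.

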