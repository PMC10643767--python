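"""Synthetic methylation cohort generator.

Emulates the statistical structure a multi-species clock/EWAS pipeline
assumes: several species with distinct lifespans, multiple tissues sampled
from the same animals, shared and tissue-specific age-related CpGs (gain
and loss), X-linked (and a few autosomal) sex effects, fetal samples with
negative ages, and per-species CpG mappability masks.

Generative model
----------------
Each CpG has a baseline beta drawn uniformly from [0.1, 0.9], perturbed by
species- and tissue-specific logit offsets (real cohorts cluster strongly
by species and tissue, and cross-species clocks depend on that signature
to calibrate per-species intercepts).  Signal is injected on the logit
scale and inverse-transformed, which keeps betas in (0, 1) and yields the
bounded, heteroskedastic noise typical of methylation arrays::

    logit(mean_ij) = logit(b0_j) + d_j * effect_size * eff_age_i / L(i)
    beta_ij = expit(logit(mean_ij) + N(0, noise_sd))  clipped to [0.001, 0.999]

where ``d_j`` is the planted direction (+1 gain / -1 loss), ``L(i)`` the
sample's species maximum lifespan, and ``eff_age`` the chronological age
plus optional animal-level ("fast ager", shared across tissues of one
animal) and sample-level biological-age offsets.  Sex CpGs receive a
beta-scale offset of ``sex_delta * d_j`` in females; a designated chimeric
species can have this signal erased, mimicking species whose blood is a
cross-sex chimera and whose sex is therefore unpredictable from
methylation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import (
    BETA_CEIL,
    BETA_FLOOR,
    REGION_CLASSES,
    CohortConfig,
    MethylationCohort,
)
from .errors import ConfigurationError

__all__ = ["simulate_cohort", "simulate_null_cohort"]

_REGION_PROBS = np.array([0.15, 0.05, 0.20, 0.05, 0.30, 0.25])
_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
_X_BACKGROUND_RATE = 0.04  # fraction of non-planted CpGs placed on chrX


def _biased_region_probs(bias: float) -> np.ndarray:
    p = _REGION_PROBS.copy()
    prom = min(p[0] * bias, 0.9)
    rest = p[1:] * (1.0 - prom) / p[1:].sum()
    return np.concatenate([[prom], rest])


def simulate_cohort(config: CohortConfig, n_samples_per_species_tissue: int = 20) -> MethylationCohort:
    """Generate a :class:`MethylationCohort` under ``config``.

    ``n_samples_per_species_tissue`` is the number of animals per species
    (each animal contributes one sample per tissue); a species whose spec
    carries ``n_animals > 0`` overrides it.  The same seed always yields a
    bit-identical cohort.
    """
    if n_samples_per_species_tissue < 1:
        raise ConfigurationError("n_samples_per_species_tissue must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_cpgs = config.n_cpgs
    tissues = list(config.tissues)

    # --- planted CpG assignment (indices drawn regardless of effect size,
    #     so changing only magnitudes leaves the random stream intact) ----
    perm = rng.permutation(n_cpgs)
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = perm[pos : pos + k]
        pos += k
        return out

    half = config.n_shared_age_cpgs // 2
    shared_gain = take(config.n_shared_age_cpgs - half)
    shared_loss = take(half)
    tissue_sets = {}
    for t in tissues:
        th = config.n_tissue_age_cpgs // 2
        tissue_sets[t] = {"gain": take(config.n_tissue_age_cpgs - th), "loss": take(th)}
    sex_x = take(config.n_sex_cpgs)
    sex_auto = take(config.n_autosomal_sex_cpgs)
    sex_dirs_x = rng.choice([-1, 1], size=config.n_sex_cpgs)
    sex_dirs_auto = rng.choice([-1, 1], size=config.n_autosomal_sex_cpgs)

    # --- CpG annotation -------------------------------------------------
    cpg_ids = np.array([f"cpg{i:05d}" for i in range(n_cpgs)])
    chrom = rng.choice(_AUTOSOMES, size=n_cpgs)
    background_x = rng.random(n_cpgs) < _X_BACKGROUND_RATE
    chrom[background_x] = "chrX"
    chrom[sex_x] = "chrX"
    chrom[sex_auto] = rng.choice(_AUTOSOMES, size=len(sex_auto))
    position = rng.integers(10_000, 150_000_000, size=n_cpgs)
    region = rng.choice(REGION_CLASSES, size=n_cpgs, p=_REGION_PROBS)
    region[shared_gain] = rng.choice(
        REGION_CLASSES, size=len(shared_gain), p=_biased_region_probs(config.promoter_gain_bias)
    )
    gene = np.array([f"GENE{i // 4:05d}" for i in range(n_cpgs)])
    tss_distance = rng.integers(-5000, 50_000, size=n_cpgs)
    cpgs = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": position,
            "gene": gene,
            "region_class": region,
            "tss_distance": tss_distance,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )

    # per-species mappability dropout (missing at random per CpG x species)
    unmappable = {}
    for sp in config.species:
        drop = rng.random(n_cpgs) < config.mappability_dropout
        unmappable[sp.species_id] = drop
        cpgs[f"mappable_{sp.species_id}"] = ~drop

    # --- sample sheet ---------------------------------------------------
    rows = []
    animal_effects: dict[str, float] = {}
    for sp in config.species:
        n_animals = sp.n_animals or n_samples_per_species_tissue
        sexes = np.array(["F"] * ((n_animals + 1) // 2) + ["M"] * (n_animals // 2))
        sexes = rng.permutation(sexes)
        ages = rng.uniform(0.0, sp.max_lifespan, size=n_animals)
        n_fetal = int(round(config.frac_fetal * n_animals))
        if n_fetal:
            fetal_idx = rng.choice(n_animals, size=n_fetal, replace=False)
            ages[fetal_idx] = rng.uniform(-sp.gestation, 0.0, size=n_fetal)
        u = rng.normal(0.0, config.animal_effect_sd, size=n_animals)
        for i in range(n_animals):
            animal = f"{sp.species_id}_a{i:03d}"
            animal_effects[animal] = float(u[i])
            for t in tissues:
                rows.append(
                    {
                        "sample_id": f"{animal}_{t}",
                        "animal_id": animal,
                        "species_id": sp.species_id,
                        "tissue": t,
                        "age": ages[i],
                        "sex": sexes[i],
                    }
                )
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_s = len(samples)
    sample_effects = rng.normal(0.0, config.sample_effect_sd, size=n_s)

    lifespan = samples["species_id"].map({s.species_id: s.max_lifespan for s in config.species}).to_numpy()
    eff_age = samples["age"].to_numpy() + np.array(
        [animal_effects[a] for a in samples["animal_id"]]
    ) + sample_effects
    rel_age = eff_age / lifespan

    # --- beta matrix ----------------------------------------------------
    # Baselines carry species- and tissue-specific signatures (real cohorts
    # cluster by species and tissue); these let a single cross-species model
    # calibrate per-species offsets, as published multi-species clocks do.
    baseline = rng.uniform(0.1, 0.9, size=n_cpgs)
    species_ids = [sp.species_id for sp in config.species]
    species_offset = rng.normal(0.0, config.species_baseline_sd, size=(len(species_ids), n_cpgs))
    tissue_offset = rng.normal(0.0, config.tissue_baseline_sd, size=(len(tissues), n_cpgs))
    sp_index = {s: i for i, s in enumerate(species_ids)}
    t_index = {t: i for i, t in enumerate(tissues)}
    m = np.tile(logit(baseline), (n_s, 1))
    m += species_offset[[sp_index[s] for s in samples["species_id"]]]
    m += tissue_offset[[t_index[t] for t in samples["tissue"]]]
    if config.effect_size:
        for idx, d in ((shared_gain, 1.0), (shared_loss, -1.0)):
            m[:, idx] += d * config.effect_size * rel_age[:, None]
        tissue_arr = samples["tissue"].to_numpy()
        for t in tissues:
            in_t = tissue_arr == t
            for key, d in (("gain", 1.0), ("loss", -1.0)):
                m[np.ix_(in_t, tissue_sets[t][key])] += d * config.effect_size * rel_age[in_t, None]
    noise = rng.normal(0.0, config.noise_sd, size=(n_s, n_cpgs))
    betas = expit(m + noise)

    if config.sex_delta:
        female = (samples["sex"] == "F").to_numpy()
        if config.chimeric_species is not None:
            female = female & (samples["species_id"] != config.chimeric_species).to_numpy()
        for idx, dirs in ((sex_x, sex_dirs_x), (sex_auto, sex_dirs_auto)):
            betas[np.ix_(female, idx)] += config.sex_delta * dirs

    betas = np.clip(betas, BETA_FLOOR, BETA_CEIL)

    # apply mappability mask: species-wide missingness
    sp_arr = samples["species_id"].to_numpy()
    for sp_id, drop in unmappable.items():
        if drop.any():
            betas[np.ix_(sp_arr == sp_id, drop)] = np.nan

    betas_df = pd.DataFrame(betas, index=samples.index, columns=cpgs.index)

    def _ids(idx) -> list[str]:
        return sorted(cpg_ids[idx].tolist())

    truth = {
        "model": "logit-linear (artifact choice; no generative model is specified for real arrays)",
        "shared_gain": _ids(shared_gain) if config.effect_size else [],
        "shared_loss": _ids(shared_loss) if config.effect_size else [],
        "tissue_age": {
            t: {
                "gain": _ids(tissue_sets[t]["gain"]) if config.effect_size else [],
                "loss": _ids(tissue_sets[t]["loss"]) if config.effect_size else [],
            }
            for t in tissues
        },
        "sex_x": {c: int(d) for c, d in zip(cpg_ids[sex_x], sex_dirs_x)} if config.sex_delta else {},
        "sex_autosomal": {c: int(d) for c, d in zip(cpg_ids[sex_auto], sex_dirs_auto)}
        if config.sex_delta
        else {},
        "animal_effect": {a: float(v) for a, v in animal_effects.items()},
        "sample_effect": {s: float(v) for s, v in zip(samples.index, sample_effects)},
        "params": {
            "effect_size": config.effect_size,
            "sex_delta": config.sex_delta,
            "noise_sd": config.noise_sd,
            "animal_effect_sd": config.animal_effect_sd,
            "sample_effect_sd": config.sample_effect_sd,
            "seed": config.seed,
        },
    }

    return MethylationCohort(
        betas=betas_df,
        samples=samples,
        cpgs=cpgs,
        species_table=list(config.species),
        truth=truth,
    )


def simulate_null_cohort(config: CohortConfig, n_samples_per_species_tissue: int = 20) -> MethylationCohort:
    """Same design as :func:`simulate_cohort` with every effect forced to zero.

    Betas are pure logit-Gaussian noise around per-CpG baselines; the truth
    record carries empty causal sets.  Used for calibration controls.
    """
    return simulate_cohort(config.null(), n_samples_per_species_tissue)
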