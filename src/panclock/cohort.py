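"""Core data containers: species table, simulator configuration, cohort bundle.

A :class:`MethylationCohort` is the universal input of every analysis stage:
a samples x CpGs matrix of methylation beta values (fractions in [0, 1]),
a sample sheet (animal, species, tissue, age in years, sex), a species table
with life-history constants (maximum lifespan, age at sexual maturity,
gestation length), and a BED-like CpG annotation including per-species
mappability flags.  CpGs that do not map to a species' genome are missing
(NaN) for every sample of that species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

BETA_FLOOR = 0.001
BETA_CEIL = 0.999

SEXES = ("F", "M", "unknown")

#: Region classes on the array annotation, in enrichment display order.
REGION_CLASSES = ("promoter", "5'UTR", "exon", "3'UTR", "intron", "intergenic")


@dataclass(frozen=True)
class SpeciesSpec:
    """Life-history constants for one species in the cohort.

    ``max_lifespan`` and ``maturity_age`` are the anAge-style constants the
    relative-age and log-linear transforms consume; ``gestation`` bounds the
    most negative (fetal) age a sample of the species can carry.
    ``n_animals`` > 0 overrides the simulator's per-species animal count.
    """

    species_id: str
    max_lifespan: float
    maturity_age: float
    gestation: float = 0.5
    n_animals: int = 0

    def __post_init__(self) -> None:
        if not self.max_lifespan > 0:
            raise ConfigurationError(f"{self.species_id}: max_lifespan must be > 0")
        if not self.maturity_age > 0:
            raise ConfigurationError(f"{self.species_id}: maturity_age must be > 0")
        if not self.maturity_age < self.max_lifespan:
            raise ConfigurationError(f"{self.species_id}: maturity_age must be < max_lifespan")
        if not 0 < self.gestation < 1:
            raise ConfigurationError(f"{self.species_id}: gestation must lie in (0, 1) years for primates")
        if self.n_animals < 0:
            raise ConfigurationError(f"{self.species_id}: n_animals must be >= 0")


def default_species() -> list[SpeciesSpec]:
    """Five primates spanning the lifespan range of the clade (anAge-style values)."""
    return [
        SpeciesSpec("human", 122.5, 13.5, 0.75),
        SpeciesSpec("baboon", 37.5, 5.5, 0.50),
        SpeciesSpec("macaque", 40.0, 4.5, 0.45),
        SpeciesSpec("vervet", 30.8, 4.0, 0.45),
        SpeciesSpec("marmoset", 16.5, 1.2, 0.40),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    The defaults are the study conditions of the recovery experiments:
    5 species with lifespans from 16.5 to 122.5 years, 3 tissues sampled
    from the same animals, 100 shared age CpGs (half gaining, half losing
    methylation), a logit-scale age slope of 3 per unit relative age,
    logit noise sd 0.3, 50 X-linked sex CpGs with a beta-scale sex offset
    of 0.3, and 5% fetal samples with negative ages.
    """

    species: Sequence[SpeciesSpec] = field(default_factory=default_species)
    tissues: Sequence[str] = ("blood", "cortex", "liver")
    n_cpgs: int = 2000
    n_shared_age_cpgs: int = 100
    n_tissue_age_cpgs: int = 20
    n_sex_cpgs: int = 50
    n_autosomal_sex_cpgs: int = 5
    effect_size: float = 3.0
    sex_delta: float = 0.3
    noise_sd: float = 0.3
    species_baseline_sd: float = 0.5
    tissue_baseline_sd: float = 0.3
    frac_fetal: float = 0.05
    mappability_dropout: float = 0.05
    chimeric_species: Optional[str] = None
    animal_effect_sd: float = 0.0
    sample_effect_sd: float = 0.0
    promoter_gain_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("species_id values must be unique")
        budget = (
            self.n_shared_age_cpgs
            + self.n_tissue_age_cpgs * len(self.tissues)
            + self.n_sex_cpgs
            + self.n_autosomal_sex_cpgs
        )
        if budget > self.n_cpgs:
            raise ConfigurationError(
                f"causal CpG budget {budget} exceeds n_cpgs={self.n_cpgs}"
            )
        for name in ("frac_fetal", "mappability_dropout"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.chimeric_species is not None and self.chimeric_species not in ids:
            raise ConfigurationError(f"chimeric_species {self.chimeric_species!r} not in species table")
        if min(
            self.noise_sd,
            self.animal_effect_sd,
            self.sample_effect_sd,
            self.species_baseline_sd,
            self.tissue_baseline_sd,
        ) < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.promoter_gain_bias <= 0:
            raise ConfigurationError("promoter_gain_bias must be > 0")

    def null(self) -> "CohortConfig":
        """The same design with every planted effect removed."""
        return replace(
            self,
            effect_size=0.0,
            sex_delta=0.0,
            animal_effect_sd=0.0,
            sample_effect_sd=0.0,
            promoter_gain_bias=1.0,
        )


@dataclass
class MethylationCohort:
    """Beta matrix + sample sheet + species table + CpG annotation.

    ``betas``: DataFrame indexed by sample_id, columns cpg_id, values in
    [0.001, 0.999] after clamping; NaN marks a CpG unmappable in the
    sample's species.  ``samples``: DataFrame indexed by sample_id with
    columns animal_id, species_id, tissue, age, sex.  ``cpgs``: DataFrame
    indexed by cpg_id with chrom, pos, gene, region_class, tss_distance
    and one boolean ``mappable_<species_id>`` column per species.
    ``truth`` optionally records the planted causal CpG sets.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    cpgs: pd.DataFrame
    species_table: list[SpeciesSpec]
    truth: Optional[dict] = None

    # ---------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.betas.shape[1]

    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species_table]

    def species(self, species_id: str) -> SpeciesSpec:
        for s in self.species_table:
            if s.species_id == species_id:
                return s
        raise KeyError(f"species {species_id!r} not in species table")

    def lifespan_map(self) -> dict[str, float]:
        return {s.species_id: s.max_lifespan for s in self.species_table}

    def maturity_map(self) -> dict[str, float]:
        return {s.species_id: s.maturity_age for s in self.species_table}

    def subset(self, mask) -> "MethylationCohort":
        """Row-subset by a boolean mask or sample-id index over the sample sheet."""
        sub_samples = self.samples.loc[mask]
        return MethylationCohort(
            betas=self.betas.loc[sub_samples.index],
            samples=sub_samples,
            cpgs=self.cpgs,
            species_table=self.species_table,
            truth=self.truth,
        )

    def mappable_cpgs(self, species_id: str) -> pd.Index:
        col = f"mappable_{species_id}"
        if col not in self.cpgs.columns:
            return self.cpgs.index
        return self.cpgs.index[self.cpgs[col].astype(bool)]

    # ---------------------------------------------------------------
    def validate(self) -> None:
        """Check the cross-table contracts; raise ValidationError on the first breach."""
        if not self.betas.index.equals(self.samples.index):
            raise ValidationError("betas rows and sample sheet are not aligned")
        if not self.betas.columns.equals(self.cpgs.index):
            raise ValidationError("betas columns and CpG annotation are not aligned")
        known = set(self.species_ids())
        stray = set(self.samples["species_id"]) - known
        if stray:
            raise ValidationError(f"samples reference species missing from species table: {sorted(stray)}")
        vals = self.betas.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            bad = np.argwhere((vals < 0) | (vals > 1))
            r, c = bad[0]
            raise ValidationError(
                f"beta value {vals[r, c]} out of [0, 1] at row {r + 1} "
                f"(sample {self.betas.index[r]!r}, CpG {self.betas.columns[c]!r})"
            )
        bad_sex = set(self.samples["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex codes: {sorted(bad_sex)}")
        for s in self.species_table:
            sel = self.samples["species_id"] == s.species_id
            ages = self.samples.loc[sel, "age"]
            if len(ages) and ages.min() < -1:
                raise ValidationError(f"{s.species_id}: age below -1 year is not representable")
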