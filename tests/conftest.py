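import numpy as np
import pandas as pd
import pytest

from panclock import CohortConfig, SpeciesSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One species, one tissue, strong signal; cheap enough for unit tests."""
    cfg = CohortConfig(
        species=[SpeciesSpec("baboon", 37.5, 5.5, 0.5)],
        tissues=["cortex"],
        n_cpgs=300,
        n_shared_age_cpgs=30,
        n_tissue_age_cpgs=0,
        n_sex_cpgs=20,
        n_autosomal_sex_cpgs=2,
        mappability_dropout=0.0,
        frac_fetal=0.0,
        seed=7,
    )
    return simulate_cohort(cfg, 60)


@pytest.fixture(scope="session")
def multi_cohort():
    """Three species, two tissues, mappability dropout; for EWAS/meta tests."""
    cfg = CohortConfig(
        species=[
            SpeciesSpec("human", 122.5, 13.5, 0.75),
            SpeciesSpec("baboon", 37.5, 5.5, 0.5),
            SpeciesSpec("lemur", 18.2, 0.8, 0.2),
        ],
        tissues=["blood", "cortex"],
        n_cpgs=400,
        n_shared_age_cpgs=40,
        n_tissue_age_cpgs=10,
        n_sex_cpgs=20,
        n_autosomal_sex_cpgs=2,
        mappability_dropout=0.05,
        seed=11,
    )
    return simulate_cohort(cfg, 25)


@pytest.fixture()
def toy_genes():
    """Tiny gene-model table for region-class annotation tests."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [10_000, 40_000, 5_000],
            "end": [20_000, 60_000, 9_000],
            "strand": ["+", "-", "+"],
            "gene": ["GA", "GB", "GC"],
            "cds_start": [12_000, 45_000, 5_000],
            "cds_end": [18_000, 55_000, 9_000],
            "exon_starts": ["10000,15000", "40000,50000", "5000"],
            "exon_ends": ["13000,20000", "47000,60000", "9000"],
        }
    )


def pearson(x, y):
    return float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])
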