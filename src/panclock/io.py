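"""Readers and writers for the cohort bundle.

A cohort directory holds ``betas.csv`` (rows = samples, header = CpG ids),
``samples.csv``, ``species.csv``, ``cpgs.bed`` (0-based half-open BED-like
annotation with extra columns gene, region_class, tss_distance and one
mappable_<species> flag per species) and optionally ``truth.json``.  Every
file starts with comment lines recording the package version, the seed
that produced the data and a content hash, for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import MethylationCohort, SpeciesSpec
from .errors import ValidationError

__all__ = ["read_cohort", "write_cohort"]

BED_CORE = ["chrom", "start", "end", "cpg_id", "gene", "region_class", "tss_distance"]


def _provenance(seed: Optional[int], payload: str) -> str:
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    return f"# panclock v{__version__} seed={seed if seed is not None else 'NA'} sha256={digest}\n"


def _write_with_header(path: Path, body: str, seed: Optional[int]) -> None:
    path.write_text(_provenance(seed, body) + body)


def write_table(df: pd.DataFrame, path, seed: Optional[int] = None, sep: str = ",", index_label=None) -> None:
    """Write a DataFrame with a leading provenance comment line."""
    body = df.to_csv(sep=sep, index_label=index_label) if index_label else df.to_csv(sep=sep, index=False)
    _write_with_header(Path(path), body, seed)


def write_cohort(cohort: MethylationCohort, out_dir, seed: Optional[int] = None, decimals: Optional[int] = None) -> None:
    """Write the bundle to ``out_dir``.

    ``decimals`` optionally rounds betas (e.g. 6 for compact files); the
    default writes full precision so a read-back is value-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    betas = cohort.betas if decimals is None else cohort.betas.round(decimals)
    _write_with_header(out / "betas.csv", betas.to_csv(index_label="sample_id"), seed)
    _write_with_header(out / "samples.csv", cohort.samples.to_csv(index_label="sample_id"), seed)

    species = pd.DataFrame([s.__dict__ for s in cohort.species_table])
    _write_with_header(out / "species.csv", species.to_csv(index=False), seed)

    ann = cohort.cpgs.reset_index()
    bed = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": ann["pos"],
            "end": ann["pos"] + 1,
            "cpg_id": ann["cpg_id"],
            "gene": ann["gene"],
            "region_class": ann["region_class"],
            "tss_distance": ann["tss_distance"],
        }
    )
    for col in ann.columns:
        if col.startswith("mappable_"):
            bed[col] = ann[col].astype(int)
    _write_with_header(out / "cpgs.bed", bed.to_csv(sep="\t", index=False), seed)

    if cohort.truth is not None:
        (out / "truth.json").write_text(json.dumps(cohort.truth, indent=1, sort_keys=True))


def read_cohort(in_dir) -> MethylationCohort:
    """Read a cohort bundle; validation errors name the offending rows."""
    d = Path(in_dir)
    for fname in ("betas.csv", "samples.csv", "species.csv", "cpgs.bed"):
        if not (d / fname).exists():
            raise ValidationError(f"cohort directory {d} is missing {fname}")

    betas = pd.read_csv(d / "betas.csv", comment="#", index_col="sample_id")
    samples = pd.read_csv(d / "samples.csv", comment="#", index_col="sample_id")
    species_df = pd.read_csv(d / "species.csv", comment="#")
    bed = pd.read_csv(d / "cpgs.bed", comment="#", sep="\t")

    vals = betas.to_numpy(dtype=float)
    bad = np.argwhere((vals < 0) | (vals > 1))
    if len(bad):
        r, c = bad[0]
        raise ValidationError(
            f"beta value {vals[r, c]} out of [0, 1] in betas.csv row {r + 1} "
            f"(sample {betas.index[r]!r}, CpG {betas.columns[c]!r})"
        )
    missing_sheet = betas.index.difference(samples.index)
    if len(missing_sheet):
        raise ValidationError(f"samples present in betas.csv but missing from samples.csv: {list(missing_sheet[:5])}")
    samples = samples.loc[betas.index]

    species_table = [
        SpeciesSpec(
            species_id=row["species_id"],
            max_lifespan=float(row["max_lifespan"]),
            maturity_age=float(row["maturity_age"]),
            gestation=float(row.get("gestation", 0.5)),
            n_animals=int(row.get("n_animals", 0)),
        )
        for _, row in species_df.iterrows()
    ]

    cpgs = pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "pos": bed["start"].to_numpy(),
            "gene": bed["gene"].to_numpy(),
            "region_class": bed["region_class"].to_numpy(),
            "tss_distance": bed["tss_distance"].to_numpy(),
        },
        index=pd.Index(bed["cpg_id"], name="cpg_id"),
    )
    for col in bed.columns:
        if col.startswith("mappable_"):
            cpgs[col] = bed[col].astype(bool).to_numpy()
    cpgs = cpgs.loc[betas.columns]

    truth = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())

    cohort = MethylationCohort(
        betas=betas, samples=samples, cpgs=cpgs, species_table=species_table, truth=truth
    )
    cohort.validate()
    return cohort
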