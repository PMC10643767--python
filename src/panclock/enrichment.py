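"""Gene-region-class enrichment of top CpG sets against the array background.

For each region class (promoter, 5'UTR, exon, 3'UTR, intron, intergenic)
a 2x2 table {in top set vs not} x {in class vs not} is formed over the
full CpG background; the odds ratio is the sample cross-product of the
table and the p-value a two-sided Fisher exact test.  Region classes can
also be derived from BED-like gene models with the deterministic
precedence promoter > 5'UTR > exon > 3'UTR > intron > intergenic, using a
strand-aware promoter window (default 5 kb upstream to 1 kb downstream of
the TSS).  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import REGION_CLASSES

__all__ = ["EnrichmentRow", "region_enrichment", "annotate_region_class", "significance_stars"]

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star codes at 0.05 / 0.01 / 0.001 / 0.0001, figure-legend style."""
    for cut, stars in _STAR_LEVELS:
        if p < cut:
            return stars
    return ""


@dataclass
class EnrichmentRow:
    region_class: str
    direction: str
    count_in_set: int
    count_in_background: int
    odds_ratio: float
    fisher_p: float
    stars: str
    zero_cell_corrected: bool = False


def region_enrichment(
    top_cpgs: Sequence[str],
    annotation: pd.DataFrame,
    background: Iterable[str] | None = None,
    direction: str = "gain",
) -> list[EnrichmentRow]:
    """Fisher-exact enrichment of ``top_cpgs`` per region class.

    ``annotation`` must carry a ``region_class`` column indexed by cpg_id;
    ``background`` defaults to every annotated CpG (the array universe).
    Odds ratios are the cross-product of the 2x2 table; a Haldane-Anscombe
    0.5 correction is applied (and flagged) only when reporting the odds
    ratio of a table with a zero cell — the exact p is unaffected.
    """
    bg = pd.Index(background) if background is not None else annotation.index
    top = pd.Index(top_cpgs)
    if len(top) == 0:
        warnings.warn("empty top-CpG set; no enrichment computed")
        return []
    stray = top.difference(bg)
    if len(stray):
        raise ValueError(f"top CpGs not in background: {list(stray[:5])}")
    classes = annotation["region_class"].reindex(bg)
    in_top = bg.isin(top)
    rows = []
    for rc in REGION_CLASSES:
        in_class = (classes == rc).to_numpy()
        a = int((in_top & in_class).sum())  # top & class
        b = int((in_top & ~in_class).sum())  # top, other class
        c = int((~in_top & in_class).sum())  # background rest & class
        d = int((~in_top & ~in_class).sum())
        corrected = False
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        else:
            aa, bb, cc, dd = a, b, c, d
        odds = (aa * dd) / (bb * cc)
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append(
            EnrichmentRow(
                region_class=rc,
                direction=direction,
                count_in_set=a,
                count_in_background=a + c,
                odds_ratio=float(odds),
                fisher_p=p,
                stars=significance_stars(p),
                zero_cell_corrected=corrected,
            )
        )
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# ----------------------------------------------------------------------
# region-class annotation from gene models
# ----------------------------------------------------------------------

def annotate_region_class(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_upstream: int = 5000,
    promoter_downstream: int = 1000,
) -> pd.Series:
    """Classify CpG positions against BED-like gene models.

    ``cpgs`` needs ``chrom`` and ``pos`` columns (0-based positions);
    ``genes`` needs ``chrom, start, end, strand, cds_start, cds_end`` and
    exon blocks as ``exon_starts``/``exon_ends`` (comma-joined strings or
    sequences).  The promoter window extends ``promoter_upstream`` bases
    upstream to ``promoter_downstream`` downstream of the strand-aware
    TSS (the interval end for minus-strand genes).  When a CpG overlaps
    several features, the highest-precedence class wins:
    promoter > 5'UTR > exon > 3'UTR > intron > intergenic.  CpGs on
    contigs absent from the gene models are intergenic.
    """
    precedence = {rc: i for i, rc in enumerate(REGION_CLASSES)}
    gene_contigs = set(genes["chrom"])

    def _blocks(v):
        if isinstance(v, str):
            return [int(x) for x in v.split(",") if x != ""]
        return [int(x) for x in v]

    out = []
    for cpg_id, row in cpgs.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        best = "intergenic"
        if chrom in gene_contigs:
            for _, g in genes[genes["chrom"] == chrom].iterrows():
                cls = _classify_against_gene(pos, g, promoter_upstream, promoter_downstream, _blocks)
                if cls is not None and precedence[cls] < precedence[best]:
                    best = cls
        out.append(best)
    return pd.Series(out, index=cpgs.index, name="region_class")


def _classify_against_gene(pos, g, up, down, blocks):
    start, end = int(g["start"]), int(g["end"])
    strand = g.get("strand", "+")
    if strand == "+":
        prom_lo, prom_hi = start - up, start + down
    else:
        prom_lo, prom_hi = end - down, end + up
    if prom_lo <= pos < prom_hi:
        return "promoter"
    if not (start <= pos < end):
        return None
    cds_start, cds_end = int(g["cds_start"]), int(g["cds_end"])
    exon_starts, exon_ends = blocks(g["exon_starts"]), blocks(g["exon_ends"])
    in_exon = any(s <= pos < e for s, e in zip(exon_starts, exon_ends))
    if not in_exon:
        return "intron"
    if cds_start >= cds_end:  # non-coding: treat the whole exon as exon
        return "exon"
    if pos < cds_start:
        return "5'UTR" if strand == "+" else "3'UTR"
    if pos >= cds_end:
        return "3'UTR" if strand == "+" else "5'UTR"
    return "exon"
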