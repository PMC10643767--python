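"""Fisher enrichment against an exact hypergeometric oracle; region annotation."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from panclock import CohortConfig, SpeciesSpec, annotate_region_class, region_enrichment, simulate_cohort
from panclock.enrichment import significance_stars


def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating the hypergeometric support.

    Sums P(k) over all tables with the same margins whose probability does
    not exceed that of the observed table.
    """
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)

    p_obs = pmf(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-10))


def _annotation(classes):
    return pd.DataFrame(
        {"region_class": classes},
        index=pd.Index([f"c{i}" for i in range(len(classes))], name="cpg_id"),
    )


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 100, 4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        classes = ["promoter"] * (a + c) + ["intron"] * (b + d)
        ann = _annotation(classes)
        top = list(ann.index[:a]) + list(ann.index[a + c : a + c + b])
        if not top:
            continue
        rows = region_enrichment(top, ann)
        row = next(r for r in rows if r.region_class == "promoter")
        assert row.count_in_set == a
        oracle = fisher_two_sided_oracle(a, b, c, d)
        assert row.fisher_p == pytest.approx(oracle, abs=1e-12)


def test_odds_ratio_cross_product():
    """Table [[10,490],[490,19010]] -> OR = 10*19010/(490*490) ~ 0.792."""
    classes = ["promoter"] * 500 + ["intron"] * 19500
    ann = _annotation(classes)
    top = list(ann.index[:10]) + list(ann.index[500:990])
    rows = region_enrichment(top, ann)
    row = next(r for r in rows if r.region_class == "promoter")
    assert row.count_in_set == 10
    assert row.odds_ratio == pytest.approx((10 * 19010) / (490 * 490), rel=1e-12)
    assert row.fisher_p == pytest.approx(fisher_two_sided_oracle(10, 490, 490, 19010), abs=1e-12)


def test_uniform_top_set_is_unenriched():
    rng = np.random.default_rng(8)
    classes = rng.choice(["promoter", "exon", "intron", "intergenic"], size=5000, p=[0.15, 0.2, 0.4, 0.25])
    ann = _annotation(classes)
    top = rng.choice(ann.index, 400, replace=False)
    rows = region_enrichment(list(top), ann)
    ors = [r.odds_ratio for r in rows if r.count_in_background > 0]
    assert all(0.5 < o < 2.0 for o in ors)
    assert np.mean([r.fisher_p > 0.05 for r in rows if r.count_in_background > 0]) >= 0.75


def test_counts_partition_top_set():
    rng = np.random.default_rng(9)
    classes = rng.choice(["promoter", "exon", "intron"], size=1000)
    ann = _annotation(classes)
    top = list(rng.choice(ann.index, 100, replace=False))
    rows = region_enrichment(top, ann)
    assert sum(r.count_in_set for r in rows) == 100


def test_zero_cell_haldane_flag():
    classes = ["promoter"] * 10 + ["intron"] * 90
    ann = _annotation(classes)
    top = list(ann.index[:5])  # all promoter -> zero cell b
    rows = region_enrichment(top, ann)
    row = next(r for r in rows if r.region_class == "promoter")
    assert row.zero_cell_corrected
    # a=5, b=0, c=5, d=90 -> corrected cross-product (5.5*90.5)/(0.5*5.5)
    assert row.odds_ratio == pytest.approx((5.5 * 90.5) / (0.5 * 5.5))


def test_empty_top_set_warns():
    ann = _annotation(["exon"] * 10)
    with pytest.warns(UserWarning, match="empty"):
        assert region_enrichment([], ann) == []


def test_top_cpg_outside_background_rejected():
    ann = _annotation(["exon"] * 10)
    with pytest.raises(ValueError, match="not in background"):
        region_enrichment(["zzz"], ann)


def test_promoter_biased_gains_recover_enrichment():
    cfg = CohortConfig(
        species=[SpeciesSpec("baboon", 37.5, 5.5, 0.5)],
        tissues=["cortex"],
        n_cpgs=2000,
        n_shared_age_cpgs=200,
        n_tissue_age_cpgs=0,
        n_sex_cpgs=10,
        n_autosomal_sex_cpgs=0,
        promoter_gain_bias=4.0,
        mappability_dropout=0.0,
        seed=21,
    )
    co = simulate_cohort(cfg, 60)
    rows = region_enrichment(co.truth["shared_gain"], co.cpgs)
    prom = next(r for r in rows if r.region_class == "promoter")
    assert prom.odds_ratio > 3
    assert prom.fisher_p < 1e-4
    assert prom.stars == "****"


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(1e-6) == "****"


# -------------------- region-class annotation --------------------


def brute_force_classify(pos, chrom, genes, up=5000, down=1000):
    """Exhaustive interval-membership scan, highest precedence wins."""
    order = ["promoter", "5'UTR", "exon", "3'UTR", "intron", "intergenic"]
    hits = []
    for _, g in genes.iterrows():
        if g["chrom"] != chrom:
            continue
        s, e, strand = g["start"], g["end"], g["strand"]
        tss_lo, tss_hi = (s - up, s + down) if strand == "+" else (e - down, e + up)
        if tss_lo <= pos < tss_hi:
            hits.append("promoter")
        if s <= pos < e:
            ex_s = [int(x) for x in str(g["exon_starts"]).split(",")]
            ex_e = [int(x) for x in str(g["exon_ends"]).split(",")]
            if any(a <= pos < b for a, b in zip(ex_s, ex_e)):
                if pos < g["cds_start"]:
                    hits.append("5'UTR" if strand == "+" else "3'UTR")
                elif pos >= g["cds_end"]:
                    hits.append("3'UTR" if strand == "+" else "5'UTR")
                else:
                    hits.append("exon")
            else:
                hits.append("intron")
    return min(hits, key=order.index) if hits else "intergenic"


def test_annotation_examples(toy_genes):
    cpgs = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr1", "chr3"],
            "pos": [8000, 16_000, 14_000, 59_500, 100],
        },
        index=pd.Index(["p1", "p2", "p3", "p4", "p5"], name="cpg_id"),
    )
    classes = annotate_region_class(cpgs, toy_genes)
    assert classes["p1"] == "promoter"  # 2 kb upstream of + strand TSS
    assert classes["p2"] == "exon"  # inside CDS exon, beyond promoter window
    assert classes["p3"] == "intron"  # between exon blocks
    assert classes["p4"] == "promoter"  # within 1 kb of - strand TSS (gene end)
    assert classes["p5"] == "intergenic"  # contig absent from gene models


def test_annotation_matches_brute_force(toy_genes):
    rng = np.random.default_rng(10)
    positions = rng.integers(0, 70_000, 300)
    chroms = rng.choice(["chr1", "chr2", "chr9"], 300)
    cpgs = pd.DataFrame(
        {"chrom": chroms, "pos": positions},
        index=pd.Index([f"r{i}" for i in range(300)], name="cpg_id"),
    )
    got = annotate_region_class(cpgs, toy_genes)
    for cpg_id, row in cpgs.iterrows():
        assert got[cpg_id] == brute_force_classify(row["pos"], row["chrom"], toy_genes), cpg_id
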