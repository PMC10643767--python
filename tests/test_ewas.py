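"""Correlation EWAS, Stouffer combination, top-list selection and overlap.

The screening statistics are cross-checked against scipy.stats.pearsonr
(an independent code path through the beta distribution) and the two-stage
meta-analysis against a brute-force tree traversal written here.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panclock import (
    EwasTable,
    MetaResult,
    correlation_ewas,
    overlap_top_lists,
    select_top_cpgs,
    stouffer,
    two_stage_meta,
)
from panclock.errors import ConfigurationError


def test_t_statistic_closed_form():
    """n=12, r=0.6 -> t = r sqrt(n-2)/sqrt(1-r^2) = 2.3717."""
    r, n = 0.6, 12
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    assert t == pytest.approx(2.3717, abs=1e-4)
    p = 2 * stats.t.sf(t, n - 2)
    z = stats.norm.isf(p / 2)
    assert p == pytest.approx(0.0391629, abs=1e-6)
    assert z == pytest.approx(2.0624714, abs=1e-6)


def test_ewas_matches_pearsonr_oracle(small_cohort):
    table = correlation_ewas(small_cohort, species_id="baboon", tissue="cortex").stats
    age = small_cohort.samples["age"].to_numpy()
    rng = np.random.default_rng(0)
    sample = rng.choice(table.index, size=100, replace=False)
    for cpg in sample:
        res = stats.pearsonr(small_cohort.betas[cpg], age)
        assert table.loc[cpg, "r"] == pytest.approx(res.statistic, abs=1e-10)
        assert table.loc[cpg, "p"] == pytest.approx(res.pvalue, abs=1e-10)
        z = np.sign(res.statistic) * stats.norm.isf(res.pvalue / 2)
        assert table.loc[cpg, "Z"] == pytest.approx(z, abs=1e-8)


def test_ewas_sign_convention_follows_direction(small_cohort):
    table = correlation_ewas(small_cohort, species_id="baboon", tissue="cortex").stats
    truth = small_cohort.truth
    gains = table.loc[[c for c in truth["shared_gain"] if c in table.index]]
    losses = table.loc[[c for c in truth["shared_loss"] if c in table.index]]
    assert (gains["Z"] > 0).mean() > 0.95
    assert (losses["Z"] < 0).mean() > 0.95


def test_zero_variance_cpg_flagged(small_cohort):
    co = small_cohort
    betas = co.betas.copy()
    betas.iloc[:, 0] = 0.5
    import panclock

    co2 = panclock.MethylationCohort(betas, co.samples, co.cpgs, co.species_table)
    table = correlation_ewas(co2, species_id="baboon", tissue="cortex").stats
    row = table.iloc[0]
    assert row["flag"] == "zero_variance"
    assert row["p"] == 1.0 and row["Z"] == 0.0


def test_perfect_correlation_saturates():
    rng = np.random.default_rng(2)
    n = 200
    ages = rng.uniform(0, 30, n)
    import panclock

    betas = pd.DataFrame(
        {"cpgA": (ages - ages.min()) / (ages.max() - ages.min()) * 0.9 + 0.05, "cpgB": rng.uniform(0.2, 0.8, n)},
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    samples = pd.DataFrame(
        {"animal_id": betas.index, "species_id": "x", "tissue": "t", "age": ages, "sex": "F"},
        index=betas.index,
    )
    cpgs = pd.DataFrame(
        {"chrom": "chr1", "pos": [1, 2], "gene": "G", "region_class": "exon", "tss_distance": 0},
        index=pd.Index(["cpgA", "cpgB"], name="cpg_id"),
    )
    co = panclock.MethylationCohort(betas, samples, cpgs, [panclock.SpeciesSpec("x", 30.0, 3.0)])
    table = correlation_ewas(co).stats
    assert table.loc["cpgA", "flag"] == "saturated"
    assert np.isfinite(table.loc["cpgA", "Z"])
    assert table.loc["cpgA", "Z"] > 35


def test_mappability_skips_cpgs(multi_cohort):
    sp = multi_cohort.species_ids()[0]
    table = correlation_ewas(multi_cohort, species_id=sp, tissue="blood").stats
    unmappable = multi_cohort.cpgs.index[~multi_cohort.cpgs[f"mappable_{sp}"]]
    assert len(set(table.index) & set(unmappable)) == 0


# -------------------- Stouffer --------------------


def test_stouffer_closed_forms():
    z, p = stouffer([1.96, 1.96])
    assert z == pytest.approx(3.92 / np.sqrt(2), abs=1e-10)
    assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-15)
    z1, _ = stouffer([2.5])
    assert z1 == 2.5
    with pytest.raises(ValueError):
        stouffer([])
    with pytest.raises(ValueError):
        stouffer([1.0, np.inf])


def test_stouffer_null_is_standard_normal():
    rng = np.random.default_rng(3)
    k = 7
    zs = rng.standard_normal((1000, k))
    metas = zs.sum(axis=1) / np.sqrt(k)
    computed = [stouffer(row)[0] for row in zs]
    np.testing.assert_allclose(computed, metas, atol=1e-12)
    assert stats.kstest(metas, "norm").pvalue > 0.01


def _table(sp, tissue, cpgs, zs, n=30):
    df = pd.DataFrame(
        {"n": n, "r": 0.0, "t": 0.0, "p": 2 * stats.norm.sf(np.abs(zs)), "Z": zs, "q": 1.0, "flag": ""},
        index=pd.Index(cpgs, name="cpg_id"),
    )
    return EwasTable(species_id=sp, tissue=tissue, n_samples=n, stats=df)


def _brute_force_two_stage(tables, pools):
    """Independent traversal: explicit loops over the species/tissue tree."""
    group = {}
    for t in tables:
        g = next((name for name, members in pools.items() if t.species_id in members), t.species_id)
        group.setdefault(g, []).append(t)
    cpg_ids = sorted(set().union(*[set(t.stats.index) for t in tables]))
    out = {}
    for cpg in cpg_ids:
        stage1 = []
        k_total = 0
        for g, members in group.items():
            zs = [t.stats.loc[cpg, "Z"] for t in members if cpg in t.stats.index]
            if zs:
                stage1.append(sum(zs) / np.sqrt(len(zs)))
                k_total += len(zs)
        if stage1:
            out[cpg] = (sum(stage1) / np.sqrt(len(stage1)), k_total)
    return out


def test_two_stage_single_stratum_identity():
    t = _table("a", "t1", ["c1", "c2"], np.array([1.5, -2.0]))
    res = two_stage_meta([t])
    assert res.stats.loc["c1", "Z_meta"] == pytest.approx(1.5)
    assert res.stats.loc["c2", "Z_meta"] == pytest.approx(-2.0)
    assert (res.stats["k"] == 1).all()


def test_two_stage_equal_z_chain():
    """Two species x two tissues all at Z=z combine to exactly 2z."""
    z = 1.3
    tables = [_table(sp, t, ["c"], np.array([z])) for sp in ("a", "b") for t in ("t1", "t2")]
    res = two_stage_meta(tables)
    assert res.stats.loc["c", "Z_meta"] == pytest.approx(2 * z, abs=1e-12)
    assert res.stats.loc["c", "k"] == 4


def test_two_stage_matches_brute_force():
    rng = np.random.default_rng(4)
    cpg_pool = [f"c{i}" for i in range(40)]
    tables = []
    for sp in ("a", "b", "lemur1", "lemur2"):
        for tissue in ("t1", "t2", "t3"):
            cpgs = sorted(rng.choice(cpg_pool, size=30, replace=False))
            tables.append(_table(sp, tissue, cpgs, rng.standard_normal(len(cpgs))))
    pools = {"lemur": {"lemur1", "lemur2"}}
    res = two_stage_meta(tables, pooled_species=pools)
    brute = _brute_force_two_stage(tables, pools)
    assert set(res.stats.index) == set(brute)
    for cpg, (z, k) in brute.items():
        assert res.stats.loc[cpg, "Z_meta"] == pytest.approx(z, abs=1e-10)
        assert res.stats.loc[cpg, "k"] == k


def test_two_stage_excludes_small_strata():
    big = _table("a", "t1", ["c"], np.array([2.0]), n=30)
    small = _table("a", "t2", ["c"], np.array([5.0]), n=9)
    res = two_stage_meta([big, small])
    assert res.stats.loc["c", "Z_meta"] == pytest.approx(2.0)
    assert ("a", "t2", 9) not in res.tree["a"]


def test_two_stage_order_invariance():
    rng = np.random.default_rng(5)
    tables = [_table(sp, t, ["c"], rng.standard_normal(1)) for sp in "abc" for t in ("t1", "t2")]
    z1 = two_stage_meta(tables).stats.loc["c", "Z_meta"]
    z2 = two_stage_meta(tables[::-1]).stats.loc["c", "Z_meta"]
    assert z1 == pytest.approx(z2, abs=1e-12)


def test_overlapping_pools_rejected():
    t = _table("a", "t1", ["c"], np.array([1.0]))
    with pytest.raises(ConfigurationError, match="more than one pool"):
        two_stage_meta([t], pooled_species={"g1": {"a"}, "g2": {"a"}})


# -------------------- top lists --------------------


def _meta_from(z, p, cpgs):
    df = pd.DataFrame({"k": 1, "Z_meta": z, "p_meta": p}, index=pd.Index(cpgs, name="cpg_id"))
    return MetaResult(stats=df, tree={})


def test_select_top_empty_when_nothing_passes():
    res = _meta_from([1.0, -1.0], [0.3, 0.3], ["c1", "c2"])
    assert select_top_cpgs(res, "gain") == []


def test_select_top_truncates_at_max_k():
    n = 600
    z = np.linspace(5, 10, n)
    p = 2 * stats.norm.sf(z)
    res = _meta_from(z, p, [f"c{i:03d}" for i in range(n)])
    top = select_top_cpgs(res, "gain", max_k=500)
    assert len(top) == 500
    # the 500 smallest p = the 500 largest Z = the last 500 ids
    assert set(top) == {f"c{i:03d}" for i in range(100, 600)}
    assert top[0] == "c599"


def test_select_top_direction_and_ties():
    res = _meta_from([3.0, -3.0, 3.0], [1e-5, 1e-5, 1e-5], ["cB", "cC", "cA"])
    top = select_top_cpgs(res, "gain", p_threshold=1e-4)
    assert top == ["cA", "cB"]  # equal p and |Z| -> lexicographic
    assert select_top_cpgs(res, "loss", p_threshold=1e-4) == ["cC"]


def test_overlap_identical_and_disjoint():
    a = [f"c{i}" for i in range(500)]
    b = [f"d{i}" for i in range(500)]
    k, p = overlap_top_lists(a, a, universe_size=20000)
    assert k == 500 and p < 1e-300
    k, p = overlap_top_lists(a, b, universe_size=20000)
    assert k == 0 and p == pytest.approx(1.0, abs=1e-9)


def test_overlap_random_lists_near_hypergeometric_mean():
    rng = np.random.default_rng(6)
    universe = np.array([f"c{i}" for i in range(20000)])
    a = rng.choice(universe, 500, replace=False)
    b = rng.choice(universe, 500, replace=False)
    k, _ = overlap_top_lists(a, b, universe_size=20000)
    mean = 500 * 500 / 20000  # 12.5
    var = stats.hypergeom(20000, 500, 500).var()
    assert abs(k - mean) <= 3 * np.sqrt(var)


def test_overlap_duplicates_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        overlap_top_lists(["c1", "c1"], ["c2"], universe_size=10)
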