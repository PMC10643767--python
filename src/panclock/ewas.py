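"""Correlation EWAS of age and Stouffer meta-analysis.

Per stratum (one species x tissue), each CpG is screened by the Pearson
correlation of its beta values with age: ``t = r*sqrt(n-2)/sqrt(1-r^2)``,
two-sided p from the t distribution with n-2 degrees of freedom, and a
signed Z score ``sign(r) * qnorm(1 - p/2)`` which is standard normal under
the null of zero correlation.  Positive Z means age-related gain of
methylation, negative Z loss.  Strata are combined with the unweighted
Stouffer method ``Z_meta = sum(z)/sqrt(k)``, in two stages: across tissues
within a species, then across species; strata with fewer than 10 samples
are excluded, and species too sparse to analyze alone (the lemur case) can
be pooled into one pseudo-species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import MethylationCohort
from .errors import ConfigurationError, ValidationError

__all__ = [
    "EwasTable",
    "MetaResult",
    "correlation_ewas",
    "stouffer",
    "two_stage_meta",
    "select_top_cpgs",
    "overlap_top_lists",
]

#: p-values are floored here before conversion to Z, with a saturation flag.
P_FLOOR = 1e-320
Z_CAP = float(stats.norm.isf(P_FLOOR / 2))
MIN_META_STRATUM_N = 10


@dataclass
class EwasTable:
    """Per-CpG age-correlation statistics for one (species, tissue) stratum.

    ``stats`` is indexed by cpg_id with columns n, r, t, p, Z, q, flag
    (flag marks zero-variance CpGs and saturated p-values).
    """

    species_id: str
    tissue: str
    n_samples: int
    stats: pd.DataFrame


@dataclass
class MetaResult:
    """Combined Z/p per CpG plus the stratification tree that produced it."""

    stats: pd.DataFrame  # index cpg_id; columns k, Z_meta, p_meta
    tree: dict  # species/group -> list of (species_id, tissue, n)


def _pairwise_pearson(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r of each column of X with y; returns (r, n)."""
    mask = ~np.isnan(X)
    Xz = np.where(mask, X, 0.0)
    n = mask.sum(axis=0).astype(float)
    sy = mask.T @ y
    sy2 = mask.T @ (y * y)
    sx = Xz.sum(axis=0)
    sx2 = (Xz * Xz).sum(axis=0)
    sxy = Xz.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sx2 - sx * sx
        vary = n * sy2 - sy * sy
        r = cov / np.sqrt(varx * vary)
    r[(varx <= 0) | (vary <= 0)] = np.nan
    return r, n


def correlation_ewas(
    cohort: MethylationCohort,
    species_id: Optional[str] = None,
    tissue: Optional[str] = None,
    min_n: int = 4,
) -> EwasTable:
    """Screen every mappable CpG for correlation with age in one stratum.

    CpGs unmappable in the stratum's species are skipped; CpGs with fewer
    than ``min_n`` pairwise-complete samples are dropped from the table.
    Zero-variance CpGs are emitted with r undefined, p=1, Z=0 and the flag
    ``zero_variance``; p-values below the floating floor saturate Z at
    +/-``Z_CAP`` with the flag ``saturated``.
    """
    sel = pd.Series(True, index=cohort.samples.index)
    if species_id is not None:
        sel &= cohort.samples["species_id"] == species_id
    if tissue is not None:
        sel &= cohort.samples["tissue"] == tissue
    sub = cohort.subset(sel)

    cols = cohort.betas.columns
    if species_id is not None:
        cols = sub.mappable_cpgs(species_id)
    X = sub.betas[cols].to_numpy(dtype=float)
    y = sub.samples["age"].to_numpy(dtype=float)

    r, n = _pairwise_pearson(X, y)
    tested = n >= min_n
    cols = cols[tested]
    r, n = r[tested], n[tested]

    zero_var = np.isnan(r)
    r_safe = np.where(zero_var, 0.0, r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_safe * np.sqrt(n - 2) / np.sqrt(1 - r_safe**2)
        t = np.where(np.abs(r_safe) >= 1, np.sign(r_safe) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[zero_var] = 1.0
    saturated = p < P_FLOOR
    p_eff = np.maximum(p, P_FLOOR)
    Z = np.sign(r_safe) * stats.norm.isf(p_eff / 2)
    Z[zero_var] = 0.0
    Z = np.clip(Z, -Z_CAP, Z_CAP)
    q = multipletests(np.minimum(p_eff, 1.0), method="fdr_bh")[1] if len(p) else np.array([])

    flag = np.where(zero_var, "zero_variance", np.where(saturated, "saturated", ""))
    table = pd.DataFrame(
        {
            "n": n.astype(int),
            "r": np.where(zero_var, np.nan, r),
            "t": np.where(zero_var, np.nan, t),
            "p": np.minimum(p_eff, 1.0),
            "Z": Z,
            "q": q,
            "flag": flag,
        },
        index=pd.Index(cols, name="cpg_id"),
    )
    return EwasTable(
        species_id=species_id or "all",
        tissue=tissue or "all",
        n_samples=len(sub.samples),
        stats=table,
    )


def stouffer(z_values) -> tuple[float, float]:
    """Unweighted Stouffer combination: ``Z = sum(z)/sqrt(k)``, two-sided p."""
    z = np.asarray(list(z_values), dtype=float)
    if z.size == 0:
        raise ValueError("stouffer requires at least one Z score")
    if not np.all(np.isfinite(z)):
        raise ValueError("stouffer requires finite Z scores")
    Z = float(z.sum() / np.sqrt(z.size))
    p = float(2 * stats.norm.sf(abs(Z)))
    return Z, p


def _normalize_pools(pooled_species) -> dict[str, set]:
    if pooled_species is None:
        return {}
    if isinstance(pooled_species, Mapping):
        pools = {g: set(v) for g, v in pooled_species.items()}
    else:
        pooled_species = set(pooled_species)
        pools = {"pooled": pooled_species} if pooled_species else {}
    seen: set = set()
    for g, members in pools.items():
        overlap = seen & members
        if overlap:
            raise ConfigurationError(f"species {sorted(overlap)} assigned to more than one pool")
        seen |= members
    return pools


def two_stage_meta(
    tables: Iterable[EwasTable],
    pooled_species: Union[None, set, Mapping[str, set]] = None,
    min_stratum_n: int = MIN_META_STRATUM_N,
) -> MetaResult:
    """Two-stage unweighted Stouffer meta-analysis over (species, tissue) strata.

    Stage 1 combines tissues within each species (species in
    ``pooled_species`` are first merged into one pseudo-species); stage 2
    combines the species-level Zs.  Strata with fewer than
    ``min_stratum_n`` samples are excluded.  A CpG absent from a stratum
    simply contributes nothing there; ``k`` counts the strata that did
    contribute.
    """
    pools = _normalize_pools(pooled_species)
    group_of = {sp: g for g, members in pools.items() for sp in members}

    kept = [t for t in tables if t.n_samples >= min_stratum_n]
    if not kept:
        raise ValidationError(f"no stratum reaches the minimum sample size {min_stratum_n}")
    tree: dict[str, list] = {}
    for t in kept:
        g = group_of.get(t.species_id, t.species_id)
        tree.setdefault(g, []).append((t.species_id, t.tissue, t.n_samples))

    universe = pd.Index(sorted(set().union(*[set(t.stats.index) for t in kept])), name="cpg_id")
    species_z = {}
    species_k = {}
    for g in sorted(tree):
        members = [t for t in kept if group_of.get(t.species_id, t.species_id) == g]
        zmat = pd.concat(
            [t.stats["Z"].reindex(universe) for t in members], axis=1, keys=range(len(members))
        )
        k1 = zmat.notna().sum(axis=1)
        with np.errstate(invalid="ignore"):
            species_z[g] = zmat.sum(axis=1, skipna=True) / np.sqrt(k1.where(k1 > 0))
        species_k[g] = k1
    zsp = pd.DataFrame(species_z)
    ksp = pd.DataFrame(species_k)
    k2 = zsp.notna().sum(axis=1)
    with np.errstate(invalid="ignore"):
        Z_meta = zsp.sum(axis=1, skipna=True) / np.sqrt(k2.where(k2 > 0))
    k_total = ksp.sum(axis=1).astype(int)
    p_meta = 2 * stats.norm.sf(Z_meta.abs())
    out = pd.DataFrame({"k": k_total, "Z_meta": Z_meta, "p_meta": p_meta}, index=universe)
    out = out[out["k"] >= 1]
    return MetaResult(stats=out, tree=tree)


def _stats_frame(obj) -> pd.DataFrame:
    if isinstance(obj, EwasTable):
        return obj.stats.rename(columns={"Z": "Z", "p": "p"})
    if isinstance(obj, MetaResult):
        return obj.stats.rename(columns={"Z_meta": "Z", "p_meta": "p"})
    return obj


def select_top_cpgs(
    result, direction: str, max_k: int = 500, p_threshold: float = 1e-4
) -> list[str]:
    """Top CpGs by p-value in one direction of age association.

    ``direction`` is ``gain`` (Z > 0) or ``loss`` (Z < 0); candidates must
    pass ``p < p_threshold``; at most ``max_k`` are returned, ordered by p
    ascending with ties broken by larger |Z| then lexicographic cpg_id.
    """
    if direction not in ("gain", "loss"):
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    df = _stats_frame(result)
    sign = 1 if direction == "gain" else -1
    cand = df[(np.sign(df["Z"]) == sign) & (df["p"] < p_threshold)].copy()
    cand["_absz"] = cand["Z"].abs()
    cand.index.name = cand.index.name or "cpg_id"
    if cand.index.name != "cpg_id":
        cand.index = cand.index.rename("cpg_id")
    cand = cand.reset_index().sort_values(
        ["p", "_absz", "cpg_id"], ascending=[True, False, True], kind="mergesort"
    )
    return cand["cpg_id"].head(max_k).tolist()


def overlap_top_lists(list_a, list_b, universe_size: int) -> tuple[int, float]:
    """Overlap of two top-CpG lists and its hypergeometric enrichment p.

    Returns ``(|A & B|, P[overlap >= observed])`` for lists of sizes |A|
    and |B| drawn from a shared universe of ``universe_size`` CpGs.
    Duplicate ids within a list are an error.
    """
    a, b = list(list_a), list(list_b)
    if len(set(a)) != len(a):
        raise ValueError("duplicate CpG ids in the first list")
    if len(set(b)) != len(b):
        raise ValueError("duplicate CpG ids in the second list")
    if max(len(a), len(b)) > universe_size:
        raise ValueError("lists larger than their universe")
    k = len(set(a) & set(b))
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, p
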