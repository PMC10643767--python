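"""Sex effects on methylation: stratified EWAS, SMP counting, sex predictor.

Within each stratum (species x tissue x age category) every CpG is fit by
ordinary least squares ``beta ~ 1 + age + female``, with females coded 1
so increased methylation in females maps to a positive coefficient.  CpGs
whose sex coefficient survives a 5% Benjamini-Hochberg FDR within the
stratum are sex-associated methylation positions (SMPs); consensus SMPs
are those significant in at least a chosen number of the regression
models.  A pooled EWAS of sex ignores species and tissue entirely.

The sex predictor is a binomial elastic-net on the female indicator with
an internal tenfold cross-validation for the penalty; probabilities come
from the logistic link and the label threshold is 0.5 (exactly 0.5 yields
``unknown``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .cohort import MethylationCohort
from .errors import ClockParseError, FitError

__all__ = [
    "SexEwasTable",
    "SexPredictor",
    "default_strata",
    "sex_ewas",
    "count_smps",
    "consensus_smps",
    "pooled_sex_ewas",
    "fit_sex_predictor",
    "predict_sex",
    "save_sex_predictor",
    "load_sex_predictor",
]


@dataclass
class SexEwasTable:
    """Per-CpG sex-coefficient statistics for one regression model (stratum)."""

    species_id: str
    tissue: str
    age_category: str
    n: int
    n_female: int
    n_male: int
    stats: pd.DataFrame  # index cpg_id; columns coef, t, p, q


@dataclass
class SexPredictor:
    """Sparse logistic model of female sex on CpG betas (logit scale)."""

    intercept: float
    weights: dict[str, float]
    training_means: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.5
    training_meta: dict = field(default_factory=dict)


def default_strata(
    cohort: MethylationCohort, age_breaks: Sequence[float] = (1.0,), min_per_sex: int = 3
) -> list[tuple[str, str, str]]:
    """Enumerate (species, tissue, age-category) cells with enough of each sex.

    Age categories are formed from ``age_breaks`` in years; the default
    single break at 1 year separates neonates from older animals.
    """
    cats = _age_categories(cohort.samples["age"], age_breaks)
    cells = []
    df = cohort.samples[cohort.samples["sex"].isin(["F", "M"])].assign(age_cat=cats)
    for (sp, t, c), sub in df.groupby(["species_id", "tissue", "age_cat"], observed=True):
        counts = sub["sex"].value_counts()
        if counts.get("F", 0) >= min_per_sex and counts.get("M", 0) >= min_per_sex:
            cells.append((sp, t, str(c)))
    return sorted(cells)


def _age_categories(ages: pd.Series, age_breaks: Sequence[float]) -> pd.Series:
    edges = [-np.inf, *sorted(age_breaks), np.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo):
            labels.append(f"<{hi:g}y")
        elif np.isinf(hi):
            labels.append(f">={lo:g}y")
        else:
            labels.append(f"{lo:g}-{hi:g}y")
    return pd.cut(ages, bins=edges, labels=labels, right=False).astype(str)


def _ols_sex(X: np.ndarray, age: np.ndarray, female: np.ndarray) -> pd.DataFrame:
    """Vectorized OLS of each CpG on [1, age, female]; stats for the sex term."""
    cols = [np.ones_like(age)]
    if np.std(age) > 0:
        cols.append(age)
    cols.append(female.astype(float))
    D = np.column_stack(cols)
    n, k = D.shape
    DtD_inv = np.linalg.inv(D.T @ D)
    coefs = DtD_inv @ D.T @ X  # k x p
    resid = X - D @ coefs
    df_resid = n - k
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[-1, -1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coefs[-1] / se
    t = np.where(se == 0, 0.0, t)
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    return pd.DataFrame({"coef": coefs[-1], "t": t, "p": p})


def sex_ewas(
    cohort: MethylationCohort,
    strata: Optional[Iterable[tuple[str, str, str]]] = None,
    age_breaks: Sequence[float] = (1.0,),
    min_per_sex: int = 3,
) -> list[SexEwasTable]:
    """Stratified EWAS of sex with age as covariate.

    ``strata`` is an explicit list of (species, tissue, age-category)
    model cells; by default every cell with at least ``min_per_sex``
    samples of each sex is analyzed.  Single-sex cells are skipped with a
    warning.  q-values are BH within each model over its tested CpGs.
    """
    if strata is None:
        strata = default_strata(cohort, age_breaks, min_per_sex)
    cats = _age_categories(cohort.samples["age"], age_breaks)
    out = []
    for sp, tissue, cat in strata:
        sel = (
            (cohort.samples["species_id"] == sp)
            & (cohort.samples["tissue"] == tissue)
            & (cats == cat)
            & cohort.samples["sex"].isin(["F", "M"])
        )
        sub = cohort.subset(sel)
        sexes = sub.samples["sex"]
        n_f, n_m = int((sexes == "F").sum()), int((sexes == "M").sum())
        if n_f == 0 or n_m == 0:
            warnings.warn(f"stratum ({sp}, {tissue}, {cat}) is single-sex; skipped")
            continue
        if n_f < min_per_sex or n_m < min_per_sex:
            warnings.warn(f"stratum ({sp}, {tissue}, {cat}) has < {min_per_sex} per sex; skipped")
            continue
        betas = sub.betas.dropna(axis=1, how="any")
        table = _ols_sex(
            betas.to_numpy(dtype=float),
            sub.samples["age"].to_numpy(dtype=float),
            (sexes == "F").to_numpy(),
        )
        table.index = betas.columns
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        out.append(
            SexEwasTable(
                species_id=sp,
                tissue=tissue,
                age_category=cat,
                n=len(sub.samples),
                n_female=n_f,
                n_male=n_m,
                stats=table,
            )
        )
    return out


def count_smps(tables: Iterable[SexEwasTable], cpgs: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Per-model SMP counts split autosome / X / Y and by direction in females."""
    rows = []
    chrom = cpgs["chrom"]
    for t in tables:
        sig = t.stats[t.stats["q"] < fdr]
        ch = chrom.reindex(sig.index)
        group = np.where(ch == "chrX", "X", np.where(ch == "chrY", "Y", "autosome"))
        up = sig["coef"] > 0
        row = {
            "species_id": t.species_id,
            "tissue": t.tissue,
            "age_category": t.age_category,
            "n_smps": len(sig),
        }
        for g in ("autosome", "X", "Y"):
            row[f"{g}_up_in_female"] = int(((group == g) & up).sum())
            row[f"{g}_down_in_female"] = int(((group == g) & ~up).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def consensus_smps(tables: Iterable[SexEwasTable], min_models: int, fdr: float = 0.05) -> set[str]:
    """CpGs significant for sex in at least ``min_models`` regression models."""
    tables = list(tables)
    if min_models > len(tables):
        raise ValueError(f"min_models={min_models} exceeds the number of models ({len(tables)})")
    counts: dict[str, int] = {}
    for t in tables:
        for cpg in t.stats.index[t.stats["q"] < fdr]:
            counts[cpg] = counts.get(cpg, 0) + 1
    return {cpg for cpg, c in counts.items() if c >= min_models}


def pooled_sex_ewas(
    cohort: MethylationCohort, p_threshold: float = 1e-300
) -> tuple[list[str], list[str], pd.DataFrame]:
    """EWAS of sex ignoring species and tissue.

    Returns (hypermethylated-in-females, hypomethylated-in-females, full
    statistics).  The default significance threshold is the extreme value
    appropriate for consortium-scale sample sizes; desk-scale analyses
    should lower it.
    """
    sel = cohort.samples["sex"].isin(["F", "M"])
    sub = cohort.subset(sel)
    sexes = sub.samples["sex"]
    if (sexes == "F").sum() < 3 or (sexes == "M").sum() < 3:
        raise FitError("pooled sex EWAS needs >= 3 samples of each sex")
    betas = sub.betas
    filled = betas.fillna(betas.mean(axis=0)).dropna(axis=1, how="any")
    table = _ols_sex(
        filled.to_numpy(dtype=float),
        sub.samples["age"].to_numpy(dtype=float),
        (sexes == "F").to_numpy(),
    )
    table.index = filled.columns
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    sig = table[table["p"] < p_threshold]
    hyper = sorted(sig.index[sig["coef"] > 0])
    hypo = sorted(sig.index[sig["coef"] < 0])
    return hyper, hypo, table


# ----------------------------------------------------------------------
# elastic-net sex predictor
# ----------------------------------------------------------------------

def fit_sex_predictor(
    cohort: MethylationCohort,
    alpha: float = 0.5,
    seed: int = 0,
    x_only: bool = False,
    n_penalties: int = 10,
    inner_folds: int = 10,
) -> SexPredictor:
    """Binomial elastic-net predictor of female sex from CpG betas.

    ``x_only`` restricts candidate features to X-chromosome CpGs (the
    selected CpGs concentrate there anyway when the signal is X-linked).
    Raises :class:`FitError` for single-class training sets.
    """
    sel = cohort.samples["sex"].isin(["F", "M"])
    sub = cohort.subset(sel)
    y = (sub.samples["sex"] == "F").to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise FitError("sex predictor training set contains a single class")
    betas = sub.betas
    if x_only:
        betas = betas.loc[:, cohort.cpgs["chrom"].reindex(betas.columns) == "chrX"]
    means = betas.mean(axis=0)
    X = betas.fillna(means)
    sd = X.std(axis=0, ddof=0)
    keep = (sd > 0) & means.notna()
    X, sd, means = X.loc[:, keep], sd[keep], means[keep]
    mu = X.mean(axis=0)
    Xs = (X - mu) / sd

    inner = StratifiedKFold(n_splits=min(inner_folds, int(np.bincount(y).min())), shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegressionCV(
            Cs=n_penalties,
            cv=inner,
            penalty="elasticnet",
            solver="saga",
            l1_ratios=[alpha],
            scoring="accuracy",
            max_iter=2000,
            tol=1e-3,
            n_jobs=1,
            random_state=seed,
        )
        clf.fit(Xs.to_numpy(), y)

    coef = clf.coef_.ravel() / sd.to_numpy()
    intercept = float(clf.intercept_[0] - np.dot(coef, mu.to_numpy()))
    nz = np.flatnonzero(clf.coef_.ravel())
    return SexPredictor(
        intercept=intercept,
        weights={X.columns[j]: float(coef[j]) for j in nz},
        training_means={X.columns[j]: float(means.iloc[j]) for j in nz},
        training_meta={
            "n_samples": len(y),
            "n_female": int(y.sum()),
            "alpha": alpha,
            "seed": seed,
            "x_only": x_only,
            "C": float(np.atleast_1d(clf.C_)[0]),
        },
    )


def cross_validated_sex_predictions(
    cohort: MethylationCohort,
    k: int = 10,
    alpha: float = 0.5,
    seed: int = 0,
    n_penalties: int = 5,
    inner_folds: int = 5,
) -> pd.DataFrame:
    """Out-of-fold sex predictions under k-fold CV (stratified by sex).

    Each sample is predicted by a predictor refit (including its internal
    penalty search) on the other folds.  Returns a DataFrame with
    prob_female, label, and the fold index; join with the sample sheet to
    compute per-species accuracy.
    """
    sel = cohort.samples["sex"].isin(["F", "M"])
    sub = cohort.subset(sel)
    y = (sub.samples["sex"] == "F").to_numpy().astype(int)
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    parts = []
    for fold, (train_idx, test_idx) in enumerate(outer.split(np.zeros(len(y)), y), start=1):
        train = sub.subset(sub.samples.index[train_idx])
        test = sub.subset(sub.samples.index[test_idx])
        predictor = fit_sex_predictor(
            train, alpha=alpha, seed=seed + fold, n_penalties=n_penalties, inner_folds=inner_folds
        )
        p = predict_sex(predictor, test)
        p["fold"] = fold
        parts.append(p)
    return pd.concat(parts).loc[sub.samples.index]


def predict_sex(predictor: SexPredictor, cohort: MethylationCohort) -> pd.DataFrame:
    """Per-sample female probability and label (F/M; exactly 0.5 -> unknown)."""
    ids = list(predictor.weights)
    w = np.array([predictor.weights[c] for c in ids])
    cols = {}
    for c in ids:
        if c in cohort.betas.columns:
            cols[c] = cohort.betas[c].fillna(predictor.training_means.get(c, np.nan))
        else:
            cols[c] = pd.Series(predictor.training_means.get(c, np.nan), index=cohort.betas.index)
    X = pd.DataFrame(cols, index=cohort.betas.index) if ids else pd.DataFrame(index=cohort.betas.index)
    score = predictor.intercept + (X.to_numpy() @ w if ids else 0.0)
    prob = 1.0 / (1.0 + np.exp(-(np.asarray(score, dtype=float) + np.zeros(len(cohort.betas)))))
    label = np.where(prob > predictor.threshold, "F", np.where(prob < predictor.threshold, "M", "unknown"))
    return pd.DataFrame({"prob_female": prob, "label": label}, index=cohort.betas.index)


def save_sex_predictor(predictor: SexPredictor, path) -> None:
    """Same clock-file format, with the transform tag ``logit-sex``."""
    header = {
        "name": "sex-predictor",
        "transform": {"kind": "logit-sex", "threshold": predictor.threshold},
        "training_means": {k: float(v) for k, v in sorted(predictor.training_means.items())},
        "training_meta": predictor.training_meta,
    }
    buf = io.StringIO()
    for line in yaml.safe_dump(header, sort_keys=True).rstrip("\n").split("\n"):
        buf.write(f"# {line}\n")
    buf.write("cpg_id,coefficient\n")
    buf.write(f"Intercept,{predictor.intercept!r}\n")
    for cpg in sorted(predictor.weights):
        buf.write(f"{cpg},{predictor.weights[cpg]!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_sex_predictor(path) -> SexPredictor:
    header_lines: list[str] = []
    intercept = None
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                header_lines.append(line[2:] if line.startswith("# ") else line[1:])
                continue
            if not line.strip() or line == "cpg_id,coefficient":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ClockParseError(f"expected 'cpg_id,coefficient', got {line!r}", line=lineno)
            try:
                value = float(parts[1])
            except ValueError:
                raise ClockParseError(f"coefficient {parts[1]!r} is not a number", line=lineno) from None
            if parts[0] == "Intercept":
                intercept = value
            else:
                rows.append((parts[0], value))
    header = yaml.safe_load("\n".join(header_lines)) or {}
    tag = (header.get("transform") or {}).get("kind")
    if tag != "logit-sex":
        raise ClockParseError(f"not a sex-predictor file (transform tag {tag!r})")
    if intercept is None:
        raise ClockParseError("missing Intercept row")
    return SexPredictor(
        intercept=intercept,
        weights=dict(rows),
        training_means={k: float(v) for k, v in (header.get("training_means") or {}).items()},
        threshold=float((header.get("transform") or {}).get("threshold", 0.5)),
        training_meta=header.get("training_meta") or {},
    )
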