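"""Cross-validated clock accuracy and epigenetic age acceleration.

Two schemes: LOOCV (leave one sample out) and LOFO10, a tenfold scheme in
which every fold contains the same proportion of each species (per-species
fold sizes differ by at most one).  Accuracy is summarized by the Pearson
correlation between predicted and chronological age and the median
absolute error in years, computed only on out-of-fold predictions.

Age acceleration is the discrepancy between DNAm age and chronological
age, under two conventions: ``delta`` (DNAmAge - Age) and ``residual``
(residual of DNAmAge regressed on Age; zero-mean and age-uncorrelated by
construction, and invariant to calibration offsets — the default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .clock import MIN_TRAIN_SAMPLES, fit_clock, predict_age
from .cohort import MethylationCohort
from .errors import FitError
from .transforms import TransformSpec

__all__ = [
    "FoldAssignment",
    "make_folds",
    "run_cv",
    "cv_metrics",
    "age_acceleration",
    "acceleration_table",
    "cross_tissue_acceleration_correlation",
]

SCHEMES = ("LOOCV", "LOFO10")


@dataclass
class FoldAssignment:
    """Per-sample fold labels (1..K) under a named scheme."""

    folds: pd.Series  # sample_id -> fold in 1..k
    scheme: str
    seed: int
    k: int


def make_folds(cohort: MethylationCohort, scheme: str = "LOFO10", seed: int = 0, k: int = 10) -> FoldAssignment:
    """Assign samples to folds.

    LOFO10 shuffles within species (seeded) then deals samples round-robin
    from a random starting fold, so per-species fold counts differ by at
    most one while overall fold sizes stay balanced.
    """
    n = cohort.n_samples
    if scheme == "LOOCV":
        return FoldAssignment(
            folds=pd.Series(np.arange(1, n + 1), index=cohort.samples.index),
            scheme="LOOCV",
            seed=seed,
            k=n,
        )
    if scheme != "LOFO10":
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    folds = pd.Series(0, index=cohort.samples.index, dtype=int)
    for sp in sorted(cohort.samples["species_id"].unique()):
        idx = cohort.samples.index[cohort.samples["species_id"] == sp].to_numpy()
        idx = rng.permutation(idx)
        start = int(rng.integers(k))
        folds.loc[idx] = (start + np.arange(len(idx))) % k + 1
    return FoldAssignment(folds=folds, scheme="LOFO10", seed=seed, k=k)


def cv_metrics(predictions: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Pearson R and median absolute error (years), overall / per species / per tissue."""
    df = predictions.join(samples[["species_id", "tissue"]])
    rows = []

    def one(group: str, key: str, sub: pd.DataFrame) -> None:
        err = np.abs(sub["dnam_age"] - sub["age"])
        r = np.nan
        if len(sub) >= 3 and sub["age"].std() > 0 and sub["dnam_age"].std() > 0:
            r = float(np.corrcoef(sub["age"], sub["dnam_age"])[0, 1])
        rows.append(
            {"grouping": group, "key": key, "n": len(sub), "pearson_r": r, "mae": float(err.median())}
        )

    one("overall", "all", df)
    for sp, sub in df.groupby("species_id"):
        one("species", sp, sub)
    for t, sub in df.groupby("tissue"):
        one("tissue", t, sub)
    return pd.DataFrame(rows)


def run_cv(
    cohort: MethylationCohort,
    transform: TransformSpec,
    scheme: str = "LOFO10",
    alpha: float = 0.5,
    seed: int = 0,
    sample_filter: Optional[Callable[[pd.Series], bool]] = None,
    n_alphas: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Out-of-fold clock predictions and accuracy metrics.

    Every sample is predicted exactly once by a model never trained on it;
    the elastic-net penalty is re-selected inside each training fold (no
    leakage).  Returns ``(predictions, metrics)`` where predictions carry
    fold, age, transformed and year-scale DNAm age per sample.
    """
    work = cohort if sample_filter is None else cohort.subset(
        cohort.samples.apply(sample_filter, axis=1).astype(bool)
    )
    assignment = make_folds(work, scheme=scheme, seed=seed)
    folds = assignment.folds
    preds = []
    for f in sorted(folds.unique()):
        test_ids = folds.index[folds == f]
        train_ids = folds.index[folds != f]
        if len(train_ids) < MIN_TRAIN_SAMPLES:
            raise FitError(
                f"fold {f}: training half has {len(train_ids)} samples (< {MIN_TRAIN_SAMPLES}); "
                "use a larger cohort"
            )
        model = fit_clock(
            work.subset(train_ids),
            transform,
            alpha=alpha,
            seed=seed + int(f),
            n_alphas=n_alphas,
            name=f"cv-fold{f}",
        )
        p = predict_age(model, work.subset(test_ids))
        p["fold"] = int(f)
        preds.append(p)
    predictions = pd.concat(preds).loc[work.samples.index]
    predictions["age"] = work.samples["age"]
    metrics = cv_metrics(predictions, work.samples)
    return predictions, metrics


def age_acceleration(dnam_age, age, definition: str = "residual") -> np.ndarray:
    """Per-sample epigenetic age acceleration in years.

    ``delta`` is DNAmAge - Age.  ``residual`` is the residual of the
    least-squares line of DNAmAge on Age (needs >= 3 samples and
    non-constant ages).
    """
    d = np.asarray(dnam_age, dtype=float)
    a = np.asarray(age, dtype=float)
    if definition == "delta":
        return d - a
    if definition != "residual":
        raise ValueError(f"unknown acceleration definition {definition!r}")
    if len(a) < 3:
        raise ValueError("residual acceleration needs >= 3 samples")
    if np.std(a) == 0:
        raise ValueError("residual acceleration is degenerate with constant ages")
    slope, intercept = np.polyfit(a, d, 1)
    return d - (intercept + slope * a)


def acceleration_table(predictions: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Both acceleration definitions joined with animal and tissue ids.

    The residual regression is computed within each tissue so tissue-level
    calibration differences do not leak into cross-tissue correlations.
    """
    df = predictions.join(samples[["animal_id", "tissue", "species_id"]])
    df["acceleration_delta"] = df["dnam_age"] - df["age"]
    resid = np.full(len(df), np.nan)
    for _, sub in df.groupby("tissue"):
        pos = df.index.get_indexer(sub.index)
        resid[pos] = age_acceleration(sub["dnam_age"], sub["age"], "residual")
    df["acceleration_residual"] = resid
    return df[
        ["animal_id", "species_id", "tissue", "age", "dnam_age", "acceleration_delta", "acceleration_residual"]
    ]


def cross_tissue_acceleration_correlation(
    acc: pd.DataFrame, value: str = "acceleration_residual", min_shared: int = 3
) -> pd.DataFrame:
    """Tissue x tissue Pearson correlation of animal-matched accelerations.

    Tissues are joined on shared animal_id; pairs with fewer than
    ``min_shared`` shared animals are reported as NaN.  Symmetric with a
    unit diagonal.
    """
    wide = acc.pivot_table(index="animal_id", columns="tissue", values=value)
    tissues = list(wide.columns)
    out = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    any_pair = False
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i + 1 :]:
            pair = wide[[t1, t2]].dropna()
            if len(pair) < min_shared:
                out.loc[t1, t2] = out.loc[t2, t1] = np.nan
                continue
            any_pair = True
            r = float(np.corrcoef(pair[t1], pair[t2])[0, 1])
            out.loc[t1, t2] = out.loc[t2, t1] = r
    if len(tissues) > 1 and not any_pair:
        warnings.warn("no tissue pair shares enough animals; correlation matrix is empty")
    return out
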