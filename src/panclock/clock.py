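"""Elastic-net methylation clocks: fitting, prediction, serialization.

A clock is a sparse linear model on CpG beta values predicting transformed
age.  The elastic-net mixing parameter defaults to 0.5 (midway between
ridge and lasso) and the regularization strength is chosen by an internal
tenfold cross-validation minimizing mean squared prediction error,
mirroring the glmnet workflow standard in the clock literature.
Coefficients are reported on the raw beta scale (standardization happens
internally and is undone), so published-clock-style coefficient tables can
be written and reapplied directly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .cohort import MethylationCohort
from .errors import ClockParseError, FitError
from .transforms import TransformSpec, inverse_transform_age, transform_age

__all__ = ["ClockModel", "fit_clock", "predict_age", "save_clock", "load_clock"]

MIN_TRAIN_SAMPLES = 20


@dataclass
class ClockModel:
    """A fitted clock: intercept + sparse CpG weights + its age transform.

    ``weights`` holds only nonzero coefficients (beta scale).
    ``training_means`` stores the training-set mean beta of each model CpG,
    used to impute missing values at prediction time.  ``fitted_`` keeps
    the in-sample fitted transformed ages (not serialized).
    """

    name: str
    intercept: float
    weights: dict[str, float]
    transform: TransformSpec
    alpha: float = 0.5
    penalty: float = 0.0
    training_means: dict[str, float] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)
    fitted_: Optional[pd.Series] = None

    @property
    def n_weights(self) -> int:
        return len(self.weights)


def _transform_ages(samples: pd.DataFrame, spec: TransformSpec) -> np.ndarray:
    out = np.empty(len(samples))
    for i, (sid, row) in enumerate(samples.iterrows()):
        try:
            out[i] = transform_age(float(row["age"]), row["species_id"], spec)
        except (ValueError, KeyError) as e:
            raise type(e)(f"sample {sid!r}: {e}") from None
    return out


def fit_clock(
    cohort: MethylationCohort,
    transform: TransformSpec,
    sample_filter: Optional[Callable[[pd.Series], bool]] = None,
    alpha: float = 0.5,
    seed: int = 0,
    n_alphas: int = 50,
    name: str = "clock",
) -> ClockModel:
    """Fit an elastic-net clock for transformed age on beta values.

    ``sample_filter`` is a predicate over sample-sheet rows selecting the
    training set (e.g. one tissue, or two species for a dual-species
    clock).  Missing betas are imputed with per-CpG training means;
    all-constant CpG columns are dropped with a warning.  Raises
    :class:`FitError` with fewer than 20 training samples.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"elastic-net mixing alpha must lie in (0, 1], got {alpha}")
    samples = cohort.samples
    if sample_filter is not None:
        keep = samples.apply(sample_filter, axis=1).astype(bool)
        samples = samples.loc[keep]
    n = len(samples)
    if n < MIN_TRAIN_SAMPLES:
        raise FitError(f"need >= {MIN_TRAIN_SAMPLES} training samples, got {n}")

    y = _transform_ages(samples, transform)
    X = cohort.betas.loc[samples.index]
    col_means = X.mean(axis=0, skipna=True)
    X = X.fillna(col_means)

    sd = X.std(axis=0, ddof=0)
    constant = sd == 0
    all_missing = col_means.isna()
    drop = constant | all_missing
    if drop.any():
        warnings.warn(f"dropping {int(drop.sum())} constant or all-missing CpG columns")
        X = X.loc[:, ~drop]
        sd = sd[~drop]
        col_means = col_means[~drop]

    mu = X.mean(axis=0)
    Xs = (X - mu) / sd
    cv = KFold(n_splits=10, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on noisy folds
        enet = ElasticNetCV(l1_ratio=alpha, alphas=n_alphas, cv=cv, max_iter=5000, n_jobs=1)
        enet.fit(Xs.to_numpy(), y)

    coef_beta = enet.coef_ / sd.to_numpy()
    intercept = float(enet.intercept_ - np.dot(coef_beta, mu.to_numpy()))
    nz = np.flatnonzero(enet.coef_)
    weights = {X.columns[j]: float(coef_beta[j]) for j in nz}
    means = {X.columns[j]: float(col_means.iloc[j]) for j in nz}

    fitted = pd.Series(intercept + X.iloc[:, nz].to_numpy() @ coef_beta[nz], index=X.index)
    return ClockModel(
        name=name,
        intercept=intercept,
        weights=weights,
        transform=transform,
        alpha=alpha,
        penalty=float(enet.alpha_),
        training_means=means,
        training_meta={
            "n_samples": n,
            "species": sorted(samples["species_id"].unique().tolist()),
            "tissues": sorted(samples["tissue"].unique().tolist()),
            "seed": seed,
        },
        fitted_=fitted,
    )


def predict_age(model: ClockModel, cohort: MethylationCohort) -> pd.DataFrame:
    """Apply a clock: linear score on betas, then inverse transform per species.

    Missing (or absent) model CpGs are imputed with the stored training
    means.  Returns a DataFrame indexed by sample_id with ``y_transformed``
    (the raw linear score on the clock's regression scale) and ``dnam_age``
    in years.
    """
    spec = model.transform
    if spec.kind in ("relative", "loglinear"):
        m = spec.lifespan_by_species if spec.kind == "relative" else spec.maturity_by_species
        missing = sorted(set(cohort.samples["species_id"]) - set(m))
        if missing:
            raise KeyError(
                f"{spec.kind} clock has no parameters for species {missing}; extend the transform spec"
            )
    ids = list(model.weights)
    w = np.array([model.weights[c] for c in ids])
    cols = {}
    for c in ids:
        if c in cohort.betas.columns:
            cols[c] = cohort.betas[c].fillna(model.training_means.get(c, np.nan))
        else:
            cols[c] = pd.Series(model.training_means.get(c, np.nan), index=cohort.betas.index)
    X = pd.DataFrame(cols, index=cohort.betas.index) if ids else pd.DataFrame(index=cohort.betas.index)
    score = model.intercept + (X.to_numpy() @ w if ids else 0.0)
    score = np.asarray(score, dtype=float) + np.zeros(len(cohort.betas))

    # clamp into the inverse domain (a linear score can dip below sqrt(0)
    # for fetal-aged samples); the raw score stays in y_transformed
    inv_in = np.maximum(score, 0.0) if spec.kind == "sqrt_offset" else score
    years = np.empty_like(score)
    sp = cohort.samples["species_id"].to_numpy()
    for s in np.unique(sp):
        sel = sp == s
        years[sel] = inverse_transform_age(inv_in[sel], s, spec)
    return pd.DataFrame({"y_transformed": score, "dnam_age": years}, index=cohort.betas.index)


# ----------------------------------------------------------------------
# serialization: CSV body (Intercept + cpg,coefficient rows) with a
# commented YAML header, mirroring published clock-coefficient tables.
# ----------------------------------------------------------------------

def _header_dict(model: ClockModel) -> dict:
    return {
        "name": model.name,
        "transform": model.transform.to_dict(),
        "alpha": float(model.alpha),
        "penalty": float(model.penalty),
        "training_means": {k: float(v) for k, v in sorted(model.training_means.items())},
        "training_meta": model.training_meta,
    }


def save_clock(model: ClockModel, path) -> None:
    """Write a clock file; ``save -> load -> save`` is byte-identical."""
    buf = io.StringIO()
    header = yaml.safe_dump(_header_dict(model), sort_keys=True, default_flow_style=False)
    for line in header.rstrip("\n").split("\n"):
        buf.write(f"# {line}\n")
    buf.write("cpg_id,coefficient\n")
    buf.write(f"Intercept,{model.intercept!r}\n")
    for cpg in sorted(model.weights):
        buf.write(f"{cpg},{model.weights[cpg]!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_clock(path) -> ClockModel:
    """Read a clock file written by :func:`save_clock`.

    Malformed content raises :class:`ClockParseError` carrying the
    offending line number.
    """
    header_lines: list[str] = []
    rows: list[tuple[str, float]] = []
    intercept = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                header_lines.append(line[2:] if line.startswith("# ") else line[1:])
                continue
            if not line.strip():
                continue
            if line == "cpg_id,coefficient":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ClockParseError(f"expected 'cpg_id,coefficient', got {line!r}", line=lineno)
            key, val = parts
            try:
                value = float(val)
            except ValueError:
                raise ClockParseError(f"coefficient {val!r} is not a number", line=lineno) from None
            if key == "Intercept":
                intercept = value
            else:
                rows.append((key, value))
    try:
        header = yaml.safe_load("\n".join(header_lines)) or {}
    except yaml.YAMLError as e:
        raise ClockParseError(f"invalid YAML header: {e}") from None
    if intercept is None:
        raise ClockParseError("missing Intercept row")
    try:
        transform = TransformSpec.from_dict(header.get("transform", {}))
    except ValueError as e:
        raise ClockParseError(str(e)) from None
    return ClockModel(
        name=header.get("name", "clock"),
        intercept=intercept,
        weights=dict(rows),
        transform=transform,
        alpha=float(header.get("alpha", 0.5)),
        penalty=float(header.get("penalty", 0.0)),
        training_means={k: float(v) for k, v in (header.get("training_means") or {}).items()},
        training_meta=header.get("training_meta") or {},
    )
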