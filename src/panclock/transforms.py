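"""Dependent-variable transformations for methylation age clocks.

Clock regressions are fit on a transformed age scale and predictions are
mapped back to years through the exact inverse.  Four transforms are
supported:

``identity``
    Transformed age equals chronological age (pan-tissue single-species
    clocks).
``sqrt_offset``
    ``sqrt(age + offset)`` with a default offset of 1 year.  The offset
    keeps fetal samples, coded with negative ages, inside the domain.
``loglinear``
    The piecewise log-linear calibration used by pan-tissue human clocks:
    ``log(age+1) - log(m+1)`` before the species' age of sexual maturity
    ``m`` and ``(age-m)/(m+1)`` afterwards.  Continuous, zero at ``m``.
``relative``
    Age divided by the species' maximum recorded lifespan, so values fall
    (mostly) in [0, 1] and are comparable across species with very
    different longevities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["TransformSpec", "transform_age", "inverse_transform_age", "TRANSFORM_KINDS"]

TRANSFORM_KINDS = ("identity", "sqrt_offset", "loglinear", "relative")


@dataclass(frozen=True)
class TransformSpec:
    """Which age transformation a clock uses, with per-species parameters.

    Parameters
    ----------
    kind:
        One of ``identity``, ``sqrt_offset``, ``loglinear``, ``relative``.
    offset:
        Offset in years for ``sqrt_offset``; must be positive.
    maturity_by_species:
        species_id -> age at sexual maturity in years (``loglinear`` only).
        A single shared constant is expressed as a degenerate map.
    lifespan_by_species:
        species_id -> maximum lifespan in years (``relative`` only).
    """

    kind: str = "sqrt_offset"
    offset: float = 1.0
    maturity_by_species: Mapping[str, float] = field(default_factory=dict)
    lifespan_by_species: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; expected one of {TRANSFORM_KINDS}")
        if self.kind == "sqrt_offset" and not self.offset > 0:
            raise ValueError(f"sqrt_offset requires offset > 0, got {self.offset}")
        if self.kind == "loglinear":
            for sp, m in self.maturity_by_species.items():
                if not m > 0:
                    raise ValueError(f"loglinear requires maturity_age > 0; species {sp!r} has {m}")
        if self.kind == "relative":
            for sp, life in self.lifespan_by_species.items():
                if not life > 0:
                    raise ValueError(f"relative requires max_lifespan > 0; species {sp!r} has {life}")

    # -- serialization used inside clock files ---------------------------
    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind == "sqrt_offset":
            d["offset"] = float(self.offset)
        elif self.kind == "loglinear":
            d["maturity_by_species"] = {k: float(v) for k, v in sorted(self.maturity_by_species.items())}
        elif self.kind == "relative":
            d["lifespan_by_species"] = {k: float(v) for k, v in sorted(self.lifespan_by_species.items())}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransformSpec":
        kind = d.get("kind")
        if kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform tag {kind!r}")
        return cls(
            kind=kind,
            offset=float(d.get("offset", 1.0)),
            maturity_by_species=dict(d.get("maturity_by_species", {})),
            lifespan_by_species=dict(d.get("lifespan_by_species", {})),
        )


def _lookup(mapping: Mapping[str, float], species_id: str, what: str) -> float:
    try:
        return mapping[species_id]
    except KeyError:
        raise KeyError(f"species {species_id!r} has no {what} in the transform spec") from None


def transform_age(age, species_id: str | None, spec: TransformSpec):
    """Map chronological age in years onto the clock's regression scale.

    ``age`` may be a scalar or array; ``species_id`` is required for the
    species-parameterized transforms and ignored otherwise.  Raises
    ``ValueError`` when an age falls outside the transform's domain and
    ``KeyError`` for a species missing from the spec's map.
    """
    a = np.asarray(age, dtype=float)
    if spec.kind == "identity":
        out = a
    elif spec.kind == "sqrt_offset":
        if np.any(a < -spec.offset):
            bad = np.atleast_1d(a)[np.atleast_1d(a) < -spec.offset][0]
            raise ValueError(
                f"age {bad} is below the sqrt_offset domain (age >= {-spec.offset}) for species {species_id!r}"
            )
        out = np.sqrt(a + spec.offset)
    elif spec.kind == "loglinear":
        m = _lookup(spec.maturity_by_species, species_id, "maturity_age")
        if np.any(a <= -1):
            bad = np.atleast_1d(a)[np.atleast_1d(a) <= -1][0]
            raise ValueError(f"age {bad} is below the loglinear domain (age > -1) for species {species_id!r}")
        out = np.where(a <= m, np.log1p(np.maximum(a, -1 + 1e-300)) - np.log1p(m), (a - m) / (m + 1.0))
    elif spec.kind == "relative":
        life = _lookup(spec.lifespan_by_species, species_id, "max_lifespan")
        out = a / life
    else:  # pragma: no cover - guarded by TransformSpec
        raise ValueError(spec.kind)
    return float(out) if np.isscalar(age) else out


def inverse_transform_age(y, species_id: str | None, spec: TransformSpec):
    """Exact inverse of :func:`transform_age`, returning years."""
    v = np.asarray(y, dtype=float)
    if spec.kind == "identity":
        out = v
    elif spec.kind == "sqrt_offset":
        if np.any(v < 0):
            bad = np.atleast_1d(v)[np.atleast_1d(v) < 0][0]
            raise ValueError(f"transformed value {bad} is below the sqrt_offset inverse domain (y >= 0)")
        out = v * v - spec.offset
    elif spec.kind == "loglinear":
        m = _lookup(spec.maturity_by_species, species_id, "maturity_age")
        out = np.where(v <= 0, np.expm1(v + np.log1p(m)), m + v * (m + 1.0))
    elif spec.kind == "relative":
        life = _lookup(spec.lifespan_by_species, species_id, "max_lifespan")
        out = v * life
    else:  # pragma: no cover
        raise ValueError(spec.kind)
    return float(out) if np.isscalar(y) else out
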