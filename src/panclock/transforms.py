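"""Invertible age transformations used as clock regression targets.

Three kinds are supported:

``identity``
    Chronological age in years, untouched. Used for the single-species
    multi-tissue clock.
``relative``
    Age divided by the species' maximum recorded lifespan, so both species
    live on a common [0, 1] scale. A vervet at 15.4 y and a human at 61.25 y
    are both at relative age 0.5.
``loglinear``
    The piecewise log-linear map used for dual-species chronological-age
    clocks: logarithmic before sexual maturity (ages compress, reflecting
    fast developmental change) and linear after it,

        F(a) = log((a + k) / (m + k))      for a <= m,
        F(a) = (a - m) / (m + k)           for a >  m,

    with maturity age ``m`` and offset ``k`` in years. F is continuous and
    differentiable at ``m`` (both branches have slope 1/(m + k) there) and
    strictly increasing, hence invertible on [0, inf).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import SampleSheet, SpeciesInfo, ValidationError

__all__ = [
    "TransformSpec",
    "relative_age",
    "loglinear",
    "loglinear_inverse",
    "transform_target",
    "untransform_predictions",
]

KINDS = ("identity", "relative", "loglinear")


def relative_age(age: float, species: SpeciesInfo) -> float:
    """Age divided by the species' maximum lifespan (unitless).

    Values exceed 1 only when ``age`` exceeds the recorded maximum; such
    ages are passed through with a warning rather than clamped.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    rel = age / species.max_lifespan
    if rel > 1:
        warnings.warn(
            f"age {age} exceeds {species.name} max lifespan {species.max_lifespan}",
            stacklevel=2,
        )
    return rel


def loglinear(age: float, species: SpeciesInfo, k: float = 1.0) -> float:
    """Piecewise log-linear transform of age (unitless); see module docstring."""
    m = species.maturity_age
    if m <= 0 or k <= 0:
        raise ValueError(f"require maturity_age > 0 and k > 0, got m={m}, k={k}")
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    if age <= m:
        return math.log((age + k) / (m + k))
    return (age - m) / (m + k)


def loglinear_inverse(x: float, species: SpeciesInfo, k: float = 1.0) -> float:
    """Exact inverse of :func:`loglinear`, in years."""
    m = species.maturity_age
    if m <= 0 or k <= 0:
        raise ValueError(f"require maturity_age > 0 and k > 0, got m={m}, k={k}")
    if x <= 0:
        return math.exp(x) * (m + k) - k
    return x * (m + k) + m


@dataclass
class TransformSpec:
    """A transform kind plus the per-species constants needed to apply it.

    ``species`` maps species label -> :class:`SpeciesInfo`; it may be empty
    for the identity kind. ``k_offset`` is the loglinear offset in years.
    """

    kind: str = "identity"
    species: dict[str, SpeciesInfo] = field(default_factory=dict)
    k_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(f"unknown transform kind {self.kind!r}; choose from {KINDS}")
        if self.kind == "loglinear" and self.k_offset <= 0:
            raise ValidationError(f"loglinear offset k must be > 0, got {self.k_offset}")

    def _species_info(self, name: str) -> SpeciesInfo:
        try:
            return self.species[name]
        except KeyError:
            raise ValidationError(
                f"no transform parameters for species {name!r}; have {sorted(self.species)}"
            ) from None

    def forward(self, age: float, species_name: str | None = None) -> float:
        if self.kind == "identity":
            if age < 0:
                raise ValueError(f"age must be >= 0, got {age}")
            return float(age)
        sp = self._species_info(species_name)
        if self.kind == "relative":
            return relative_age(age, sp)
        return loglinear(age, sp, self.k_offset)

    def inverse(self, x: float, species_name: str | None = None) -> float:
        if self.kind == "identity":
            return float(x)
        sp = self._species_info(species_name)
        if self.kind == "relative":
            return float(x) * sp.max_lifespan
        return loglinear_inverse(x, sp, self.k_offset)


def transform_target(sheet: SampleSheet, spec: TransformSpec) -> np.ndarray:
    """Elementwise transform of the sheet's ages into the regression target."""
    ages = sheet.ages
    species = sheet.df["species"].to_numpy()
    if spec.kind == "identity":
        return ages.astype(float)
    missing = sorted(set(species) - set(spec.species))
    if missing:
        raise ValidationError(f"no transform parameters for species: {missing}")
    return np.array([spec.forward(a, s) for a, s in zip(ages, species)], dtype=float)


def untransform_predictions(values: np.ndarray, spec: TransformSpec, species: np.ndarray) -> np.ndarray:
    """Per-species exact inverse of :func:`transform_target`, back to years."""
    values = np.asarray(values, dtype=float)
    if spec.kind == "identity":
        return values.copy()
    missing = sorted(set(np.asarray(species)) - set(spec.species))
    if missing:
        raise ValidationError(f"no transform parameters for species: {missing}")
    return np.array([spec.inverse(v, s) for v, s in zip(values, species)], dtype=float)
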