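"""Validated containers for methylation matrices, sample metadata and probe manifests.

The containers are thin wrappers around pandas objects: a beta-value matrix
(CpG probes x samples, methylation fractions in [0, 1]), a sample sheet
(species, tissue, sex, chronological age in years, optional longitudinal
replicate grouping) and a probe manifest (genomic coordinates and
nearest-gene annotation). Validation happens at construction so that every
downstream stage can assume clean inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "SpeciesInfo",
    "ProbeManifest",
    "ValidationError",
    "FEATURE_CLASSES",
    "join_samples",
]

#: Closed vocabulary of genomic feature classes, in annotation precedence order.
FEATURE_CLASSES = (
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "downstream",
    "intergenic",
    "unassigned",
)

SAMPLE_SHEET_COLUMNS = ("sample_id", "species", "tissue", "sex", "age")


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


@dataclass(frozen=True)
class SpeciesInfo:
    """Life-history constants for one species.

    ``max_lifespan`` is the maximum recorded age of death in years (used by
    the relative-age transform); ``maturity_age`` is the age of sexual
    maturity in years (the knot of the log-linear transform).
    """

    name: str
    max_lifespan: float
    maturity_age: float = 1.0

    def __post_init__(self) -> None:
        if not (self.max_lifespan > self.maturity_age > 0):
            raise ValidationError(
                f"species {self.name!r}: require max_lifespan > maturity_age > 0, "
                f"got max_lifespan={self.max_lifespan}, maturity_age={self.maturity_age}"
            )


class BetaMatrix:
    """Methylation beta values, probes x samples, each value in [0, 1] or NaN.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
        Values are methylation fractions; missing values are permitted on
        input but all-missing rows/columns are rejected.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1]: probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}, value {arr[i, j]!r}"
            )
        if values.shape[0] and values.shape[1]:
            allnan_rows = values.index[np.isnan(arr).all(axis=1)]
            if len(allnan_rows):
                raise ValidationError(f"all-missing probes: {allnan_rows.tolist()[:5]}")
            allnan_cols = values.columns[np.isnan(arr).all(axis=0)]
            if len(allnan_cols):
                raise ValidationError(f"all-missing samples: {allnan_cols.tolist()[:5]}")
        values = values.astype(float)
        values.index = values.index.rename("probe_id")
        values.columns = values.columns.rename(None)
        self.values = values

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[:, list(sample_ids)])

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[list(probe_ids), :])

    def complete_probes(self) -> tuple["BetaMatrix", int]:
        """Drop probes with any missing value; return (matrix, n_dropped)."""
        keep = ~self.values.isna().any(axis=1)
        return BetaMatrix(self.values.loc[keep]), int((~keep).sum())

    def __repr__(self) -> str:
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


class SampleSheet:
    """Per-sample metadata table keyed by ``sample_id``.

    Required columns: sample_id, species, tissue, sex, age (years, >= 0).
    An optional ``replicate_group`` column links longitudinal samples from
    one animal. Extra columns are preserved untouched.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        ages = pd.to_numeric(df["age"], errors="coerce")
        if ages.isna().any() or not np.isfinite(ages).all():
            bad = df.loc[ages.isna() | ~np.isfinite(ages), "sample_id"].tolist()
            raise ValidationError(f"non-finite ages for samples: {bad[:5]}")
        if (ages < 0).any():
            bad = df.loc[ages < 0, "sample_id"].tolist()
            raise ValidationError(f"negative ages for samples: {bad[:5]}")
        df = df.copy()
        df["age"] = ages.astype(float)
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    @property
    def ages(self) -> np.ndarray:
        return self.df["age"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, sample_ids) -> "SampleSheet":
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleSheet(sub)

    def replicate_pairs(self) -> dict[str, list[str]]:
        """Map replicate_group -> sample ids, sorted by age within group."""
        if "replicate_group" not in self.df.columns:
            return {}
        out: dict[str, list[str]] = {}
        sub = self.df.dropna(subset=["replicate_group"])
        for grp, rows in sub.groupby("replicate_group", sort=True):
            ordered = rows.sort_values(["age", "sample_id"])
            out[str(grp)] = ordered["sample_id"].tolist()
        return out

    def __repr__(self) -> str:
        return f"SampleSheet({len(self)} samples)"


class ProbeManifest:
    """Per-probe genomic coordinates and nearest-gene annotation.

    Positions are 1-based. ``dist_to_tss`` is signed in the orientation of
    the nearest gene (negative upstream of the TSS). ``feature`` is one of
    :data:`FEATURE_CLASSES`.
    """

    REQUIRED = ("probe_id", "chrom", "pos")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if df["probe_id"].duplicated().any():
            dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        pos = pd.to_numeric(df["pos"], errors="coerce")
        if pos.isna().any() or (pos < 1).any():
            bad = df.loc[pos.isna() | (pos < 1), "probe_id"].tolist()
            raise ValidationError(f"positions must be integers >= 1 (1-based): {bad[:5]}")
        df = df.copy()
        df["pos"] = pos.astype(int)
        if "feature" in df.columns:
            bad_feat = set(df["feature"].dropna()) - set(FEATURE_CLASSES)
            if bad_feat:
                raise ValidationError(f"unknown feature classes: {sorted(bad_feat)}")
        else:
            df["feature"] = "unassigned"
        self.df = df.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.df["probe_id"])

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"ProbeManifest({len(self)} probes)"


@dataclass
class JoinReport:
    """Book-keeping from aligning a beta matrix with a sample sheet."""

    dropped_from_matrix: list[str] = field(default_factory=list)
    dropped_from_sheet: list[str] = field(default_factory=list)


def join_samples(bm: BetaMatrix, sheet: SampleSheet) -> tuple[BetaMatrix, SampleSheet, JoinReport]:
    """Align a beta matrix and a sample sheet on their shared samples.

    The result follows the sheet's ordering. Samples present in only one of
    the two inputs are dropped and reported.

    Raises
    ------
    ValidationError
        If the two inputs share no samples.
    """
    bm_ids = set(bm.sample_ids)
    sheet_ids = set(sheet.sample_ids)
    shared = [s for s in sheet.sample_ids if s in bm_ids]
    if not shared:
        raise ValidationError("beta matrix and sample sheet share no sample ids")
    report = JoinReport(
        dropped_from_matrix=sorted(bm_ids - sheet_ids),
        dropped_from_sheet=sorted(sheet_ids - bm_ids),
    )
    return bm.subset_samples(shared), sheet.subset(shared), report
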