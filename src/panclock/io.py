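"""Readers and writers for the package's tabular formats.

Beta matrices, sample sheets and probe manifests are plain delimited text
(TSV for ``.tsv``/``.txt``, CSV otherwise); lines starting with ``#`` are
treated as provenance headers and skipped on read. Clock models are stored
as a sectioned key-value text file (``[meta]``, ``[transform]``,
``[coefficients]``) with floats written via ``repr`` so that a write/read
cycle is bit-exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd

from .datamodel import BetaMatrix, ProbeManifest, SampleSheet, SpeciesInfo, ValidationError
from .transforms import KINDS, TransformSpec

if TYPE_CHECKING:  # avoid a circular import; clock.py imports nothing from here
    from .clock import ClockModel

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_clock_model",
    "write_clock_model",
    "ClockModelParseError",
]


def _sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _write_df(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = (), index: bool = False) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep(path), index=index)


def read_beta_matrix(path: str | Path, orientation: str = "probes") -> BetaMatrix:
    """Read a delimited beta-value matrix.

    Parameters
    ----------
    path
        Delimited text file with an identifier header row and an identifier
        first column.
    orientation
        ``"probes"`` if rows are probes (GEO series-matrix style) or
        ``"samples"`` if rows are samples; the result is always
        probes x samples.
    """
    if orientation not in ("probes", "samples"):
        raise ValueError("orientation must be 'probes' or 'samples'")
    df = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples":
        df = df.T
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    df = bm.values.copy()
    df.index.name = "probe_id"
    _write_df(df, path, header_lines, index=True)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    _write_df(sheet.df, path, header_lines)


def read_probe_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype={"probe_id": str, "chrom": str})
    return ProbeManifest(df)


def write_probe_manifest(manifest: ProbeManifest, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    _write_df(manifest.df, path, header_lines)


# ---------------------------------------------------------------------------
# Clock model text format
# ---------------------------------------------------------------------------

class ClockModelParseError(ValidationError):
    """Raised on a malformed clock-model file; carries the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        where = f" (line {line_no})" if line_no is not None else ""
        super().__init__(f"{message}{where}")


def write_clock_model(model: "ClockModel", path: str | Path, comment_lines: Iterable[str] = ()) -> None:
    """Write a fitted clock to a portable sectioned key-value text file.

    Only non-zero coefficients are listed. Floats are written with ``repr``
    so the decimal text round-trips bit-exactly through ``float()``.
    """
    spec = model.transform
    lines: list[str] = [f"# {c}" for c in comment_lines]
    lines += [
        "[meta]",
        "format = panclock-model-1",
        f"alpha = {model.alpha!r}",
        f"lambda = {model.lam!r}",
        f"n_training_samples = {model.n_training}",
        f"n_coefficients = {len(model.coef)}",
        "",
        "[transform]",
        f"kind = {spec.kind}",
        f"k_offset = {spec.k_offset!r}",
    ]
    for name in sorted(spec.species):
        sp = spec.species[name]
        lines.append(f"species.{name} = {sp.max_lifespan!r},{sp.maturity_age!r}")
    lines += ["", "[coefficients]", f"intercept = {model.intercept!r}"]
    for probe in sorted(model.coef):
        lines.append(f"{probe} = {model.coef[probe]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clock_model(path: str | Path) -> "ClockModel":
    """Parse a clock-model file written by :func:`write_clock_model`."""
    from .clock import ClockModel

    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    order: list[str] = []  # coefficient insertion order within [coefficients]
    current_name = ""
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current_name = line[1:-1]
            current = sections.setdefault(current_name, {})
            continue
        if "=" not in line:
            raise ClockModelParseError(f"expected 'key = value', got {line!r}", line_no)
        if current is None:
            raise ClockModelParseError("key-value line before any [section]", line_no)
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in current:
            raise ClockModelParseError(f"duplicate key {key!r} in [{current_name}]", line_no)
        current[key] = value
        if current_name == "coefficients":
            order.append(key)

    for section in ("meta", "transform", "coefficients"):
        if section not in sections:
            raise ClockModelParseError(f"missing [{section}] section")

    meta, trans, coefs = sections["meta"], sections["transform"], sections["coefficients"]
    kind = trans.get("kind", "")
    if kind not in KINDS:
        raise ClockModelParseError(f"unknown transform kind {kind!r}; expected one of {KINDS}")
    species: dict[str, SpeciesInfo] = {}
    for key, value in trans.items():
        if key.startswith("species."):
            name = key[len("species."):]
            try:
                lifespan, maturity = (float(v) for v in value.split(","))
            except ValueError:
                raise ClockModelParseError(
                    f"species line must be 'max_lifespan,maturity_age', got {value!r}"
                ) from None
            species[name] = SpeciesInfo(name, lifespan, maturity)
    spec = TransformSpec(kind=kind, species=species, k_offset=float(trans.get("k_offset", 1.0)))

    if "intercept" not in coefs:
        raise ClockModelParseError("[coefficients] must contain an 'intercept' line")
    try:
        intercept = float(coefs["intercept"])
        coef = {k: float(v) for k, v in coefs.items() if k != "intercept"}
    except ValueError as exc:
        raise ClockModelParseError(f"non-numeric coefficient: {exc}") from None

    declared = int(meta.get("n_coefficients", len(coef)))
    if declared != len(coef):
        raise ClockModelParseError(
            f"file declares {declared} coefficients but lists {len(coef)} (truncated file?)"
        )

    return ClockModel(
        intercept=intercept,
        coef=coef,
        transform=spec,
        alpha=float(meta.get("alpha", 0.5)),
        lam=float(meta.get("lambda", "nan")),
        n_training=int(meta.get("n_training_samples", 0)),
    )
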