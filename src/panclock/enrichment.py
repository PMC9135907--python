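"""Hypergeometric over-representation of CpG sets against a restricted background.

Given a query probe set (e.g. age-gain CpGs), an annotated background
universe, and category -> probe maps (transcription-factor motif occupancy
or gene-set membership, read from GMT files), each category is tested with
the upper-tail hypergeometric probability

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

where N is the background size, K the category members inside the
background, n the query size inside the background, k the overlap.
Categories are intersected with the background first, mirroring the
restricted-background convention of array enrichment analyses.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .datamodel import ValidationError

__all__ = ["read_gmt", "write_gmt", "hypergeom_enrich", "hypergeom_upper_tail"]

log = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> member1 <tab> member2 ..."""
    out: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line {line_no}: need name, description, >=1 member")
        name = parts[0]
        if name in out:
            raise ValidationError(f"GMT line {line_no}: duplicate set name {name!r}")
        out[name] = {m for m in parts[2:] if m}
    return out


def write_gmt(categories: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name, *sorted(set(members))])
        for name, members in categories.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); k = 0 gives 1 exactly."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: Iterable[str],
    background: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Test each category for over-representation of the query in the background.

    Query members outside the background are dropped (count logged); each
    category is intersected with the background before testing. Fold
    enrichment is k*N / (n*K), NaN when undefined.
    """
    bg = set(background)
    if not bg:
        raise ValidationError("empty background universe")
    q_all = set(query)
    q = q_all & bg
    dropped = len(q_all) - len(q)
    if dropped:
        log.warning("%d query probes outside the background were dropped", dropped)
    N, n = len(bg), len(q)
    rows = []
    for name in sorted(category_map):
        members = set(category_map[name]) & bg
        K = len(members)
        k = len(q & members)
        fold = (k * N) / (n * K) if n and K else float("nan")
        rows.append({
            "set_name": name, "background_size": N, "background_successes": K,
            "query_size": n, "overlap": k,
            "p": hypergeom_upper_tail(N, K, n, k), "fold_enrichment": fold,
        })
    return pd.DataFrame(rows)
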