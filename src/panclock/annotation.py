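"""Probe-to-gene annotation relative to the closest transcription start site.

Each probe is assigned to its nearest gene by minimal absolute signed TSS
distance. Distances are oriented: negative upstream of the TSS *in the
gene's reading direction*, positive downstream, so a probe at coordinate
5100 next to a minus-strand gene spanning [1000, 5000] sits 100 bp
upstream (distance -100). Feature classes are assigned with the precedence

    promoter > five_prime_utr > exon > intron > downstream > intergenic

where "promoter" is a configurable window around the TSS (default
-2000..+500 bp oriented) and "downstream" a window past the gene's 3' end.
All coordinates are 1-based closed internally; BED input (0-based
half-open) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ProbeManifest, ValidationError

__all__ = [
    "GeneModel",
    "read_bed12",
    "read_gff3",
    "annotate_probes",
    "feature_distribution",
]

Interval = tuple[int, int]  # 1-based closed


@dataclass
class GeneModel:
    """One gene: span, strand, exon and 5'-UTR intervals (1-based closed)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    five_prime_utrs: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in [(self.start, self.end), *self.exons, *self.five_prime_utrs]:
            if not (1 <= s <= e):
                raise ValidationError(f"gene {self.gene_id}: bad interval ({s}, {e})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    def signed_tss_distance(self, pos: int) -> int:
        """Oriented distance from the TSS; negative upstream of the gene."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file (0-based half-open, converted).

    Block structure provides the exons; the 5' UTR is taken as the part of
    the transcript between the transcription start and ``thickStart`` (the
    coding start) on the appropriate strand, intersected with the exons.
    """
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = []
    for row in df.itertuples(index=False):
        start1, end1 = int(row.start) + 1, int(row.end)  # to 1-based closed
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(int(row.start) + off + 1, int(row.start) + off + size)
                 for off, size in zip(offsets, sizes)]
        # untranslated leader: transcript bases 5' of the coding start
        thick_start1, thick_end1 = int(row.thick_start) + 1, int(row.thick_end)
        if row.strand == "+":
            utr_span = (start1, thick_start1 - 1) if thick_start1 > start1 else None
        else:
            utr_span = (thick_end1 + 1, end1) if thick_end1 < end1 else None
        utrs = []
        if utr_span:
            for es, ee in exons:
                s, e = max(es, utr_span[0]), min(ee, utr_span[1])
                if s <= e:
                    utrs.append((s, e))
        genes.append(GeneModel(str(row.name), str(row.chrom), str(row.strand),
                               start1, end1, exons, utrs))
    return genes


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (already 1-based closed, taken as-is)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("Name", g.attributes.get("ID", [g.id]))[0]
        exons = [(f.start, f.end) for f in db.children(g, featuretype="exon")]
        utrs = [(f.start, f.end) for f in db.children(g, featuretype="five_prime_UTR")]
        genes.append(GeneModel(gene_id, g.seqid, g.strand, g.start, g.end,
                               sorted(exons), sorted(utrs)))
    return genes


def _in_any(pos: int, intervals: list[Interval]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def annotate_probes(
    manifest: ProbeManifest,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = (-2000, 500),
    downstream_window: int = 3000,
) -> ProbeManifest:
    """Fill nearest_gene, dist_to_tss and feature for every manifest probe.

    Nearest gene = minimal |signed TSS distance|, ties broken by
    lexicographic gene id. Probes on chromosomes absent from the gene set
    become ``intergenic`` with the ``off_chromosome`` flag set.
    """
    if promoter_window[0] > promoter_window[1]:
        raise ValidationError(f"bad promoter window {promoter_window}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        by_chrom.setdefault(g.chrom, []).append(g)

    nearest: list[str | None] = []
    dists: list[float] = []
    feats: list[str] = []
    off: list[bool] = []
    for row in manifest.df.itertuples(index=False):
        cands = by_chrom.get(str(row.chrom))
        if not cands:
            nearest.append(None)
            dists.append(np.nan)
            feats.append("intergenic")
            off.append(True)
            continue
        # lexicographic gene order above makes min() break ties as declared
        best = min(cands, key=lambda g: abs(g.signed_tss_distance(int(row.pos))))
        d = best.signed_tss_distance(int(row.pos))
        pos = int(row.pos)
        if promoter_window[0] <= d <= promoter_window[1]:
            feat = "promoter"
        elif _in_any(pos, best.five_prime_utrs):
            feat = "five_prime_utr"
        elif _in_any(pos, best.exons):
            feat = "exon"
        elif best.start <= pos <= best.end:
            feat = "intron"
        else:
            tail = (pos - best.three_prime_end if best.strand == "+"
                    else best.three_prime_end - pos)
            feat = "downstream" if 0 < tail <= downstream_window else "intergenic"
        nearest.append(best.gene_id)
        dists.append(float(d))
        feats.append(feat)
        off.append(False)

    df = manifest.df.copy()
    df["nearest_gene"] = nearest
    df["dist_to_tss"] = dists
    df["feature"] = feats
    df["off_chromosome"] = off
    return ProbeManifest(df)


def feature_distribution(selected_probes: list[str], manifest: ProbeManifest) -> pd.DataFrame:
    """Feature-class counts and fractions for a selection vs the full universe."""
    from .datamodel import FEATURE_CLASSES

    man = manifest.df.set_index("probe_id")
    sel_feats = man.loc[[p for p in selected_probes if p in man.index], "feature"]
    rows = []
    n_sel, n_bg = len(sel_feats), len(man)
    for feat in FEATURE_CLASSES:
        k_sel = int((sel_feats == feat).sum())
        k_bg = int((man["feature"] == feat).sum())
        rows.append({
            "feature": feat,
            "selected_count": k_sel,
            "selected_fraction": k_sel / n_sel if n_sel else 0.0,
            "background_count": k_bg,
            "background_fraction": k_bg / n_bg if n_bg else 0.0,
        })
    return pd.DataFrame(rows)
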