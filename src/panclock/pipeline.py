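"""Config-driven orchestration of the full study workflow.

A run executes, in order: ingest (files or a named synthetic fixture) ->
clustering QC -> clock fitting and LOOCV -> per-tissue EWAS with meta-
analysis -> directional top-CpG selection and overlap -> annotation-based
feature distributions -> optional GMT enrichment. Every output file starts
with ``#`` provenance lines carrying the config hash and seed, and reruns
with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from . import clustering, enrichment, ewas, io
from .simulate import FIXTURES, HUMAN, VERVET, make_fixture
from .datamodel import SpeciesInfo, ValidationError, join_samples
from .transforms import TransformSpec

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, clock scopes and thresholds for one pipeline run."""

    # either a fixture name ...
    fixture: str | None = None
    # ... or explicit input files
    beta_path: str | None = None
    sheet_path: str | None = None
    manifest_path: str | None = None
    gene_model_path: str | None = None  # BED12 or GFF3, optional
    gmt_path: str | None = None  # category map for enrichment, optional

    species: list[dict[str, Any]] = field(default_factory=list)
    clocks: list[dict[str, Any]] = field(
        default_factory=lambda: [{"name": "pan", "transform": "identity", "loocv": True}]
    )
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    p_cut: float = 1e-10
    plot_cut: float = 1e-20
    cap_per_direction: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def preflight(self) -> None:
        """Fail on any missing input before running a single stage."""
        if self.fixture is None and (self.beta_path is None or self.sheet_path is None):
            raise ValidationError("config needs either a fixture name or beta+sheet paths")
        if self.fixture is not None and self.fixture not in FIXTURES:
            raise ValidationError(
                f"unknown fixture {self.fixture!r}; available: {sorted(FIXTURES)}"
            )
        for label in ("beta_path", "sheet_path", "manifest_path", "gene_model_path", "gmt_path"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{label} does not exist: {value}")
        if self.p_cut <= 0 or self.plot_cut <= 0 or self.cap_per_direction <= 0:
            raise ValidationError("thresholds must be positive")

    def species_info(self) -> dict[str, SpeciesInfo]:
        out = {}
        for entry in self.species:
            sp = SpeciesInfo(entry["name"], float(entry["max_lifespan"]),
                             float(entry.get("maturity_age", 1.0)))
            out[sp.name] = sp
        return out


def _transform_for(name: str, cfg: RunConfig, sheet) -> TransformSpec:
    if name == "identity":
        return TransformSpec("identity")
    species = cfg.species_info()
    if not species:
        # fall back to the registered fixture species
        species = {sp.name: sp for sp in (VERVET, HUMAN)}
    present = set(sheet.df["species"])
    return TransformSpec(name, {k: v for k, v in species.items() if k in present} or species)


def run_all(cfg: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute every stage; returns a summary dict (also written as JSON)."""
    cfg.preflight()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={cfg.digest()}", f"seed={cfg.seed}"]
    summary: dict[str, Any] = {"config_hash": cfg.digest(), "seed": cfg.seed, "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        return summary["stages"].setdefault(name, {})

    try:
        # --- ingest / simulate --------------------------------------------
        info = stage("ingest")
        if cfg.fixture is not None:
            bundle = make_fixture(cfg.fixture, seed=cfg.seed)
            bm, sheet, manifest = bundle.beta, bundle.sheet, bundle.manifest
            io.write_beta_matrix(bm, outdir / "beta.csv", header)
            io.write_sample_sheet(sheet, outdir / "samples.csv", header)
            io.write_probe_manifest(manifest, outdir / "manifest.csv", header)
        else:
            bm = io.read_beta_matrix(cfg.beta_path)
            sheet = io.read_sample_sheet(cfg.sheet_path)
            manifest = io.read_probe_manifest(cfg.manifest_path) if cfg.manifest_path else None
        bm, sheet, join_report = join_samples(bm, sheet)
        bm, n_dropped_probes = bm.complete_probes()
        info.update(n_samples=len(sheet), n_probes=bm.shape[0],
                    dropped_incomplete_probes=n_dropped_probes,
                    dropped_samples=len(join_report.dropped_from_matrix)
                    + len(join_report.dropped_from_sheet))

        # --- clustering QC ------------------------------------------------
        info = stage("cluster")
        report = clustering.cluster_samples(bm, cfg.cluster_distance, cfg.cluster_linkage)
        tissues = sorted(set(sheet.df["tissue"]))
        k = max(2, len(tissues))
        purity = report.purity(sheet, k)
        (outdir / "dendrogram.nwk").write_text(report.to_newick())
        labels = report.labels(k).rename_axis("sample_id").reset_index()
        io_header = [f"# {h}" for h in header]
        (outdir / "clusters.csv").write_text(
            "\n".join(io_header) + "\n" + labels.to_csv(index=False))
        info.update(k=k, purity=purity)

        # --- clocks -------------------------------------------------------
        info = stage("clocks")
        for entry in cfg.clocks:
            name = entry["name"]
            tspec = _transform_for(entry.get("transform", "identity"), cfg, sheet)
            scope_sheet = sheet
            if entry.get("tissues"):
                keep = sheet.df["tissue"].isin(entry["tissues"])
                scope_sheet = sheet.subset(sheet.df.loc[keep, "sample_id"])
            if entry.get("species"):
                keep = scope_sheet.df["species"].isin(entry["species"])
                scope_sheet = scope_sheet.subset(scope_sheet.df.loc[keep, "sample_id"])
            spec = clock_mod.ClockSpec(transform=tspec, seed=cfg.seed)
            model = clock_mod.train_clock(bm, scope_sheet, spec)
            io.write_clock_model(model, outdir / f"clock_{name}.txt", header)
            entry_summary = {"n_coefficients": len(model.coef), "lambda": model.lam,
                             "n_training": model.n_training}
            if entry.get("loocv", False):
                ev = clock_mod.loocv(bm, scope_sheet, spec)
                ev.predictions.to_csv(outdir / f"loocv_{name}.csv", index=False)
                entry_summary.update(loocv_r=ev.r, loocv_mae=ev.mae)
            info[name] = entry_summary

        # --- EWAS + selection + overlap -----------------------------------
        info = stage("ewas")
        per_tissue = ewas.ewas_all_tissues(bm, sheet)
        selections = []
        for tissue, res in per_tissue.items():
            res.to_csv(outdir / f"ewas_{tissue}.csv")
            gain, loss = ewas.select_top(res, tissue, cfg.p_cut, cfg.cap_per_direction)
            selections += [gain, loss]
            info[tissue] = {
                "n_significant": int((res["log10_p"] < np.log10(cfg.p_cut)).sum()),
                "gain": len(gain), "loss": len(loss),
            }
        if len(per_tissue) >= 2:
            zmat = pd.DataFrame({t: res["z"] for t, res in per_tissue.items()})
            meta = ewas.stouffer_meta(zmat)
            meta.to_csv(outdir / "ewas_meta.csv")
            gain, loss = ewas.select_top(meta, "meta", cfg.p_cut, cfg.cap_per_direction)
            selections += [gain, loss]
            info["meta"] = {"gain": len(gain), "loss": len(loss)}
        for sel in selections:
            (outdir / f"selection_{sel.label}.txt").write_text("\n".join(sel.probes) + "\n")
        if len([s for s in selections if len(s)]) >= 2:
            cells = ewas.overlap_sets([s for s in selections if len(s)])
            cells.assign(probes=cells["probes"].map(";".join)).to_csv(
                outdir / "overlap.csv", index=False)
            info["overlap_cells"] = len(cells)

        # --- annotation + enrichment --------------------------------------
        if manifest is not None:
            from .annotation import annotate_probes, feature_distribution, read_bed12, read_gff3

            info = stage("annotation")
            if cfg.gene_model_path:
                reader = read_gff3 if str(cfg.gene_model_path).endswith((".gff", ".gff3")) else read_bed12
                manifest = annotate_probes(manifest, reader(cfg.gene_model_path))
                io.write_probe_manifest(manifest, outdir / "manifest_annotated.csv", header)
            for sel in selections:
                if len(sel):
                    dist = feature_distribution(sel.probes, manifest)
                    dist.to_csv(outdir / f"features_{sel.label}.csv", index=False)
            info["n_selections_annotated"] = sum(1 for s in selections if len(s))

            if cfg.gmt_path:
                info = stage("enrichment")
                categories = enrichment.read_gmt(cfg.gmt_path)
                background = manifest.probe_ids.tolist()
                for sel in selections:
                    if len(sel):
                        table = enrichment.hypergeom_enrich(sel.probes, background, categories)
                        table.to_csv(outdir / f"enrichment_{sel.label}.csv", index=False)
                info["n_categories"] = len(categories)
    except Exception as exc:
        current = list(summary["stages"])[-1] if summary["stages"] else "preflight"
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
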