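"""Synthetic multi-species, multi-tissue methylation datasets with planted age signal.

The generator emulates the structure of a cross-sectional primate
methylation study: a few tissues sampled across the whole lifespan, strong
tissue-of-origin differences, a minority of CpGs whose methylation drifts
with age (some shared across tissues, some tissue-specific), a promoter
bias among CpGs that *gain* methylation with age, longitudinal replicate
pairs from the same animals, and optionally a second species with a very
different maximum lifespan.

Signal is linear on the latent M-value (logit2) scale, not the beta scale:

    L_ij = b0_j + tissue_offset_j(tissue_i) + animal_effect_ij
           + slope_j * T(age_i) + eps_ij,      eps ~ N(0, noise_sd)

    beta_ij = 1 / (1 + 2^(-L_ij))

where T is the species' relative age (age / max lifespan), so that a given
latent slope means the same thing in species with 30-year and 120-year
lifespans. The logistic map keeps every emitted beta strictly inside (0, 1)
and mimics the saturation real probes show near fully (un)methylated.
Slope-recovery comparisons therefore belong on the latent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    ProbeManifest,
    SampleSheet,
    SpeciesInfo,
    ValidationError,
)

__all__ = ["SimConfig", "SimTruth", "FixtureBundle", "simulate", "make_fixture", "FIXTURES"]

VERVET = SpeciesInfo("vervet", max_lifespan=30.8, maturity_age=5.0)
HUMAN = SpeciesInfo("human", max_lifespan=122.5, maturity_age=15.0)

# background genomic-feature mix for probes without planted gain bias
BACKGROUND_FEATURES = ("promoter", "five_prime_utr", "exon", "intron", "downstream", "intergenic")
BACKGROUND_PROPS = (0.15, 0.05, 0.20, 0.35, 0.05, 0.20)
# methylation-gain probes sit preferentially in promoters / 5' UTRs
GAIN_PROPS = (0.60, 0.20, 0.08, 0.07, 0.02, 0.03)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults define the standard study conditions.

    Counts are per (species, tissue) arm. Latent-scale units: slopes are per
    unit of relative age (a slope of 4 moves a mid-range probe most of the
    way across its dynamic range over a lifespan); ``tissue_offset_sd``,
    ``noise_sd`` and ``animal_sd`` are latent logit2 standard deviations.
    """

    n_samples_per_tissue: int = 50
    tissues: tuple[str, ...] = ("blood", "cortex", "liver")
    species: tuple[SpeciesInfo, ...] = (VERVET,)
    n_probes: int = 3000
    n_age_probes_shared: int = 150
    n_age_probes_per_tissue: int = 50
    slope_mean: float = 4.0
    slope_sd: float = 1.5
    slope_min: float = 0.5
    fraction_hyper: float = 0.6
    tissue_offset_sd: float = 1.0
    noise_sd: float = 0.5
    animal_sd: float = 0.25
    baseline_sd: float = 1.5
    n_longitudinal_pairs: int = 0
    pair_gap_range: tuple[float, float] = (3.9, 10.93)
    age_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"vervet": (0.0, 26.0), "human": (0.0, 90.0)}
    )
    #: optional (tissue, age threshold in years, latent sd) extra offset applied
    #: to samples of that tissue older than the threshold — plants an
    #: age-coherent subcluster for clustering diagnostics
    old_tissue_shift: tuple[str, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples_per_tissue, self.n_probes, self.n_age_probes_shared,
               self.n_age_probes_per_tissue, self.n_longitudinal_pairs) < 0:
            raise ValidationError("all counts must be >= 0")
        n_planted = self.n_age_probes_shared + len(self.tissues) * self.n_age_probes_per_tissue
        if n_planted > self.n_probes:
            raise ValidationError(
                f"{n_planted} planted age probes exceed n_probes={self.n_probes}"
            )
        if not (0 <= self.fraction_hyper <= 1):
            raise ValidationError(f"fraction_hyper must be in [0, 1], got {self.fraction_hyper}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for sp in self.species:
            if sp.name not in self.age_range:
                raise ValidationError(f"no age_range for species {sp.name!r}")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests.

    ``probes``: probe_id, is_age_associated, affected tissues ("*" = all),
    latent slope. ``samples``: sample_id, animal_id, species, tissue, age,
    replicate_group.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame

    def planted_probe_ids(self, tissue: str | None = None) -> list[str]:
        df = self.probes[self.probes["is_age_associated"]]
        if tissue is not None:
            df = df[(df["tissues"] == "*") | (df["tissues"] == tissue)]
        return df["probe_id"].tolist()


@dataclass
class FixtureBundle:
    name: str
    config: SimConfig
    beta: BetaMatrix
    sheet: SampleSheet
    manifest: ProbeManifest
    truth: SimTruth


def _draw_slopes(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    mag = np.maximum(rng.normal(cfg.slope_mean, cfg.slope_sd, n), cfg.slope_min)
    sign = np.where(rng.random(n) < cfg.fraction_hyper, 1.0, -1.0)
    return mag * sign


def simulate(cfg: SimConfig) -> tuple[BetaMatrix, SampleSheet, ProbeManifest, SimTruth]:
    """Generate one dataset under ``cfg``; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n_probes = cfg.n_probes
    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]

    # --- planted age signal ------------------------------------------------
    slopes = np.zeros((n_probes, len(cfg.tissues)))  # per probe x tissue
    tissues_of = np.array([""] * n_probes, dtype=object)
    is_age = np.zeros(n_probes, dtype=bool)
    shared = np.arange(cfg.n_age_probes_shared)
    shared_slopes = _draw_slopes(rng, len(shared), cfg)
    slopes[shared, :] = shared_slopes[:, None]
    is_age[shared] = True
    tissues_of[shared] = "*"
    cursor = cfg.n_age_probes_shared
    for t_idx, tissue in enumerate(cfg.tissues):
        idx = np.arange(cursor, cursor + cfg.n_age_probes_per_tissue)
        slopes[idx, t_idx] = _draw_slopes(rng, len(idx), cfg)
        is_age[idx] = True
        tissues_of[idx] = tissue
        cursor += cfg.n_age_probes_per_tissue

    baseline = rng.normal(0.0, cfg.baseline_sd, n_probes)
    tissue_offsets = rng.normal(0.0, cfg.tissue_offset_sd, (n_probes, len(cfg.tissues)))
    old_shift = None
    if cfg.old_tissue_shift is not None:
        old_shift = rng.normal(0.0, cfg.old_tissue_shift[2], n_probes)

    # --- samples -----------------------------------------------------------
    rows: list[dict] = []
    animal_counter = 0
    for sp in cfg.species:
        lo, hi = cfg.age_range[sp.name]
        for tissue in cfg.tissues:
            ages = rng.uniform(lo, hi, cfg.n_samples_per_tissue)
            for age in ages:
                animal_counter += 1
                rows.append({
                    "animal_id": f"an{animal_counter:05d}", "species": sp.name,
                    "tissue": tissue, "age": float(age), "replicate_group": None,
                })
    # longitudinal pairs: first species, first tissue, shared animal baseline
    if cfg.n_longitudinal_pairs:
        sp = cfg.species[0]
        lo, hi = cfg.age_range[sp.name]
        g_lo, g_hi = cfg.pair_gap_range
        if hi - lo <= g_hi:
            raise ValidationError("age_range too narrow for the requested pair gaps")
        for _ in range(cfg.n_longitudinal_pairs):
            animal_counter += 1
            gap = rng.uniform(g_lo, g_hi)
            early = rng.uniform(lo, hi - gap)
            for age in (early, early + gap):
                rows.append({
                    "animal_id": f"an{animal_counter:05d}", "species": sp.name,
                    "tissue": cfg.tissues[0], "age": float(age),
                    "replicate_group": f"an{animal_counter:05d}",
                })
    samples = pd.DataFrame(rows)
    samples.insert(0, "sample_id", [f"s{i:05d}" for i in range(len(samples))])
    samples["sex"] = np.where(rng.random(len(samples)) < 0.5, "F", "M")

    # --- latent matrix -> betas -------------------------------------------
    max_lifespan = {sp.name: sp.max_lifespan for sp in cfg.species}
    rel_age = samples["age"].to_numpy() / samples["species"].map(max_lifespan).to_numpy()
    tissue_idx = samples["tissue"].map({t: i for i, t in enumerate(cfg.tissues)}).to_numpy()

    animal_ids = samples["animal_id"].to_numpy()
    unique_animals, animal_pos = np.unique(animal_ids, return_inverse=True)
    animal_fx = rng.normal(0.0, cfg.animal_sd, (n_probes, len(unique_animals)))

    L = (
        baseline[:, None]
        + tissue_offsets[:, tissue_idx]
        + animal_fx[:, animal_pos]
        + slopes[:, tissue_idx] * rel_age[None, :]
    )
    if cfg.noise_sd > 0:
        L = L + rng.normal(0.0, cfg.noise_sd, L.shape)
    if old_shift is not None:
        t_name, age_thr, _ = cfg.old_tissue_shift
        mask = ((samples["tissue"] == t_name) & (samples["age"] > age_thr)).to_numpy()
        L[:, mask] += old_shift[:, None]

    beta = 1.0 / (1.0 + np.exp2(-L))
    bm = BetaMatrix(pd.DataFrame(beta, index=probe_ids, columns=samples["sample_id"]))

    # --- manifest ----------------------------------------------------------
    manifest = _make_manifest(rng, probe_ids, slopes, is_age)

    sheet = SampleSheet(samples[["sample_id", "species", "tissue", "sex", "age",
                                 "replicate_group", "animal_id"]])
    truth = SimTruth(
        probes=pd.DataFrame({
            "probe_id": probe_ids, "is_age_associated": is_age,
            "tissues": tissues_of,
            # for shared probes all tissue slopes are equal; report the max-|.|
            "slope": slopes[np.arange(n_probes), np.abs(slopes).argmax(axis=1)],
        }),
        samples=samples,
    )
    return bm, sheet, manifest, truth


def _make_manifest(rng: np.random.Generator, probe_ids: list[str],
                   slopes: np.ndarray, is_age: np.ndarray) -> ProbeManifest:
    """Synthetic manifest: gain probes land preferentially in promoters/5'UTRs."""
    n = len(probe_ids)
    gain = is_age & (slopes.max(axis=1) > 0)
    features = np.empty(n, dtype=object)
    features[~gain] = rng.choice(BACKGROUND_FEATURES, size=int((~gain).sum()), p=BACKGROUND_PROPS)
    features[gain] = rng.choice(BACKGROUND_FEATURES, size=int(gain.sum()), p=GAIN_PROPS)

    dist_ranges = {
        "promoter": (-2000, 500), "five_prime_utr": (1, 800), "exon": (200, 5000),
        "intron": (500, 50000), "downstream": (1000, 3000), "intergenic": (20000, 200000),
    }
    dist = np.array([rng.integers(*dist_ranges[f]) for f in features])
    dist[features == "intergenic"] *= rng.choice([-1, 1], size=n)[features == "intergenic"]

    chroms = [f"chr{(i % 20) + 1}" for i in range(n)]
    pos = np.cumsum(rng.integers(500, 5000, n)) + 1
    genes = [f"g{(i // 5):05d}" for i in range(n)]  # ~5 probes per gene
    strand = rng.choice(["+", "-"], size=n)
    return ProbeManifest(pd.DataFrame({
        "probe_id": probe_ids, "chrom": chroms, "pos": pos,
        "strand_of_nearest_gene": strand, "nearest_gene": genes,
        "dist_to_tss": dist, "feature": features,
    }))


# ---------------------------------------------------------------------------
# Fixture registry
# ---------------------------------------------------------------------------

def _two_species_cfg(seed: int) -> SimConfig:
    return SimConfig(
        n_samples_per_tissue=40, tissues=("blood",), species=(VERVET, HUMAN),
        n_probes=1000, n_age_probes_shared=100, n_age_probes_per_tissue=0, seed=seed,
    )


FIXTURES: dict[str, SimConfig] = {
    # <= 60 samples, <= 500 probes, sub-second: smoke tests and CLI demos
    "tiny": SimConfig(n_samples_per_tissue=15, n_probes=400,
                      n_age_probes_shared=40, n_age_probes_per_tissue=10, seed=101),
    # the standard recovery conditions: 3 tissues x 50 samples, 3000 probes,
    # 300 planted age CpGs (150 shared + 50 per tissue)
    "three-tissue": SimConfig(seed=202),
    # vervet + human, lifespans 30.8 / 122.5 y, shared relative-age signal
    "two-species": _two_species_cfg(303),
    # no planted signal at all: EWAS calibration (>= 1000 probes per tissue)
    "null": SimConfig(n_samples_per_tissue=50, n_probes=1200,
                      n_age_probes_shared=0, n_age_probes_per_tissue=0, seed=404),
    # small single-tissue null for permutation-based LOOCV bounds
    "null-small": SimConfig(n_samples_per_tissue=40, tissues=("blood",), n_probes=400,
                            n_age_probes_shared=0, n_age_probes_per_tissue=0, seed=505),
    # blood arm with 14 longitudinal replicate pairs 3.9-10.93 y apart
    "longitudinal": SimConfig(n_samples_per_tissue=60, tissues=("blood",),
                              n_probes=1200, n_age_probes_shared=120,
                              n_age_probes_per_tissue=0,
                              n_longitudinal_pairs=14, seed=606),
    # blood-arm EWAS power conditions: n = 144 samples
    "ewas": SimConfig(n_samples_per_tissue=144, tissues=("blood",), n_probes=2000,
                      n_age_probes_shared=200, n_age_probes_per_tissue=0, seed=707),
    # liver samples older than 8.7 y carry an extra latent offset -> subcluster
    "old-liver": SimConfig(n_samples_per_tissue=24, n_probes=1000,
                           n_age_probes_shared=60, n_age_probes_per_tissue=20,
                           old_tissue_shift=("liver", 8.7, 1.0), seed=808),
}


def make_fixture(name: str, seed: int | None = None) -> FixtureBundle:
    """Build a registered fixture; ``seed`` overrides the committed default."""
    try:
        cfg = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    bm, sheet, manifest, truth = simulate(cfg)
    return FixtureBundle(name, cfg, bm, sheet, manifest, truth)
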