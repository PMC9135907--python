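"""Epigenome-wide association of methylation with age, per tissue and meta.

Per tissue, each probe's beta values are tested against chronological age
with the Pearson correlation test:

    t = r * sqrt(n - 2) / sqrt(1 - r^2),     p two-sided from Student t(n-2),
    z = sign(r) * Phi^-1(1 - p/2).

p-values are carried in log space throughout: a perfectly age-tracking
probe at n = 144 has p far below the smallest positive double, and both the
z-score derivation and the selection thresholds must survive that underflow.
The ``p`` column is the (possibly underflowed-to-zero) linear value kept for
convenience; ``log10_p`` is the authoritative one.

Tissue-level results are combined with Stouffer's method,
Z = sum(w_i z_i) / sqrt(sum(w_i^2)), with equal weights by default or
sqrt(n) weights on request. Directional top-CpG lists take probes below a
hard p cut-off, ranked by |z|, capped per direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import BetaMatrix, SampleSheet, ValidationError

__all__ = [
    "screen_tissue",
    "ewas_all_tissues",
    "stouffer_meta",
    "CpGSelection",
    "select_top",
    "overlap_sets",
]

LOG10E = np.log10(np.e)


def _z_from_logp(logp: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed z with the same two-sided tail mass as exp(logp), in log space."""
    # z = sign * Phi^-1(1 - p/2) = -sign * Phi^-1(p/2); ndtri_exp takes log(p/2)
    return -sign * special.ndtri_exp(logp - np.log(2.0))


def _log_p_two_sided_t(t_abs: np.ndarray, df: int) -> np.ndarray:
    """log of the two-sided t-test p-value, robust to extreme statistics.

    Uses ``t.logsf`` where it is finite and otherwise the leading term of
    the regularized incomplete beta at small x = df/(df + t^2):

        p = I_x(df/2, 1/2) ~= x^(df/2) (1-x)^(1/2) / ((df/2) B(df/2, 1/2))

    The switch only engages when p < ~1e-300, where x < df/t^2 is tiny and
    the truncation error is negligible.
    """
    logp = np.log(2.0) + stats.t.logsf(t_abs, df)
    under = ~np.isfinite(logp)
    if under.any():
        a, b = df / 2.0, 0.5
        x = df / (df + t_abs[under] ** 2)
        logp[under] = (
            a * np.log(x) + b * np.log1p(-x) - np.log(a)
            - (special.gammaln(a) + special.gammaln(b) - special.gammaln(a + b))
        )
    return np.minimum(logp, 0.0)


def screen_tissue(bm: BetaMatrix, ages: np.ndarray, tissue: str = "") -> pd.DataFrame:
    """Correlation screen of every probe against age within one tissue.

    Returns a DataFrame indexed by probe id with columns ``tissue``, ``n``,
    ``r``, ``t``, ``p``, ``log10_p``, ``z`` and ``zero_variance``. Probes
    with no variance get r = 0, p = 1, z = 0 and the flag set.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if n < 4:
        raise ValidationError(f"need >= 4 samples for the correlation screen, got {n}")
    if np.ptp(ages) == 0:
        raise ValidationError("ages are constant; the screen is undefined")
    X = bm.values.to_numpy(dtype=float)
    if X.shape[1] != n:
        raise ValidationError(f"matrix has {X.shape[1]} samples but {n} ages given")
    if np.isnan(X).any():
        raise ValidationError("missing beta values; drop incomplete probes first")

    Xc = X - X.mean(axis=1, keepdims=True)
    ac = ages - ages.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=1))
    sa = np.sqrt((ac ** 2).sum())
    flat = sx == 0
    sx_safe = np.where(flat, 1.0, sx)
    r = (Xc @ ac) / (sx_safe * sa)
    r[flat] = 0.0
    # clip just inside +-1: a numerically perfect probe keeps a finite,
    # n-monotone statistic instead of collapsing to t = inf, p = 0
    r_lim = np.nextafter(1.0, 0.0)
    r = np.clip(r, -r_lim, r_lim)

    df_t = n - 2
    t = r * np.sqrt(df_t) / np.sqrt(1.0 - r ** 2)
    logp = _log_p_two_sided_t(np.abs(t), df_t)
    z = _z_from_logp(logp, np.sign(r))
    z[flat] = 0.0
    logp[flat] = 0.0

    return pd.DataFrame({
        "tissue": tissue, "n": n, "r": r, "t": t,
        "p": np.exp(logp), "log10_p": logp * LOG10E, "z": z,
        "zero_variance": flat,
    }, index=bm.probe_ids.rename("probe_id"))


def ewas_all_tissues(bm: BetaMatrix, sheet: SampleSheet) -> dict[str, pd.DataFrame]:
    """Run the screen separately in every tissue of a joined dataset."""
    out: dict[str, pd.DataFrame] = {}
    for tissue, sub in sheet.df.groupby("tissue", sort=True):
        sub_bm = bm.subset_samples(sub["sample_id"].tolist())
        out[str(tissue)] = screen_tissue(sub_bm, sub["age"].to_numpy(), str(tissue))
    return out


def stouffer_meta(
    z_by_tissue: pd.DataFrame,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Combine per-tissue signed z-scores into a meta z and two-sided p.

    Parameters
    ----------
    z_by_tissue
        Probes x tissues frame of signed z-scores; NaN marks a tissue where
        the probe was not testable.
    weights
        Per-tissue weights; equal weights when omitted. For each probe only
        the tissues with finite z contribute: Z = sum(w z) / sqrt(sum(w^2)).

    Probes with fewer than two finite z-scores are excluded (flagged NaN in
    the output's meta columns, ``n_tissues`` still reported).
    """
    if z_by_tissue.shape[1] < 2:
        raise ValidationError("Stouffer meta-analysis needs >= 2 tissues")
    w = np.array([1.0 if weights is None else float(weights[c]) for c in z_by_tissue.columns])
    Z = z_by_tissue.to_numpy(dtype=float)
    finite = np.isfinite(Z)
    n_tissues = finite.sum(axis=1)
    wz = np.where(finite, Z * w[None, :], 0.0).sum(axis=1)
    ww = np.where(finite, (w ** 2)[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        meta_z = wz / np.sqrt(ww)
    usable = n_tissues >= 2
    meta_z = np.where(usable, meta_z, np.nan)
    log_meta_p = np.where(
        usable,
        np.log(2.0) + stats.norm.logsf(np.abs(np.where(usable, meta_z, 0.0))),
        np.nan,
    )
    return pd.DataFrame({
        "meta_z": meta_z,
        "meta_p": np.exp(log_meta_p),
        "log10_meta_p": log_meta_p * LOG10E,
        "n_tissues": n_tissues,
    }, index=z_by_tissue.index)


@dataclass
class CpGSelection:
    """An ordered directional top-CpG list for one scope (tissue or meta)."""

    scope: str
    direction: str  # "gain" (z > 0) or "loss" (z < 0)
    probes: list[str]
    p_cut: float
    cap: int

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def label(self) -> str:
        return f"{self.scope}.{self.direction}"


def select_top(
    res: pd.DataFrame,
    scope: str,
    p_cut: float = 1e-10,
    cap_per_direction: int = 500,
) -> tuple[CpGSelection, CpGSelection]:
    """Directional top-CpG selection under a hard p threshold.

    Within each direction (z > 0 gain, z < 0 loss), probes with p < p_cut
    are ranked by |z| descending — ties broken by lexicographic probe id —
    and truncated at the cap. ``res`` may be a per-tissue screen (columns
    ``z``/``log10_p``) or a meta table (``meta_z``/``log10_meta_p``).
    """
    zcol, pcol = ("meta_z", "log10_meta_p") if "meta_z" in res.columns else ("z", "log10_p")
    log_cut = np.log10(p_cut)
    passing = res[res[pcol] < log_cut]

    def pick(direction: str) -> CpGSelection:
        sub = passing[passing[zcol] > 0] if direction == "gain" else passing[passing[zcol] < 0]
        # rank by (-|z|, probe_id): lexsort's last key is primary
        ranked = sub.iloc[np.lexsort((sub.index.to_numpy(), -sub[zcol].abs().to_numpy()))]
        return CpGSelection(scope, direction, ranked.index[:cap_per_direction].tolist(),
                            p_cut, cap_per_direction)

    return pick("gain"), pick("loss")


def overlap_sets(selections: list[CpGSelection]) -> pd.DataFrame:
    """Upset-style exclusive intersections across selection lists.

    Every probe in the union is assigned to exactly one membership pattern
    (the subset of selections containing it), so the cell counts sum to the
    union size. Returns one row per non-empty pattern with the member lists.
    """
    if len(selections) < 2:
        raise ValidationError("need >= 2 selections for an overlap analysis")
    labels = [s.label for s in selections]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"selection labels are not unique: {labels}")
    membership: dict[str, tuple[str, ...]] = {}
    for sel in selections:
        for probe in sel.probes:
            membership[probe] = membership.get(probe, ()) + (sel.label,)
    cells: dict[tuple[str, ...], list[str]] = {}
    for probe, pattern in membership.items():
        cells.setdefault(pattern, []).append(probe)
    rows = []
    for size in range(len(labels), 0, -1):
        for combo in combinations(labels, size):
            if combo in cells:
                members = sorted(cells[combo])
                rows.append({"pattern": "&".join(combo), "degree": size,
                             "count": len(members), "probes": members})
    return pd.DataFrame(rows)
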