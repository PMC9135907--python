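"""Unsupervised hierarchical clustering of samples for tissue-structure QC.

Samples of a well-behaved methylation dataset cluster perfectly by tissue
of origin; this module reproduces that diagnostic. The default metric is
1 - Pearson correlation across probes with average linkage — the standard
choice for methylation sample QC. Leaf order is canonicalized (tighter
subtree first, ties by smallest sample id) so reports are reproducible
regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .datamodel import BetaMatrix, SampleSheet, ValidationError

__all__ = ["ClusterReport", "cluster_samples", "subcluster_flag"]

_METRICS = {"correlation": "correlation", "euclidean": "euclidean"}
_LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterReport:
    """Linkage tree over samples plus flat-cut and purity helpers."""

    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]
    distance: str
    method: str

    def labels(self, k: int) -> pd.Series:
        """Flat cluster labels at a k-cluster cut (1..k), indexed by sample."""
        if not (1 <= k <= len(self.sample_ids)):
            raise ValidationError(f"k must be in [1, {len(self.sample_ids)}], got {k}")
        lab = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(lab, index=self.sample_ids, name="cluster")

    def purity(self, sheet: SampleSheet, k: int, attribute: str = "tissue") -> float:
        """Fraction of samples whose cluster's majority attribute matches their own."""
        lab = self.labels(k)
        attr = sheet.df.set_index("sample_id")[attribute].reindex(lab.index)
        correct = 0
        for _, idx in lab.groupby(lab).groups.items():
            values = attr.loc[idx]
            correct += int((values == values.mode().iloc[0]).sum())
        return correct / len(lab)

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.sample_ids, columns=self.sample_ids)

    def leaf_order(self) -> list[str]:
        """Canonical leaf order: tighter (lower) subtree first, ties by min sample id."""
        tree = hierarchy.to_tree(self.linkage)
        out: list[str] = []

        def key(node) -> tuple[float, str]:
            leaves = node.pre_order(lambda x: self.sample_ids[x.id])
            return (node.dist, min(leaves))

        def walk(node) -> None:
            if node.is_leaf():
                out.append(self.sample_ids[node.id])
                return
            left, right = sorted((node.left, node.right), key=key)
            walk(left)
            walk(right)

        walk(tree)
        return out

    def to_newick(self) -> str:
        """Ultrametric dendrogram as a newick string with branch lengths."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        return str(tree)


def cluster_samples(
    bm: BetaMatrix,
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterReport:
    """Hierarchically cluster the samples of a beta matrix.

    ``distance``: "correlation" (1 - Pearson across probes) or "euclidean";
    ``linkage``: average, complete or ward (ward requires euclidean).
    """
    if distance not in _METRICS:
        raise ValidationError(f"unknown distance {distance!r}; choose from {sorted(_METRICS)}")
    if linkage not in _LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {_LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValidationError("ward linkage requires the euclidean distance")
    if bm.shape[1] < 2:
        raise ValidationError(f"need >= 2 samples to cluster, got {bm.shape[1]}")
    X = bm.values.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(X).any():
        raise ValidationError("missing beta values; drop incomplete probes first")
    d = pdist(X, metric=_METRICS[distance])
    d = np.maximum(d, 0.0)  # correlation distance can dip below 0 by rounding
    Z = hierarchy.linkage(d, method=linkage)
    return ClusterReport(Z, [str(s) for s in bm.sample_ids], distance, linkage)


def subcluster_flag(
    report: ClusterReport,
    sheet: SampleSheet,
    attribute: pd.Series,
    k: int,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Detect attribute-coherent subclusters within each flat cluster.

    ``attribute`` is a boolean partition of all samples (indexed by sample
    id), e.g. age > 8.7 years. For every cluster at the k-cut that contains
    both groups, the cluster's own top split is examined: the cluster is
    flagged when one side captures >= ``threshold`` of the cluster's
    members of one group and is itself >= ``threshold`` pure for that group.
    """
    attr = attribute.reindex(report.sample_ids)
    if attr.isna().any():
        raise ValidationError("attribute must cover every clustered sample")
    attr = attr.astype(bool)
    if attr.all() or (~attr).all():
        raise ValidationError("attribute partition is degenerate (one group is empty)")

    tree = hierarchy.to_tree(report.linkage)
    ids = report.sample_ids

    def leaves(node) -> frozenset[str]:
        return frozenset(node.pre_order(lambda x: ids[x.id]))

    # map each subtree's leaf set to its node, to locate flat clusters' roots
    subtree: dict[frozenset[str], object] = {}

    def index(node) -> None:
        subtree[leaves(node)] = node
        if not node.is_leaf():
            index(node.left)
            index(node.right)

    index(tree)

    rows = []
    lab = report.labels(k)
    for cluster, members_idx in lab.groupby(lab).groups.items():
        members = frozenset(members_idx)
        flagged, detail = False, ""
        in_group = attr.loc[list(members)]
        if in_group.any() and (~in_group).any() and len(members) >= 4:
            node = subtree.get(members)
            if node is not None and not node.is_leaf():
                for side in (leaves(node.left), leaves(node.right)):
                    for grp in (True, False):
                        grp_members = {s for s in members if attr[s] == grp}
                        captured = len(side & grp_members) / len(grp_members)
                        side_purity = len(side & grp_members) / len(side)
                        if captured >= threshold and side_purity >= threshold:
                            flagged = True
                            detail = (f"group={grp} captured={captured:.2f} "
                                      f"purity={side_purity:.2f} side_n={len(side)}")
        rows.append({"cluster": cluster, "n": len(members), "flagged": flagged,
                     "detail": detail})
    return pd.DataFrame(rows)
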