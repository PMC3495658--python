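"""Taxonomic hierarchical clustering of group-average expression profiles.

Groups (tumour entities / subtypes) are summarised by their per-gene mean
log2 expression and clustered agglomeratively with average linkage under
one of five distance metrics: Euclidean, squared Euclidean, Manhattan,
Chebyshev, or "differential" — Euclidean distance between mean-centred
profiles, i.e. a distance that ignores overall intensity level and compares
expression *patterns*.  Trees are exportable as Newick with branch lengths
derived from the merge heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

METRICS = ("euclidean", "squared_euclidean", "manhattan", "chebyshev", "differential")


def group_average(expr: pd.DataFrame, annot: pd.DataFrame, study: str | None = None) -> pd.DataFrame:
    """Groups x genes matrix of per-group mean log2 expression."""
    sub_annot = annot if study is None else annot[annot["study"] == study]
    rows = {}
    for group, samples in sub_annot.groupby("group", sort=True):
        cols = list(samples.index)
        if not cols:
            raise ValueError(f"group {group!r} has no samples")
        rows[group] = expr[cols].mean(axis=1)
    if not rows:
        raise ValueError("annotation defines no groups")
    return pd.DataFrame(rows).T


@dataclass
class Dendrogram:
    """Average-linkage tree over group profiles."""

    labels: list[str]
    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix
    metric: str

    def merge_table(self) -> pd.DataFrame:
        """One row per merge: the two children, the height, the new size."""
        n = len(self.labels)
        names = list(self.labels) + [f"node{n + i}" for i in range(self.linkage.shape[0])]
        rows = []
        for i, (a, b, h, size) in enumerate(self.linkage):
            rows.append(
                {
                    "merge": i + 1,
                    "left": names[int(a)],
                    "right": names[int(b)],
                    "height": h,
                    "n_members": int(size),
                }
            )
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"

    def pair_of_first_merge(self) -> tuple[str, str]:
        a, b = int(self.linkage[0, 0]), int(self.linkage[0, 1])
        return self.labels[a], self.labels[b]

    def cophenetic_height(self, label_a: str, label_b: str) -> float:
        """Merge height at which two leaves first join."""
        from scipy.spatial.distance import squareform

        coph = squareform(hierarchy.cophenet(self.linkage))
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(coph[i, j])


def hcluster(profiles: pd.DataFrame, metric: str = "euclidean") -> Dendrogram:
    """Average-linkage hierarchical clustering of group profiles.

    ``profiles`` has one row per group (see :func:`group_average`).  The
    "differential" metric mean-centres each profile before taking the
    Euclidean distance, so only the expression pattern, not the level,
    drives the tree.  Deterministic: ties are resolved by scipy's fixed
    agglomeration order.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {', '.join(METRICS)}")
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 group profiles to cluster")
    x = profiles.to_numpy(dtype=float)
    if metric == "differential":
        x = x - x.mean(axis=1, keepdims=True)
        dists = pdist(x, metric="euclidean")
    elif metric == "squared_euclidean":
        dists = pdist(x, metric="sqeuclidean")
    elif metric == "manhattan":
        dists = pdist(x, metric="cityblock")
    else:
        dists = pdist(x, metric=metric)
    z = hierarchy.linkage(dists, method="average")
    return Dendrogram(labels=list(profiles.index), linkage=z, metric=metric)
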