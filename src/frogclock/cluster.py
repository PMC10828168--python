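"""Unsupervised hierarchical clustering of samples for QC.

Samples are compared by 1 minus the Pearson correlation of their beta
profiles across CpGs (pairwise-complete when values are missing), merged by
average linkage (UPGMA), and branch labels are read off by cutting the
dendrogram at a height threshold — the study's device for spotting species
structure and low-quality outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import MethylationCohort, ValidationError

__all__ = [
    "Dendrogram",
    "correlation_dissimilarity",
    "average_linkage",
    "cut_height",
    "to_newick",
]


@dataclass
class Dendrogram:
    """Merge sequence in scipy linkage convention.

    ``merges[i] = (a, b)`` joins clusters a and b (leaves are 0..n-1, the
    cluster formed by merge i is n+i) at dissimilarity ``heights[i]``.
    """

    merges: np.ndarray     # (n-1, 2) int
    heights: np.ndarray    # (n-1,) float
    leaf_order: np.ndarray # (n,) int, left-to-right leaf positions
    labels: list           # sample ids, indexed by leaf number

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def linkage_matrix(self) -> np.ndarray:
        """Reconstruct the scipy (n-1, 4) linkage matrix."""
        n = self.n_leaves
        sizes = np.ones(2 * n - 1)
        Z = np.zeros((n - 1, 4))
        for i, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            sizes[n + i] = sizes[int(a)] + sizes[int(b)]
            Z[i] = [a, b, h, sizes[n + i]]
        return Z


def correlation_dissimilarity(cohort: MethylationCohort) -> pd.DataFrame:
    """Sample-by-sample matrix d(i,j) = 1 - cor(beta_i, beta_j).

    Pearson correlations are computed across CpGs, pairwise-complete over
    missing values.  A sample with zero variance has no defined correlation
    and is rejected by name.
    """
    if cohort.n_samples < 2:
        raise ValidationError("need at least 2 samples to cluster")
    df = cohort.beta.to_frame()
    if (df.notna().sum(axis=0) < 3).any():
        raise ValidationError("need >= 3 observed CpGs per sample")
    sds = df.std(axis=0, ddof=0)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValidationError(f"constant beta profile for samples: {constant}")
    cor = df.corr(method="pearson")  # pairwise-complete by construction
    d = 1.0 - cor
    np.fill_diagonal(d.values, 0.0)
    # clamp numerical fuzz: exact duplicates must give exactly 0
    d.values[np.abs(d.values) < 1e-12] = 0.0
    return d


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram of a symmetric dissimilarity matrix."""
    values = np.asarray(dist, dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    labels = (list(dist.columns) if isinstance(dist, pd.DataFrame)
              else [str(i) for i in range(values.shape[0])])
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(
        merges=Z[:, :2].astype(int),
        heights=Z[:, 2].copy(),
        leaf_order=hierarchy.leaves_list(Z),
        labels=labels,
    )


def cut_height(dend: Dendrogram, h: float) -> pd.Series:
    """Branch labels from merges strictly below height *h*.

    Labels are 1..B, numbered by first appearance in left-to-right leaf
    order.  h=0 gives every sample its own branch; h above the last merge
    gives a single branch.
    """
    if h < 0:
        raise ValueError("cut height must be >= 0")
    n = dend.n_leaves
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, ((a, b), height) in enumerate(zip(dend.merges, dend.heights)):
        if height < h:
            node = n + i
            parent[find(int(a))] = node
            parent[find(int(b))] = node

    labels = {}
    next_label = 0
    assignment = {}
    for leaf in dend.leaf_order:
        root = find(int(leaf))
        if root not in labels:
            next_label += 1
            labels[root] = next_label
        assignment[dend.labels[int(leaf)]] = labels[root]
    return pd.Series(
        [assignment[s] for s in dend.labels], index=dend.labels, name="branch"
    )


def to_newick(dend: Dendrogram) -> str:
    """Newick string with branch lengths from merge-height differences."""
    n = dend.n_leaves
    height_of = {i: 0.0 for i in range(n)}

    def esc(label: str) -> str:
        return label.replace(" ", "_").replace(",", "_").replace(":", "_")

    node_str = {i: esc(dend.labels[i]) for i in range(n)}
    for i, ((a, b), h) in enumerate(zip(dend.merges, dend.heights)):
        a, b = int(a), int(b)
        la = max(h - height_of[a], 0.0)
        lb = max(h - height_of[b], 0.0)
        node = n + i
        node_str[node] = f"({node_str[a]}:{la:.6g},{node_str[b]}:{lb:.6g})"
        height_of[node] = h
    return node_str[2 * n - 2] + ";"
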