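"""Co-expression clustering of a gene panel.

Pearson correlation of log2(count+1) profiles across a dataset's samples,
complete-linkage agglomerative clustering on the distance 1 - r, and
extraction of clusters by cutting the tree at height 1 - r_threshold.
Complete linkage is the natural choice for a "co-expression value > 0.7"
cluster criterion: cutting its tree strictly below 1 - 0.7 guarantees
every within-cluster pair correlates above 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import CountMatrix

__all__ = [
    "CoexpressionResult",
    "pearson_matrix",
    "hcluster_complete",
    "extract_clusters",
    "linkage_to_newick",
    "coexpression_analysis",
]


@dataclass
class CoexpressionResult:
    """Correlation matrix, dendrogram and threshold clusters of a panel."""

    genes: list[str]
    corr: pd.DataFrame
    linkage: np.ndarray
    clusters: list[set[str]]
    threshold: float
    dropped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "threshold": self.threshold,
            "clusters": [sorted(c) for c in self.clusters],
            "cluster_sizes": [len(c) for c in self.clusters],
            "dropped_zero_variance": self.dropped,
        }


def pearson_matrix(
    cm: CountMatrix,
    genes: list[str] | None = None,
    condition: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of log2(count+1) gene profiles.

    Samples are the features: each gene is a vector over the selected
    samples (those labelled ``condition``, or all samples when None or
    the matrix carries no labels for it).  Zero-variance genes cannot be
    correlated and are excluded; their names are returned alongside.

    Returns
    -------
    (corr, dropped)
        Symmetric correlation DataFrame with unit diagonal, and the list
        of excluded zero-variance genes.
    """
    if genes is None:
        genes = cm.gene_ids
    missing = [g for g in genes if g not in cm.counts.index]
    if missing:
        raise KeyError(f"genes not in the count matrix: {missing[:5]}")
    samples = cm.samples_of(condition) if condition else cm.sample_ids
    if condition and not samples:
        samples = cm.sample_ids
    if len(samples) < 3:
        raise ValueError(f"need >=3 samples to correlate, got {len(samples)}")
    x = np.log2(cm.counts.loc[genes, samples].to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1)
    dropped = [g for g, s in zip(genes, sd) if s == 0.0]
    keep = [g for g in genes if g not in set(dropped)]
    if len(keep) < 2:
        raise ValueError("fewer than two genes with nonzero variance")
    x = x[[genes.index(g) for g in keep]]
    corr = np.corrcoef(x)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=keep, columns=keep), dropped


def hcluster_complete(corr: pd.DataFrame) -> np.ndarray:
    """Complete-linkage dendrogram on the dissimilarity d = 1 - r.

    Returns a standard (n-1) x 4 linkage matrix.  Merge order on exactly
    tied heights follows the deterministic nearest-neighbor-chain order
    of the underlying routine.
    """
    n = corr.shape[0]
    if n < 2:
        raise ValueError("need at least two genes to cluster")
    d = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(np.maximum(d, 0.0), checks=False)
    return hierarchy.linkage(condensed, method="complete")


def extract_clusters(
    linkage: np.ndarray,
    corr: pd.DataFrame,
    r_threshold: float = 0.7,
    min_size: int = 2,
) -> list[set[str]]:
    """Clusters in which every gene pair correlates strictly above r_threshold.

    The complete-linkage tree is cut just below height 1 - r_threshold, so
    the maximum within-cluster distance — and hence the minimum pairwise
    correlation — is bounded by construction.  Clusters below ``min_size``
    are dropped; the rest are ordered by size descending, then by first
    gene name.
    """
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must lie in (0, 1)")
    cut = np.nextafter(1.0 - r_threshold, 0.0)  # strict: max distance < 1 - r
    labels = hierarchy.fcluster(linkage, t=cut, criterion="distance")
    genes = list(corr.index)
    groups: dict[int, set[str]] = {}
    for gene, lab in zip(genes, labels):
        groups.setdefault(int(lab), set()).add(gene)
    clusters = [c for c in groups.values() if len(c) >= min_size]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    for cluster in clusters:  # complete-linkage guarantee, asserted
        if len(cluster) < 2:
            continue
        idx = sorted(cluster)
        sub = corr.loc[idx, idx].to_numpy()
        if sub[np.triu_indices(len(idx), k=1)].min() <= r_threshold:
            raise AssertionError("within-cluster correlation fell below the threshold")
    return clusters


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def coexpression_analysis(
    cm: CountMatrix,
    genes: list[str] | None = None,
    r_threshold: float = 0.7,
    min_size: int = 2,
    condition: str | None = "case",
) -> CoexpressionResult:
    """Panel correlation, dendrogram and threshold clusters in one call.

    By default only case samples are used (co-expression of the disease
    state); pass ``condition=None`` to pool all samples.
    """
    corr, dropped = pearson_matrix(cm, genes, condition=condition)
    linkage = hcluster_complete(corr)
    clusters = extract_clusters(linkage, corr, r_threshold, min_size)
    return CoexpressionResult(
        genes=list(corr.index),
        corr=corr,
        linkage=linkage,
        clusters=clusters,
        threshold=r_threshold,
        dropped=dropped,
    )
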