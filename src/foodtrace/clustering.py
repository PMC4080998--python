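"""Similarity structure of product sales distributions.

Products whose sales distributions have high pairwise Spearman rank
correlation are hard to tell apart from case-report patterns alone.
This module computes the pairwise correlation matrix, clusters products
by complete linkage on the dissimilarity 1 - rho, and relates cluster
size to identification success.  Complete linkage gives the operational
guarantee used throughout: cutting the tree at height h bounds every
within-cluster dissimilarity by h, so a cut at 0.25 yields clusters in
which all pairwise correlations are at least 0.75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from foodtrace.evaluation import ExperimentResult, success_rate
from foodtrace.sales import SalesMatrix


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho between product sales rows.

    Symmetric, diagonal exactly 1.
    """

    product_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if np.abs(self.rho - self.rho.T).max() > 1e-12:
            raise ValueError("correlation matrix must be symmetric")
        self._index = {p: i for i, p in enumerate(self.product_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.product_ids, columns=self.product_ids)


def pairwise_spearman(sales: SalesMatrix) -> CorrelationMatrix:
    """Spearman correlation of every pair of product sales rows.

    Average ranks for ties (the many shared structural zeros make ties
    ubiquitous).  Constant rows have undefined correlation and are
    scored 0 against everything, with a warning.
    """
    if sales.n_products < 2:
        raise ValueError("need at least two products")
    ranks = stats.rankdata(sales.values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    constant = norms == 0
    if constant.any():
        warnings.warn(
            "constant sales vector(s), correlation set to 0: "
            f"{[sales.product_ids[i] for i in np.flatnonzero(constant)]}",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, norms)
    rho = (centered @ centered.T) / np.outer(safe, safe)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(list(sales.product_ids), rho)


@dataclass
class ClusterTree:
    """Agglomeration history of complete-linkage clustering.

    ``linkage`` is the standard (n-1) x 4 merge table: the two merged
    node ids, the merge height, and the size of the new cluster.  Merge
    heights are non-decreasing (complete linkage is monotone).
    """

    leaf_ids: list[str]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(len(self.linkage)),
            "left": self.linkage[:, 0].astype(int),
            "right": self.linkage[:, 1].astype(int),
            "height": self.linkage[:, 2],
        })


def complete_linkage(corr: CorrelationMatrix) -> ClusterTree:
    """Cluster products by complete linkage on D = 1 - rho."""
    d = 1.0 - corr.rho
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return ClusterTree(list(corr.product_ids), z)


def cut_tree(tree: ClusterTree, height: float) -> list[list[str]]:
    """Partition products by cutting the dendrogram at ``height``.

    Clusters are the maximal groups fully merged at or below the cut, so
    every within-cluster dissimilarity is <= height.  Returned in order
    of each cluster's first leaf; members keep leaf order.
    """
    if height < 0:
        raise ValueError(f"height must be >= 0, got {height}")
    labels = hierarchy.fcluster(tree.linkage, t=height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for leaf, lab in zip(tree.leaf_ids, labels):
        clusters.setdefault(lab, []).append(leaf)
    return sorted(clusters.values(), key=lambda c: tree.leaf_ids.index(c[0]))


def max_pairwise_rho(corr: CorrelationMatrix, product: str) -> float:
    """Largest correlation of ``product`` with any other product."""
    try:
        i = corr._index[product]
    except KeyError:
        raise KeyError(f"unknown product id: {product!r}") from None
    row = np.delete(corr.rho[i], i)
    return float(row.max())


@dataclass
class ClusterSuccessFit:
    """Per-cluster mean success rate regressed on log cluster size.

    ``slope`` is None when the regression is degenerate (fewer than two
    distinct cluster sizes).  A negative slope means products in larger
    clusters of near-identical distributions are harder to identify.
    """

    sizes: np.ndarray
    mean_success: np.ndarray
    slope: float | None
    intercept: float | None
    m_cases: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cluster_size": self.sizes,
                             "mean_success_rate": self.mean_success})


def cluster_size_success_relation(result: ExperimentResult,
                                  partition: list[list[str]],
                                  m: int) -> ClusterSuccessFit:
    """Relate identification success to the size of a product's cluster.

    For each cluster, averages statistic A over its member products at
    ``m`` cases, then fits least squares of cluster mean success against
    the natural log of cluster size.
    """
    sizes, means = [], []
    for cluster in partition:
        rates = [success_rate(result, x, m) for x in cluster]
        sizes.append(len(cluster))
        means.append(float(np.mean(rates)))
    sizes_arr = np.asarray(sizes)
    means_arr = np.asarray(means)
    if len(set(sizes)) < 2:
        return ClusterSuccessFit(sizes_arr, means_arr, None, None, m)
    slope, intercept = np.polyfit(np.log(sizes_arr), means_arr, 1)
    return ClusterSuccessFit(sizes_arr, means_arr, float(slope), float(intercept), m)
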