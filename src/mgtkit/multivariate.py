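"""Expression-matrix multivariate views: z-scores, hierarchical clustering
with Kendall-correlation distance, PCA, and Spearman correlation panels.

The clustering dissimilarity is 1 - Kendall tau-b between column profiles
(tau-b is the tie-corrected variant), agglomerated with average linkage.
PCA follows the common heat-map workflow: rows (genes) are z-scored first,
then samples are projected by SVD of the row-standardised matrix, so the
variance fractions describe between-sample structure of standardised genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardise each row to mean 0, sample sd 1 (ddof=1).

    Constant rows carry no ranking information and are dropped with a
    warning; an all-constant matrix is an error.
    """
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise ValueError("every row is constant; nothing to standardise")
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant row(s) before z-scoring", stacklevel=2)
        matrix = matrix.loc[~constant]
        sd = sd.loc[~constant]
    return matrix.sub(matrix.mean(axis=1), axis=0).div(sd, axis=0)


def kendall_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Kendall tau-b between columns; symmetric, zero diagonal."""
    cols = list(matrix.columns)
    for c in cols:
        if matrix[c].nunique() < 2:
            raise ValueError(f"column {c!r} has fewer than 2 distinct values; tau undefined")
    n = len(cols)
    d = np.zeros((n, n))
    x = matrix.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            tau = stats.kendalltau(x[:, i], x[:, j]).statistic
            d[i, j] = d[j, i] = 1.0 - tau
    return pd.DataFrame(d, index=cols, columns=cols)


@dataclass
class ClusterTree:
    """An agglomerative dendrogram: scipy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray
    labels: list[str]
    metric: str = "kendall-distance"
    linkage: str = "average"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        """Flat clusters at k groups; labels -> 1-based cluster id."""
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def hcluster(matrix: pd.DataFrame, axis: str = "columns") -> ClusterTree:
    """Average-linkage clustering with Kendall tau-b distance.

    ``axis="columns"`` clusters samples (the usual case); ``"rows"``
    clusters genes. Deterministic given input order: scipy's
    agglomeration picks the lowest-index minimal pair on ties.
    """
    data = matrix if axis == "columns" else matrix.T
    if data.shape[1] < 2:
        raise ValueError("need at least 2 profiles to cluster")
    dmat = kendall_distance_matrix(data)
    condensed = squareform(dmat.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    return ClusterTree(linkage_matrix=Z, labels=list(data.columns))


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_explained: np.ndarray  # fractions, non-increasing, sum 1

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(self.variance_explained))],
             "variance_fraction": self.variance_explained}
        )


def pca(matrix: pd.DataFrame, zscore: bool = True) -> PCAResult:
    """Principal components of samples from a genes x samples matrix.

    Rows are z-scored first (unless already standardised), after which
    every row has mean 0 across samples, so the SVD of the transposed
    matrix is a PCA of samples. Variance fractions are the normalised
    squared singular values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = zscore_rows(matrix) if zscore else matrix
    D = X.to_numpy(dtype=float).T  # samples x genes, columns mean-0
    U, s, _ = np.linalg.svd(D, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has no variance")
    scores = U * s
    k = scores.shape[1]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.columns, columns=[f"PC{i+1}" for i in range(k)]),
        variance_explained=var / total,
    )


def spearman_pairs(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Spearman correlations between columns (mid-rank ties).

    ``profiles`` is genes x groups (e.g. per-subtype log2 FPKM over a
    shared gene set). Returns (correlation matrix, long-form scatter
    table of ranked values).
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 shared genes for rank correlation")
    rho = profiles.corr(method="spearman")
    ranks = profiles.rank()
    scatter = ranks.reset_index().melt(id_vars=ranks.index.name or "index",
                                       var_name="group", value_name="rank")
    return rho, scatter
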