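"""Gene clustering from multi-omics data via canonical correlation.

Because every gene carries ``n0`` omics columns, gene-gene association is
measured by the first canonical correlation between the two n x n0 blocks.
The G x G association matrix is then turned into a weighted-network
adjacency by soft-thresholding (``a ** power``, WGCNA convention), converted
to a dissimilarity ``1 - adjacency`` and cut with average-linkage
hierarchical clustering.  By default the tree is cut at the largest gap in
the merge heights; the number of clusters can be forced instead.

The screening pipeline also accepts externally supplied labels, so this
module is optional when a dedicated multi-omics clustering tool has already
been run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .structure import HierarchicalStructure

__all__ = [
    "GeneAssociationMatrix",
    "ClusteringResult",
    "canonical_correlation",
    "gene_association_matrix",
    "cluster_genes",
    "adjusted_rand_index",
]

#: ridge added to within-block covariances before whitening
CCA_RIDGE = 1e-8


@dataclass(frozen=True)
class GeneAssociationMatrix:
    """Symmetric G x G matrix of first canonical correlations."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("association matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def G(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    n_clusters: int
    params: dict = field(default_factory=dict)


def _whiten(block: np.ndarray, ridge: float) -> np.ndarray:
    """Column-centre and whiten an n x n0 block: output has identity
    within-block covariance (up to the ridge)."""
    B = np.asarray(block, dtype=float)
    B = B - B.mean(axis=0)
    n = B.shape[0]
    var = (B * B).sum(axis=0) / max(n - 1, 1)
    if np.any(var <= 1e-14):
        warnings.warn("degenerate (zero-variance) omics column in block",
                      RuntimeWarning, stacklevel=3)
    S = B.T @ B / max(n - 1, 1)
    S[np.diag_indices_from(S)] += ridge
    w, V = np.linalg.eigh(S)
    w = np.clip(w, ridge, None)
    return B @ (V / np.sqrt(w)) @ V.T / np.sqrt(max(n - 1, 1))


def canonical_correlation(block_i: np.ndarray, block_j: np.ndarray,
                          ridge: float = CCA_RIDGE) -> float:
    """First canonical correlation between two n x n0 blocks, in [0, 1].

    Equals the square root of the largest eigenvalue of
    ``S11^-1 S12 S22^-1 S21``; computed as the largest singular value of the
    cross-product of the whitened blocks.  A small ridge on the within-block
    covariances guards collinear omics.
    """
    Qi = _whiten(block_i, ridge)
    Qj = _whiten(block_j, ridge)
    s = np.linalg.svd(Qi.T @ Qj, compute_uv=False)
    return float(min(s[0], 1.0))


def gene_association_matrix(X: np.ndarray,
                            structure: HierarchicalStructure,
                            ridge: float = CCA_RIDGE) -> GeneAssociationMatrix:
    """All pairwise gene canonical correlations, computed in one batch.

    Each gene block is whitened once; the first canonical correlation of a
    pair is then the largest singular value of the n0 x n0 cross-product of
    the whitened blocks, evaluated for all pairs with a batched
    eigendecomposition.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    G, n0 = structure.G, structure.n0
    if n <= n0:
        raise ValueError("need n > n0 samples for canonical correlation")
    Q = np.empty((G, n, n0))
    for g in range(G):
        Q[g] = _whiten(X[:, structure.columns_of_gene[g]], ridge)
    # cross-products for all pairs: M[g, h] = Q_g' Q_h  (G, G, n0, n0)
    M = np.einsum("gni,hnj->ghij", Q, Q, optimize=True)
    # largest singular value via eigvalsh of M M'
    MMt = M @ np.swapaxes(M, -1, -2)
    s2 = np.linalg.eigvalsh(MMt)[..., -1]
    vals = np.sqrt(np.clip(s2, 0.0, 1.0))
    np.fill_diagonal(vals, 1.0)
    vals = 0.5 * (vals + vals.T)
    return GeneAssociationMatrix(vals)


def cluster_genes(assoc: GeneAssociationMatrix | np.ndarray,
                  power: float = 6.0,
                  n_clusters: int | None = None,
                  linkage_method: str = "average") -> ClusteringResult:
    """Partition genes from their association matrix.

    The association is soft-thresholded (``a ** power``), converted to the
    dissimilarity ``1 - a**power`` and clustered by hierarchical
    agglomeration.  Without a forced ``n_clusters`` the tree is cut at the
    largest gap between consecutive merge heights, which separates the
    tight within-cluster merges from the near-unit cross-cluster ones.
    Deterministic given its inputs.
    """
    A = assoc.values if isinstance(assoc, GeneAssociationMatrix) else np.asarray(assoc, float)
    G = A.shape[0]
    params = {"power": power, "n_clusters": n_clusters, "linkage": linkage_method}
    if G == 1:
        return ClusteringResult(np.zeros(1, dtype=np.intp), 1, params)
    D = 1.0 - np.clip(A, 0.0, 1.0) ** power
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    if n_clusters is not None:
        raw = fcluster(Z, t=int(n_clusters), criterion="maxclust")
    else:
        heights = Z[:, 2]
        gaps = np.diff(heights)
        if gaps.size == 0 or gaps.max() <= 1e-12:
            raw = np.ones(G, dtype=int)
        else:
            i = int(np.argmax(gaps))
            thresh = 0.5 * (heights[i] + heights[i + 1])
            raw = fcluster(Z, t=thresh, criterion="distance")
    # relabel 0..K-1 in order of first appearance (deterministic)
    _, labels = np.unique(raw, return_inverse=True)
    order = {}
    out = np.empty(G, dtype=np.intp)
    for g in range(G):
        out[g] = order.setdefault(labels[g], len(order))
    return ClusteringResult(out, int(out.max() + 1), params)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 iff the partitions are identical (up to label renaming); expected
    value 0 for random partitions.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
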