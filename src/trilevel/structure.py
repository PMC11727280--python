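"""Tri-level index structure for multi-omics covariates.

A covariate matrix with ``p`` columns is organised on three levels:

* **cluster** -- a group of correlated genes,
* **gene** -- a subgroup holding the ``n0`` omics measurements of one gene,
* **omics** -- an individual column.

:class:`HierarchicalStructure` stores the gene -> cluster assignment and the
gene -> column map.  In the *canonical* layout the columns of gene ``g`` are
the consecutive block ``[g*n0, (g+1)*n0)`` and clusters are contiguous runs
of genes; the offsets ``alpha`` / ``kappa`` refer to that layout.  Screening
only uses the explicit maps, so cluster labels may be permuted freely (the
imperfect-clustering setting) without moving any columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Gene-cluster sizes used by the canonical simulation configurations.
CANONICAL_CLUSTER_SIZES = (5, 10, 20, 40)

#: Cluster-count configuration (counts of clusters of size 5/10/20/40)
#: for each simulated sample size.
TABLE_DIMS: dict[int, tuple[int, int, int, int]] = {
    200: (10, 5, 4, 3),
    400: (20, 10, 6, 6),
    800: (40, 20, 10, 10),
}


@dataclass(frozen=True)
class HierarchicalStructure:
    """Immutable cluster/gene/omics index map.

    Parameters
    ----------
    n0:
        Number of omics measurements per gene.
    cluster_of_gene:
        Integer array of shape ``(G,)`` mapping each gene to its cluster.
    columns_of_gene:
        Integer array of shape ``(G, n0)``; row ``g`` lists the covariate
        columns of gene ``g``.
    n_clusters:
        Total number of cluster labels ``C`` (some may be empty after a
        label permutation).
    """

    n0: int
    cluster_of_gene: np.ndarray
    columns_of_gene: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        cg = np.asarray(self.cluster_of_gene, dtype=np.intp)
        cols = np.asarray(self.columns_of_gene, dtype=np.intp)
        object.__setattr__(self, "cluster_of_gene", cg)
        object.__setattr__(self, "columns_of_gene", cols)
        if cols.ndim != 2 or cols.shape[1] != self.n0:
            raise ValueError("columns_of_gene must have shape (G, n0)")
        if cg.shape != (cols.shape[0],):
            raise ValueError("cluster_of_gene must have one entry per gene")
        flat = np.sort(cols.ravel())
        if not np.array_equal(flat, np.arange(flat.size)):
            raise ValueError("gene columns must partition 0..p-1")
        if cg.size and (cg.min() < 0 or cg.max() >= self.n_clusters):
            raise ValueError("cluster labels out of range")

    # ------------------------------------------------------------------ sizes
    @property
    def G(self) -> int:
        """Number of genes."""
        return self.columns_of_gene.shape[0]

    @property
    def p(self) -> int:
        """Number of covariate columns."""
        return self.columns_of_gene.size

    @property
    def C(self) -> int:
        """Number of cluster labels."""
        return self.n_clusters

    @property
    def Hc(self) -> np.ndarray:
        """Genes per cluster, shape ``(C,)``."""
        return np.bincount(self.cluster_of_gene, minlength=self.n_clusters)

    @property
    def cluster_sizes(self) -> np.ndarray:  # alias used by callers
        return self.Hc

    def genes_of_cluster(self, c: int) -> np.ndarray:
        """Gene indices of cluster ``c`` in ascending order."""
        return np.flatnonzero(self.cluster_of_gene == c)

    @property
    def alpha(self) -> np.ndarray:
        """Cumulative covariate offsets ``alpha_c`` (canonical layout)."""
        return np.concatenate(([0], np.cumsum(self.n0 * self.Hc)))[: self.n_clusters]

    def kappa(self, c: int, h: int) -> int:
        """Column offset of gene ``h`` (0-based) of cluster ``c`` (canonical)."""
        return int(self.alpha[c] + self.n0 * h)

    # ------------------------------------------------------------- derivation
    def with_cluster_labels(self, labels: Sequence[int] | np.ndarray,
                            n_clusters: int | None = None) -> "HierarchicalStructure":
        """Return a copy with a different gene -> cluster assignment.

        Columns stay attached to their genes, so this models re-clustering
        (perfect or imperfect) of a fixed covariate layout.
        """
        labels = np.asarray(labels, dtype=np.intp)
        if labels.shape != (self.G,):
            raise ValueError("labels must have one entry per gene")
        C = int(n_clusters if n_clusters is not None else max(self.n_clusters, labels.max() + 1))
        return HierarchicalStructure(
            n0=self.n0,
            cluster_of_gene=labels,
            columns_of_gene=self.columns_of_gene,
            n_clusters=C,
        )

    def gene_of_column(self) -> np.ndarray:
        """Inverse map: column index -> gene index, shape ``(p,)``."""
        inv = np.empty(self.p, dtype=np.intp)
        for g in range(self.G):
            inv[self.columns_of_gene[g]] = g
        return inv


def from_cluster_sizes(sizes: Sequence[int], n0: int) -> HierarchicalStructure:
    """Canonical structure from an explicit list of per-cluster gene counts."""
    sizes = [int(s) for s in sizes]
    if any(s <= 0 for s in sizes) or n0 <= 0:
        raise ValueError("cluster sizes and n0 must be positive")
    G = sum(sizes)
    cluster_of_gene = np.repeat(np.arange(len(sizes)), sizes)
    columns_of_gene = np.arange(G * n0).reshape(G, n0)
    return HierarchicalStructure(
        n0=n0,
        cluster_of_gene=cluster_of_gene,
        columns_of_gene=columns_of_gene,
        n_clusters=len(sizes),
    )


def build_structure(dims, n0: int = 3) -> HierarchicalStructure:
    """Build the canonical structure from a cluster-count configuration.

    Parameters
    ----------
    dims:
        Either a mapping ``{cluster size: number of clusters}`` or a
        sequence of four counts for clusters of size 5, 10, 20 and 40
        (the canonical simulation configurations, see :data:`TABLE_DIMS`).
    n0:
        Omics per gene.
    """
    if isinstance(dims, Mapping):
        pairs = [(int(s), int(c)) for s, c in sorted(dims.items())]
    else:
        counts = list(dims)
        if len(counts) != len(CANONICAL_CLUSTER_SIZES):
            raise ValueError(
                "dims must be a mapping or a sequence of "
                f"{len(CANONICAL_CLUSTER_SIZES)} counts for sizes "
                f"{CANONICAL_CLUSTER_SIZES}"
            )
        pairs = list(zip(CANONICAL_CLUSTER_SIZES, (int(c) for c in counts)))
    if any(c < 0 or s <= 0 for s, c in pairs):
        raise ValueError("cluster sizes must be positive, counts nonnegative")
    sizes: list[int] = []
    for s, c in pairs:
        sizes.extend([s] * c)
    if not sizes:
        raise ValueError("at least one cluster is required")
    return from_cluster_sizes(sizes, n0)
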