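"""Shared fixtures: small structures and random logistic instances."""

from __future__ import annotations

import numpy as np
import pytest

from trilevel.glm import GLMModel
from trilevel.structure import HierarchicalStructure, from_cluster_sizes


@pytest.fixture
def tiny_structure() -> HierarchicalStructure:
    """Two clusters of 2 and 3 genes, two omics each (p=10)."""
    return from_cluster_sizes([2, 3], n0=2)


def make_logistic_instance(seed: int, n: int = 60,
                           sizes=(2, 3, 2), n0: int = 2,
                           rho: float = 0.4, signal: float = 1.0):
    """Random correlated logistic instance with a sparse truth.

    Returns ``(model, structure, true_gene_indices)``.
    """
    rng = np.random.default_rng(seed)
    st = from_cluster_sizes(sizes, n0)
    p = st.p
    shared = rng.standard_normal((n, 1))
    X = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, p))
    beta = np.zeros(p)
    true_genes = [0, st.G - 1]
    for g in true_genes:
        beta[st.columns_of_gene[g]] = signal * rng.choice([-1.0, 1.0], size=n0)
    eta = X @ beta
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    if y.min() == y.max():            # degenerate draw; nudge one outcome
        y[0] = 1 - y[0]
    return GLMModel(X, y.astype(float)), st, true_genes


@pytest.fixture
def logistic_instance():
    return make_logistic_instance(seed=11)
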