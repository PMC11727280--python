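"""Joint screening with a block-diagonal weight matrix (JSBD) and rivals.

The screening problem maximises the GLM log-likelihood subject to two
cardinality constraints: at most ``q1`` clusters and at most ``q2c`` genes
inside cluster ``c``.  Because ``p >> n`` the likelihood is replaced by the
quadratic surrogate

    g(w | b) = l(b) + (w - b)' l'(b) - (u/2) (w - b)' W(b) (w - b),

whose weight ``W(b)`` is block diagonal with one ``n0 x n0`` block per gene:
the corresponding sub-block of ``-l''(b)``, scaled by ``q2c * n0`` within
cluster ``c``.  Block diagonality gives the unconstrained maximiser in
closed form, ``w_hat = b + (1/u) W(b)^-1 l'(b)``, and makes the constrained
maximiser a simple double ranking: keep the top ``q2c`` genes per cluster
by the quadratic score ``r_ch = w_hat' W_ch w_hat``, zero the rest, then
keep the top ``q1`` clusters by ``R_c = w_hat' W_c w_hat``.  The retained
coordinates are refitted by maximum likelihood and the loop repeats from
``b(0) = 0`` until the relative change in ``b`` falls below ``tol``.

For ``u`` at least the largest generalised eigenvalue ``tau(k)`` of
``-l''`` against ``W``, each sweep cannot decrease the log-likelihood
(ascent property).  The default ``u = 1e5`` is far above the ``tau``
observed in practice.

Variants: JSD uses only the diagonal of each gene block (ignoring
within-gene correlation); OMS and GMS are marginal p-value screeners at the
omics and gene level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.special import expit

from .glm import (
    ETA_BOUND,
    GLMModel,
    LogisticFit,
    fit_logistic,
    genewise_logistic_tests,
    univariate_logistic_tests,
    _loglik_eta,
)
from .structure import HierarchicalStructure

__all__ = [
    "ScreeningConfig",
    "BlockWeightMatrix",
    "ScreeningResult",
    "MarginalScreeningResult",
    "build_block_W",
    "surrogate_argmax",
    "gene_scores",
    "cluster_scores",
    "constrained_select",
    "refit",
    "jsbd_screen",
    "jsd_screen",
    "oms_screen",
    "gms_screen",
    "retention_metrics",
    "genes_from_omics",
    "compute_tau_bound",
]


def q2_from_rule(structure: HierarchicalStructure, rate: float = 0.10) -> np.ndarray:
    """Per-cluster gene cap ``q2c = max(1, ceil(rate * Hc))`` (0 for empty
    clusters)."""
    Hc = structure.Hc
    q2 = np.maximum(1, np.ceil(rate * Hc).astype(int))
    q2[Hc == 0] = 0
    return np.minimum(q2, Hc)


@dataclass
class ScreeningConfig:
    """Tuning constants of the joint screening algorithm.

    ``q2`` may be an explicit per-cluster vector, a scalar applied to every
    cluster, or None for the 10%-of-cluster-size rule.  ``scale_blocks``
    controls the ``q2c * n0`` factor on the cluster blocks ``W_c``; it is on
    by default and exposed only for sensitivity checks.
    """

    q1: int
    q2: np.ndarray | int | None = None
    q2_rate: float = 0.10
    u: float = 1e5
    tol: float = 1e-6
    max_iter: int = 100
    scale_blocks: bool = True
    track_tau: bool = False
    ridge_cond: float = 1e12

    def resolve_q2(self, structure: HierarchicalStructure) -> np.ndarray:
        Hc = structure.Hc
        if self.q2 is None:
            q2 = q2_from_rule(structure, self.q2_rate)
        elif np.isscalar(self.q2):
            q2 = np.minimum(int(self.q2), Hc)
        else:
            q2 = np.asarray(self.q2, dtype=int)
            if q2.shape != (structure.C,):
                raise ValueError("q2 must have one entry per cluster")
            if np.any((q2 < 1) & (Hc > 0)) or np.any(q2 > Hc):
                raise ValueError("need 1 <= q2c <= Hc for nonempty clusters")
        if not 1 <= self.q1 <= structure.C:
            raise ValueError("need 1 <= q1 <= C")
        if self.u <= 0:
            raise ValueError("u must be positive")
        return q2


@dataclass
class BlockWeightMatrix:
    """Per-gene ``n0 x n0`` blocks of ``W(beta)`` plus their cluster scales.

    ``blocks[g]`` is the (ridge-stabilised) sub-block of ``-l''(beta)`` for
    gene ``g``; the matrix actually used in the surrogate is
    ``scale[g] * blocks[g]`` with ``scale[g] = q2c * n0`` of the gene's
    cluster (or 1 when scaling is disabled).
    """

    blocks: np.ndarray          # (G, n0, n0)
    scale: np.ndarray           # (G,)
    cluster_of_gene: np.ndarray
    beta_point: np.ndarray | None = None

    @property
    def G(self) -> int:
        return self.blocks.shape[0]

    def solve(self, vectors: np.ndarray) -> np.ndarray:
        """Blockwise solve ``blocks[g] x_g = vectors[g]`` (unscaled)."""
        return np.linalg.solve(self.blocks, vectors[..., None])[..., 0]

    def dense(self, structure: HierarchicalStructure) -> np.ndarray:
        """Assemble the scaled p x p block-diagonal matrix (small-p oracle)."""
        p = structure.p
        W = np.zeros((p, p))
        for g in range(self.G):
            cols = structure.columns_of_gene[g]
            W[np.ix_(cols, cols)] = self.scale[g] * self.blocks[g]
        return W


def _stabilise_blocks(blocks: np.ndarray, ridge_cond: float) -> np.ndarray:
    """Add a trace-scaled ridge to blocks whose condition number exceeds
    ``ridge_cond`` (degenerate omics must not crash the solve)."""
    n0 = blocks.shape[-1]
    if n0 == 1:
        flat = blocks[:, 0, 0]
        bad = flat <= 1e-300
        if bad.any():
            blocks = blocks.copy()
            blocks[bad, 0, 0] = 1e-12
        return blocks
    w = np.linalg.eigvalsh(blocks)
    cond = w[:, -1] / np.maximum(w[:, 0], 1e-300)
    bad = (cond > ridge_cond) | (w[:, 0] <= 0)
    if bad.any():
        blocks = blocks.copy()
        tr = np.trace(blocks[bad], axis1=1, axis2=2)
        eye = np.eye(n0)
        blocks[bad] += (1e-8 * np.maximum(tr, 1e-4) / n0)[:, None, None] * eye
    return blocks


def _gene_design(model: GLMModel, structure: HierarchicalStructure) -> np.ndarray:
    """Covariates rearranged as (n, G, n0), gene-major."""
    n = model.n
    return model.X[:, structure.columns_of_gene.reshape(-1)].reshape(
        n, structure.G, structure.n0
    )


def build_block_W(model: GLMModel, beta: np.ndarray,
                  structure: HierarchicalStructure, config: ScreeningConfig,
                  beta0: float = 0.0, *, diagonal: bool = False) -> BlockWeightMatrix:
    """Evaluate the per-gene blocks of ``W(beta)``.

    Each block is ``Xg' diag(mu(1-mu)) Xg`` (the negative Hessian restricted
    to the gene's columns); only ``G`` small blocks are materialised.  With
    ``diagonal=True`` the off-diagonal entries are dropped (JSD).
    """
    Xr = _gene_design(model, structure)
    eta = beta0 + model.X @ np.asarray(beta, dtype=float)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    return _block_W_from_parts(Xr, w, structure, config, diagonal=diagonal,
                               beta_point=np.asarray(beta, dtype=float))


def _block_W_from_parts(Xr: np.ndarray, w: np.ndarray,
                        structure: HierarchicalStructure,
                        config: ScreeningConfig, *, diagonal: bool,
                        beta_point: np.ndarray | None = None) -> BlockWeightMatrix:
    n0 = structure.n0
    if diagonal:
        diag = np.einsum("ngi,n->gi", Xr * Xr, w, optimize=True)
        blocks = np.zeros((structure.G, n0, n0))
        idx = np.arange(n0)
        blocks[:, idx, idx] = diag
    else:
        blocks = np.einsum("ngi,n,ngj->gij", Xr, w, Xr, optimize=True)
    blocks = _stabilise_blocks(blocks, config.ridge_cond)
    q2 = config.resolve_q2(structure)
    if config.scale_blocks:
        scale = (q2 * n0).astype(float)[structure.cluster_of_gene]
    else:
        scale = np.ones(structure.G)
    return BlockWeightMatrix(blocks, scale, structure.cluster_of_gene, beta_point)


def surrogate_argmax(beta_genes: np.ndarray, grad_genes: np.ndarray,
                     W: BlockWeightMatrix, u: float) -> np.ndarray:
    """Unconstrained maximiser of the surrogate, blockwise:
    ``w_hat_g = beta_g + (1 / (u * scale_g)) * blocks_g^-1 grad_g``.

    Inputs and output are gene-major ``(G, n0)`` arrays.
    """
    step = W.solve(grad_genes) / (u * W.scale)[:, None]
    return beta_genes + step


def gene_scores(omega: np.ndarray, W: BlockWeightMatrix) -> np.ndarray:
    """Quadratic importance ``r_ch = w' W_ch w`` per gene (unscaled block;
    the cluster constant cannot change within-cluster ranking)."""
    return np.einsum("gi,gij,gj->g", omega, W.blocks, omega, optimize=True)


def cluster_scores(omega: np.ndarray, W: BlockWeightMatrix,
                   structure: HierarchicalStructure) -> np.ndarray:
    """Quadratic importance ``R_c = w' W_c w`` per cluster, using the
    scaled cluster blocks."""
    per_gene = W.scale * gene_scores(omega, W)
    return np.bincount(W.cluster_of_gene, weights=per_gene,
                       minlength=structure.C)


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, ties broken by ascending index."""
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def constrained_select(omega: np.ndarray, W: BlockWeightMatrix,
                       structure: HierarchicalStructure,
                       config: ScreeningConfig):
    """Apply both cardinality constraints to the surrogate maximiser.

    Within every cluster the top ``q2c`` genes by ``r_ch`` are kept and the
    remaining genes' entries of ``w_hat`` are zeroed; the cluster scores
    ``R_c`` are recomputed on the masked vector and the top ``q1`` clusters
    are kept.  Returns ``(selected gene indices, masked w_hat, r, R)``.
    """
    q2 = config.resolve_q2(structure)
    r = gene_scores(omega, W)
    keep_gene = np.zeros(structure.G, dtype=bool)
    for c in range(structure.C):
        genes = structure.genes_of_cluster(c)
        if genes.size == 0:
            continue
        top = _top_k(r[genes], int(q2[c]))
        keep_gene[genes[top]] = True
    masked = np.where(keep_gene[:, None], omega, 0.0)
    R = cluster_scores(masked, W, structure)
    nonempty = np.flatnonzero(structure.Hc > 0)
    top_clusters = nonempty[_top_k(R[nonempty], int(config.q1))]
    in_top = np.isin(W.cluster_of_gene, top_clusters)
    selected = np.flatnonzero(keep_gene & in_top)
    masked[~(keep_gene & in_top)] = 0.0
    return selected, masked, r, R


def refit(model: GLMModel, columns: np.ndarray, **kwargs) -> LogisticFit:
    """Maximum-likelihood refit on the retained columns (others fixed at
    zero, intercept unpenalised)."""
    cols = np.asarray(columns, dtype=np.intp)
    if cols.size >= model.n:
        raise ValueError("refit requires fewer retained columns than samples")
    return fit_logistic(model.X[:, cols], model.y, **kwargs)


def compute_tau_bound(model: GLMModel, W: BlockWeightMatrix,
                      structure: HierarchicalStructure) -> float:
    """Diagnostic upper bound on ``tau(k)``: the largest generalised
    eigenvalue of ``X'X / 4`` (the global envelope of ``-l''`` for the
    logistic family) against the scaled block-diagonal ``W``.  Dense; small
    instances only."""
    H = model.X.T @ model.X / 4.0
    Wd = W.dense(structure)
    vals = scipy.linalg.eigh(H, Wd, eigvals_only=True)
    return float(vals[-1])


@dataclass
class ScreeningResult:
    """Output of one joint-screening run."""

    method: str
    retained_clusters: np.ndarray
    retained_genes: dict[int, np.ndarray]
    support_genes: np.ndarray
    beta_hat: np.ndarray
    beta0: float
    gene_scores: np.ndarray
    cluster_scores: np.ndarray
    loglik_trace: np.ndarray
    iterations: int
    converged: bool
    tau_trace: np.ndarray | None = None

    @property
    def retained_gene_set(self) -> frozenset[int]:
        return frozenset(int(g) for g in self.support_genes)


def _joint_screen(model: GLMModel, structure: HierarchicalStructure,
                  config: ScreeningConfig, *, diagonal: bool,
                  method: str) -> ScreeningResult:
    n, p = model.n, model.p
    if structure.p != p:
        raise ValueError("structure does not match X")
    config.resolve_q2(structure)  # validate early
    G, n0 = structure.G, structure.n0
    Xr = _gene_design(model, structure)
    y = model.y

    beta_g = np.zeros((G, n0))
    beta0 = 0.0
    support = np.zeros(0, dtype=np.intp)
    loglik_trace: list[float] = []
    tau_trace: list[float] = []
    best = (-np.inf, None)
    converged = False
    it = 0
    last_r = np.zeros(G)
    last_R = np.zeros(structure.C)
    for it in range(1, config.max_iter + 1):
        # linear predictor from the sparse current iterate
        if support.size:
            eta = beta0 + np.einsum("ngi,gi->n", Xr[:, support, :], beta_g[support])
        else:
            eta = np.full(n, beta0)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = np.einsum("n,ngi->gi", y - mu, Xr, optimize=True)
        W = _block_W_from_parts(Xr, w, structure, config, diagonal=diagonal)
        omega = surrogate_argmax(beta_g, grad, W, config.u)
        selected, _, last_r, last_R = constrained_select(omega, W, structure, config)
        if config.track_tau:
            tau_trace.append(compute_tau_bound(model, W, structure))
        cols = structure.columns_of_gene[selected].reshape(-1)
        fit = refit(model, cols)
        new_beta = np.zeros((G, n0))
        new_beta[selected] = fit.beta.reshape(selected.size, n0)
        loglik_trace.append(fit.loglik)
        if fit.loglik > best[0]:
            best = (fit.loglik, (selected, new_beta, fit.beta0))
        denom = np.linalg.norm(beta_g)
        delta = np.linalg.norm(new_beta - beta_g)
        beta_g, beta0, support = new_beta, fit.beta0, selected
        if (delta / denom if denom > 1e-12 else delta) < config.tol:
            converged = True
            break
    if not converged and best[1] is not None:
        support, beta_g, beta0 = best[1][0], best[1][1], best[1][2]
    beta_hat = np.zeros(p)
    beta_hat[structure.columns_of_gene.reshape(-1)] = beta_g.reshape(-1)
    retained_genes = {
        int(c): np.intersect1d(support, structure.genes_of_cluster(c))
        for c in np.unique(structure.cluster_of_gene[support])
    }
    return ScreeningResult(
        method=method,
        retained_clusters=np.asarray(sorted(retained_genes), dtype=np.intp),
        retained_genes=retained_genes,
        support_genes=np.asarray(support, dtype=np.intp),
        beta_hat=beta_hat,
        beta0=beta0,
        gene_scores=last_r,
        cluster_scores=last_R,
        loglik_trace=np.asarray(loglik_trace),
        iterations=it,
        converged=converged,
        tau_trace=np.asarray(tau_trace) if config.track_tau else None,
    )


def jsbd_screen(model: GLMModel, structure: HierarchicalStructure,
                config: ScreeningConfig) -> ScreeningResult:
    """Joint screening with full ``n0 x n0`` gene blocks (JSBD)."""
    return _joint_screen(model, structure, config, diagonal=False, method="jsbd")


def jsd_screen(model: GLMModel, structure: HierarchicalStructure,
               config: ScreeningConfig) -> ScreeningResult:
    """Joint screening with the gene blocks reduced to their diagonals
    (JSD); coincides with JSBD when ``n0 = 1``."""
    return _joint_screen(model, structure, config, diagonal=True, method="jsd")


@dataclass
class MarginalScreeningResult:
    method: str
    retained: np.ndarray          # omics columns (OMS) or genes (GMS)
    pvalues: np.ndarray
    flagged: np.ndarray

    @property
    def retained_set(self) -> frozenset[int]:
        return frozenset(int(i) for i in self.retained)


def oms_screen(model: GLMModel, structure: HierarchicalStructure,
               k_omics: int) -> MarginalScreeningResult:
    """Omics-level marginal screening: rank single-covariate logistic
    Wald p-values, keep the ``k_omics`` smallest (ties by column index)."""
    if not 1 <= k_omics <= model.p:
        raise ValueError("k_omics out of range")
    pvals, flags = univariate_logistic_tests(model.X, model.y)
    order = np.lexsort((np.arange(model.p), pvals))
    return MarginalScreeningResult("oms", np.sort(order[:k_omics]), pvals, flags)


def gms_screen(model: GLMModel, structure: HierarchicalStructure,
               k_genes: int) -> MarginalScreeningResult:
    """Gene-level marginal screening: one logistic fit per gene on its
    ``n0`` omics, ranked by the likelihood-ratio omnibus p-value."""
    if not 1 <= k_genes <= structure.G:
        raise ValueError("k_genes out of range")
    pvals, flags = genewise_logistic_tests(model.X, model.y,
                                           structure.columns_of_gene)
    order = np.lexsort((np.arange(structure.G), pvals))
    return MarginalScreeningResult("gms", np.sort(order[:k_genes]), pvals, flags)


def genes_from_omics(omics_columns: np.ndarray,
                     structure: HierarchicalStructure,
                     rule: str = "any") -> frozenset[int]:
    """Genes represented in a set of retained omics columns.

    ``rule='any'`` (default) counts a gene as retained as soon as one of
    its omics is retained; ``rule='all'`` requires every omics.
    """
    gene_of_col = structure.gene_of_column()
    genes = gene_of_col[np.asarray(omics_columns, dtype=np.intp)]
    if rule == "any":
        return frozenset(int(g) for g in np.unique(genes))
    if rule == "all":
        counts = np.bincount(genes, minlength=structure.G)
        return frozenset(int(g) for g in np.flatnonzero(counts == structure.n0))
    raise ValueError("rule must be 'any' or 'all'")


def retention_metrics(retained_genes, true_nonzero_genes) -> tuple[int, float]:
    """Screening success measures against the generating truth.

    Returns ``(all_retained, proportion_retained)`` where the first is 1
    iff every true non-zero gene was kept and the second is the retained
    fraction of the truth.
    """
    retained = frozenset(int(g) for g in retained_genes)
    truth = frozenset(int(g) for g in true_nonzero_genes)
    if not truth:
        raise ValueError("true gene set is empty")
    hit = len(retained & truth)
    return int(hit == len(truth)), hit / len(truth)
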