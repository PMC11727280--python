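"""Logistic-model likelihood plumbing used by the screening algorithms.

Only the binomial family is implemented; the functions are written against
a small ``GLMModel`` container so that other exponential-family outcomes
could be slotted in behind the same surface.

All log-likelihoods are exact (no dispersion constant for the binomial
family); linear predictors are bounded at ``ETA_BOUND`` inside the fitting
routines to keep near-separated refits finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "GLMModel",
    "LogisticFit",
    "loglik",
    "gradient",
    "hessian_block",
    "fit_logistic",
    "univariate_logistic_tests",
    "genewise_logistic_tests",
]

#: |linear predictor| bound applied inside iterative fits (separation guard)
ETA_BOUND = 30.0


@dataclass
class GLMModel:
    """Design, outcome and family tag for one screening problem."""

    X: np.ndarray
    y: np.ndarray
    family: str = "logistic"
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.family != "logistic":
            raise NotImplementedError(f"family {self.family!r} not implemented")
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be n x p with one row per outcome")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite entries")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("logistic family requires a binary 0/1 outcome")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _loglik_eta(y: np.ndarray, eta: np.ndarray) -> float:
    # sum_i [ y_i eta_i - log(1 + exp(eta_i)) ], stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def loglik(model: GLMModel, beta: np.ndarray, beta0: float = 0.0) -> float:
    """Exact binomial log-likelihood at ``(beta0, beta)``."""
    eta = beta0 + model.X @ np.asarray(beta, dtype=float)
    return _loglik_eta(model.y, eta)


def gradient(model: GLMModel, beta: np.ndarray, beta0: float = 0.0) -> np.ndarray:
    """Score with respect to ``beta`` (the intercept is excluded):
    ``X' (y - mu)``."""
    eta = beta0 + model.X @ np.asarray(beta, dtype=float)
    return model.X.T @ (model.y - expit(eta))


def hessian_block(model: GLMModel, beta: np.ndarray, beta0: float,
                  columns: Sequence[int]) -> np.ndarray:
    """Sub-matrix of the Hessian ``l''(beta)`` on ``columns`` x ``columns``,
    computed without forming the p x p matrix: ``-Xc' diag(mu(1-mu)) Xc``."""
    cols = np.asarray(columns, dtype=np.intp)
    eta = beta0 + model.X @ np.asarray(beta, dtype=float)
    w = expit(eta)
    w = w * (1.0 - w)
    Xc = model.X[:, cols]
    return -(Xc.T * w) @ Xc


@dataclass
class LogisticFit:
    beta0: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    separated: bool = False
    rank_deficient: bool = False


def fit_logistic(X: np.ndarray, y: np.ndarray, *,
                 ridge: float = 0.0,
                 max_iter: int = 50,
                 tol: float = 1e-10,
                 eta_bound: float = ETA_BOUND) -> LogisticFit:
    """Newton/IRLS maximum likelihood for a low-dimensional logistic model.

    The intercept is always estimated and never penalised; ``ridge`` (if
    positive) penalises the slopes only.  Safeguards: step halving whenever
    a full Newton step would decrease the (penalised) log-likelihood, a
    deterministic ridge fallback on rank-deficient information matrices,
    and early exit with ``separated=True`` once the linear predictor hits
    ``eta_bound`` (the data are then (quasi-)separated and the MLE lies at
    infinity).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape if X.size else (y.size, 0)
    ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    b0 = float(np.log(ybar / (1.0 - ybar)))
    if d == 0:
        ll = _loglik_eta(y, np.full(n, b0))
        return LogisticFit(b0, np.zeros(0), ll, True, 0)
    beta = np.zeros(d)
    rank_def = False

    def pen_ll(b0_, beta_, eta_):
        return _loglik_eta(y, eta_) - 0.5 * ridge * float(beta_ @ beta_)

    eta = np.full(n, b0)
    cur = pen_ll(b0, beta, eta)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        g0 = float(np.sum(y - mu))
        g = X.T @ (y - mu) - ridge * beta
        XtW = X.T * w
        H = np.empty((d + 1, d + 1))
        H[0, 0] = w.sum()
        H[0, 1:] = H[1:, 0] = XtW.sum(axis=1)
        H[1:, 1:] = XtW @ X
        if ridge > 0:
            H[1:, 1:][np.diag_indices(d)] += ridge
        rhs = np.concatenate(([g0], g))
        try:
            step = np.linalg.solve(H, rhs)
        except np.linalg.LinAlgError:
            rank_def = True
            H[1:, 1:][np.diag_indices(d)] += 1e-8 * np.trace(H[1:, 1:]) / d
            step = np.linalg.solve(H, rhs)
        if not np.isfinite(step).all():
            rank_def = True
            break
        # step halving against the exact objective
        t = 1.0
        for _ in range(30):
            b0_new = b0 + t * step[0]
            beta_new = beta + t * step[1:]
            eta_new = b0_new + X @ beta_new
            new = pen_ll(b0_new, beta_new, eta_new)
            if new >= cur - 1e-12:
                break
            t *= 0.5
        else:
            converged = True  # no ascent direction left
            break
        delta = t * np.abs(step).max()
        b0, beta, eta, cur = b0_new, beta_new, eta_new, new
        if np.abs(eta).max() > eta_bound:
            separated = True
            break
        if delta < tol:
            converged = True
            break
    ll = _loglik_eta(y, eta)
    return LogisticFit(b0, beta, ll, converged and not separated, it,
                       separated=separated, rank_deficient=rank_def)


# ---------------------------------------------------------------------------
# vectorised marginal fits (competitor screeners)
# ---------------------------------------------------------------------------

def univariate_logistic_tests(X: np.ndarray, y: np.ndarray, *,
                              max_iter: int = 40, tol: float = 1e-9,
                              chunk: int = 1024):
    """Wald p-values from one single-covariate logistic fit per column.

    All columns are fitted simultaneously by a vectorised 2-parameter
    Newton iteration.  Columns whose fit does not converge (or separates)
    are flagged and assigned p-value 1.

    Returns ``(pvalues, flags)`` of shape ``(p,)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    pvals = np.ones(p)
    flags = np.zeros(p, dtype=bool)
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        Xc = X[:, lo:hi]
        m = hi - lo
        a = np.zeros(m)
        b = np.zeros(m)
        ok = np.ones(m, dtype=bool)
        det = np.full(m, np.nan)
        h00 = h01 = h11 = None
        for _ in range(max_iter):
            eta = np.clip(a + Xc * b, -ETA_BOUND, ETA_BOUND)
            mu = expit(eta)
            w = mu * (1.0 - mu) + 1e-12
            r = y[:, None] - mu
            g0 = r.sum(axis=0)
            g1 = (Xc * r).sum(axis=0)
            h00 = w.sum(axis=0)
            h01 = (Xc * w).sum(axis=0)
            h11 = (Xc * Xc * w).sum(axis=0)
            det = h00 * h11 - h01 * h01
            bad = ~np.isfinite(det) | (det <= 1e-12)
            ok &= ~bad
            det_safe = np.where(bad, 1.0, det)
            da = (h11 * g0 - h01 * g1) / det_safe
            db = (h00 * g1 - h01 * g0) / det_safe
            da[bad] = 0.0
            db[bad] = 0.0
            a += da
            b += db
            if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
                break
        else:
            ok &= (np.abs(da) < 1e-4) & (np.abs(db) < 1e-4)
        ok &= np.isfinite(a) & np.isfinite(b)
        se = np.sqrt(np.where(det > 0, h00 / np.where(det > 0, det, 1.0), np.inf))
        z = np.where(se > 0, b / se, 0.0)
        pv = 2.0 * norm.sf(np.abs(z))
        pv[~ok] = 1.0
        pvals[lo:hi] = pv
        flags[lo:hi] = ~ok
    return pvals, flags


def genewise_logistic_tests(X: np.ndarray, y: np.ndarray,
                            columns_of_gene: np.ndarray, *,
                            max_iter: int = 40, tol: float = 1e-9,
                            chunk: int = 512):
    """Likelihood-ratio p-values from one n0-covariate logistic fit per gene.

    For each gene, the model with its ``n0`` omics plus intercept is fitted
    (batched Newton) and compared with the intercept-only model by the LRT
    on ``n0`` degrees of freedom.  Non-convergent genes are flagged with
    p-value 1.

    Returns ``(pvalues, flags)`` of shape ``(G,)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    cols = np.asarray(columns_of_gene, dtype=np.intp)
    G, n0 = cols.shape
    d = n0 + 1
    ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    ll_null = _loglik_eta(y, np.full(n, np.log(ybar / (1 - ybar))))
    pvals = np.ones(G)
    flags = np.zeros(G, dtype=bool)
    for lo in range(0, G, chunk):
        hi = min(lo + chunk, G)
        m = hi - lo
        A = np.empty((n, m, d))
        A[:, :, 0] = 1.0
        A[:, :, 1:] = X[:, cols[lo:hi].reshape(-1)].reshape(n, m, n0)
        theta = np.zeros((m, d))
        ok = np.ones(m, dtype=bool)
        for _ in range(max_iter):
            eta = np.clip(np.einsum("ngk,gk->ng", A, theta), -ETA_BOUND, ETA_BOUND)
            mu = expit(eta)
            w = mu * (1.0 - mu) + 1e-12
            r = y[:, None] - mu
            grad = np.einsum("ng,ngk->gk", r, A)
            H = np.einsum("ngk,ng,ngl->gkl", A, w, A, optimize=True)
            H[:, np.arange(d), np.arange(d)] += 1e-10
            try:
                step = np.linalg.solve(H, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                ok[:] = False
                break
            bad = ~np.isfinite(step).all(axis=1)
            ok &= ~bad
            step[bad] = 0.0
            theta += step
            if np.abs(step).max(initial=0) < tol:
                break
        else:
            ok &= np.abs(step).max(axis=1) < 1e-4
        eta = np.clip(np.einsum("ngk,gk->ng", A, theta), -ETA_BOUND, ETA_BOUND)
        ll = (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
        stat = np.clip(2.0 * (ll - ll_null), 0.0, None)
        pv = chi2.sf(stat, df=n0)
        pv[~ok] = 1.0
        pvals[lo:hi] = pv
        flags[lo:hi] = ~ok
    return pvals, flags
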