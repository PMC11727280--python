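"""End-to-end pipeline, Monte-Carlo harness and cross-validated AUC.

The three-stage pipeline chains gene clustering (optional -- labels may be
supplied), joint screening and group-bridge selection.  The Monte-Carlo
harness replays the simulation design: generate a replicate, screen with
JSBD, then run the size-matched competitors (GMS keeps as many genes as
JSBD retained, OMS keeps three times as many omics) and record, per method,
whether every truly non-zero gene survived and which fraction did.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .clustering import cluster_genes, gene_association_matrix
from .glm import GLMModel
from .group_bridge import GroupBridgeFit, select_lambda, selected_genes_from_omics
from .screening import (
    ScreeningConfig,
    ScreeningResult,
    genes_from_omics,
    gms_screen,
    jsbd_screen,
    jsd_screen,
    oms_screen,
    retention_metrics,
)
from .structure import HierarchicalStructure
from .synthetic import (
    SimulationScenario,
    permute_cluster_labels,
    simulate_dataset,
)

logger = logging.getLogger("trilevel")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SimulationReport",
    "CVReport",
    "run_pipeline",
    "simulation_study",
    "cv_auc",
]

_JOINT = {"jsbd": jsbd_screen, "jsd": jsd_screen}


@dataclass
class PipelineConfig:
    """Knobs of the three-stage pipeline."""

    q1: int
    q2_rate: float = 0.10
    u: float = 1e5
    tol: float = 1e-6
    method: str = "jsbd"
    cluster_power: float = 6.0
    n_clusters: int | None = None
    n_lambda: int = 50

    def screening_config(self) -> ScreeningConfig:
        return ScreeningConfig(q1=self.q1, q2_rate=self.q2_rate,
                               u=self.u, tol=self.tol)


@dataclass
class PipelineResult:
    labels: np.ndarray
    screening: ScreeningResult
    fit: GroupBridgeFit
    retained_columns: np.ndarray
    gene_of_variable: np.ndarray
    selected_omics_columns: np.ndarray
    selected_genes: frozenset[int]


def _screen_to_design(X, structure, result):
    """Post-screening design: retained columns, their gene and cluster ids,
    and cluster groups over the retained variables."""
    cols = structure.columns_of_gene[result.support_genes].reshape(-1)
    gene_of_var = np.repeat(result.support_genes, structure.n0)
    cl_of_var = structure.cluster_of_gene[gene_of_var]
    groups = [np.flatnonzero(cl_of_var == c) for c in np.unique(cl_of_var)]
    return X[:, cols], cols, gene_of_var, groups


def run_pipeline(X: np.ndarray, y: np.ndarray,
                 structure: HierarchicalStructure,
                 config: PipelineConfig,
                 labels: np.ndarray | None = None) -> PipelineResult:
    """Cluster (unless labels are given), screen, then select by group
    bridge with BIC-tuned lambda.  Deterministic given its inputs."""
    if labels is None:
        logger.info("pipeline: clustering %d genes", structure.G)
        assoc = gene_association_matrix(X, structure)
        labels = cluster_genes(assoc, power=config.cluster_power,
                               n_clusters=config.n_clusters).labels
    labels = np.asarray(labels, dtype=np.intp)
    st = structure.with_cluster_labels(labels)
    model = GLMModel(X, y)
    scfg = config.screening_config()
    scfg.q1 = min(scfg.q1, st.C)
    logger.info("pipeline: screening with %s, q1=%d", config.method, scfg.q1)
    screen = _JOINT[config.method](model, st, scfg)
    Xr, cols, gene_of_var, groups = _screen_to_design(X, st, screen)
    logger.info("pipeline: group bridge on %d retained variables", Xr.shape[1])
    fit = select_lambda(Xr, y, groups, n_lambda=config.n_lambda)
    sel_cols = cols[fit.selected_omics]
    sel_genes = selected_genes_from_omics(fit.beta_hat, gene_of_var)
    return PipelineResult(
        labels=labels,
        screening=screen,
        fit=fit,
        retained_columns=cols,
        gene_of_variable=gene_of_var,
        selected_omics_columns=sel_cols,
        selected_genes=sel_genes,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------

@dataclass
class SimulationReport:
    """Aggregated retention results of one simulation arm."""

    table: pd.DataFrame          # per method: all-retained prop, mean, sd
    replicates: pd.DataFrame     # per replicate x method raw metrics
    n_replicates: int
    master_seed: int | None
    failures: int = 0


def _one_replicate(scenario: SimulationScenario, methods: Sequence[str],
                   config: ScreeningConfig, seed: int,
                   perturb_fraction: float | None) -> dict:
    data = simulate_dataset(scenario, seed=seed)
    st = data.structure
    labels = st.cluster_of_gene
    realized_ari = 1.0
    if perturb_fraction:
        perm_seed = np.random.SeedSequence([seed, 0x5EED]).generate_state(1)[0]
        labels = permute_cluster_labels(labels, perturb_fraction,
                                        seed=int(perm_seed), n_clusters=st.C)
        from .clustering import adjusted_rand_index
        realized_ari = adjusted_rand_index(st.cluster_of_gene, labels)
    st_used = st.with_cluster_labels(labels)
    model = GLMModel(data.X, data.y)
    truth = data.true_nonzero_genes
    out: dict = {"seed": seed, "ari": realized_ari}
    jsbd = None
    if any(m in methods for m in ("jsbd", "gms", "oms")):
        jsbd = jsbd_screen(model, st_used, config)
    for m in methods:
        if m == "jsbd":
            genes = jsbd.retained_gene_set
        elif m == "jsd":
            genes = jsd_screen(model, st_used, config).retained_gene_set
        elif m == "gms":
            k = len(jsbd.retained_gene_set)
            genes = gms_screen(model, st_used, k).retained_set
        elif m == "oms":
            k = st.n0 * len(jsbd.retained_gene_set)
            res = oms_screen(model, st_used, k)
            genes = genes_from_omics(res.retained, st_used)
        else:
            raise ValueError(f"unknown method {m!r}")
        all_ret, prop = retention_metrics(genes, truth)
        out[f"{m}_all"] = all_ret
        out[f"{m}_prop"] = prop
        out[f"{m}_size"] = len(genes)
    return out


def simulation_study(scenario: SimulationScenario,
                     methods: Sequence[str] = ("oms", "gms", "jsd", "jsbd"),
                     reps: int = 200,
                     seed: int | None = None,
                     config: ScreeningConfig | None = None,
                     perturb_fraction: float | None = None,
                     n_jobs: int = 1) -> SimulationReport:
    """Monte-Carlo retention study for one scenario.

    Each replicate draws fresh data from an independently seeded stream,
    runs JSBD and the requested size-matched competitors, and records
    whether all truly non-zero genes survived screening.  Replicates are
    independent tasks, so results do not depend on scheduling order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if config is None:
        config = ScreeningConfig(q1=8)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(reps)]
    runner = Parallel(n_jobs=n_jobs) if n_jobs != 1 else None
    rows = []
    failures = 0
    if runner is not None:
        results = runner(
            delayed(_one_replicate)(scenario, methods, config, s, perturb_fraction)
            for s in seeds
        )
        rows = list(results)
    else:
        for s in seeds:
            try:
                rows.append(_one_replicate(scenario, methods, config, s,
                                           perturb_fraction))
            except Exception:   # pragma: no cover - defensive
                logger.exception("replicate with seed %d failed", s)
                failures += 1
    rep = pd.DataFrame(rows)
    summary = {}
    for m in methods:
        summary[m] = {
            "prop_all_retained": rep[f"{m}_all"].mean(),
            "mean_prop_retained": rep[f"{m}_prop"].mean(),
            "sd_prop_retained": rep[f"{m}_prop"].std(ddof=1) if len(rep) > 1 else 0.0,
        }
    table = pd.DataFrame(summary).T
    return SimulationReport(table=table, replicates=rep,
                            n_replicates=len(rep), master_seed=seed,
                            failures=failures)


# ---------------------------------------------------------------------------
# cross-validated AUC
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    mean_auc: float
    sd_auc: float
    mean_n_genes: float
    sd_n_genes: float
    folds: int
    repeats: int
    per_fold: pd.DataFrame


def cv_auc(X: np.ndarray, y: np.ndarray,
           structure: HierarchicalStructure,
           config: PipelineConfig,
           labels: np.ndarray | None = None,
           folds: int = 5, repeats: int = 20,
           seed: int | None = None) -> CVReport:
    """Repeated stratified K-fold AUC of the full pipeline.

    The entire pipeline (screening and group bridge; clustering too when
    labels are not supplied) is refit inside every training fold; the AUC
    of the held-out fold is computed from the fitted probabilities.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel().astype(int)
    ss = np.random.SeedSequence(seed)
    rows = []
    for r, child in enumerate(ss.spawn(repeats)):
        fold_seed = int(child.generate_state(1)[0] % (2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=fold_seed)
        for f, (tr, te) in enumerate(skf.split(X, y)):
            if y[tr].min() == y[tr].max() or y[te].min() == y[te].max():
                logger.warning("degenerate fold %d.%d skipped", r, f)
                continue
            res = run_pipeline(X[tr], y[tr], structure, config,
                               labels=labels)
            eta = res.fit.beta0_hat + X[te][:, res.retained_columns] @ res.fit.beta_hat
            auc = roc_auc_score(y[te], expit(eta))
            rows.append({"repeat": r, "fold": f, "auc": auc,
                         "n_genes": len(res.selected_genes)})
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise RuntimeError("all folds were degenerate")
    return CVReport(
        mean_auc=float(per_fold["auc"].mean()),
        sd_auc=float(per_fold["auc"].std(ddof=1)) if len(per_fold) > 1 else 0.0,
        mean_n_genes=float(per_fold["n_genes"].mean()),
        sd_n_genes=float(per_fold["n_genes"].std(ddof=1)) if len(per_fold) > 1 else 0.0,
        folds=folds,
        repeats=repeats,
        per_fold=per_fold,
    )
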