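import numpy as np
import pytest
import statsmodels.api as sm
from itertools import combinations, product

from trilevel.glm import GLMModel, gradient, loglik
from trilevel.screening import (
    BlockWeightMatrix,
    ScreeningConfig,
    build_block_W,
    cluster_scores,
    compute_tau_bound,
    constrained_select,
    gene_scores,
    genes_from_omics,
    gms_screen,
    jsbd_screen,
    jsd_screen,
    oms_screen,
    refit,
    retention_metrics,
    surrogate_argmax,
)
from trilevel.structure import from_cluster_sizes

from conftest import make_logistic_instance


def _grad_genes(model, structure, beta_flat, beta0=0.0):
    g = gradient(model, beta_flat, beta0)
    return g[structure.columns_of_gene]


class TestBlockW:
    def test_blocks_at_zero_are_scaled_gram_over_four(self):
        model, st, _ = make_logistic_instance(0)
        cfg = ScreeningConfig(q1=st.C, q2=None)
        W = build_block_W(model, np.zeros(st.p), st, cfg)
        q2 = cfg.resolve_q2(st)
        for g in range(st.G):
            Xg = model.X[:, st.columns_of_gene[g]]
            np.testing.assert_allclose(W.blocks[g], Xg.T @ Xg / 4.0, atol=1e-10)
            assert W.scale[g] == q2[st.cluster_of_gene[g]] * st.n0

    def test_blocks_positive_semidefinite(self):
        model, st, _ = make_logistic_instance(1)
        rng = np.random.default_rng(0)
        beta = 0.3 * rng.standard_normal(st.p)
        W = build_block_W(model, beta, st, ScreeningConfig(q1=1))
        assert np.linalg.eigvalsh(W.blocks).min() >= -1e-10

    def test_dense_assembly_matches_masked_hessian(self):
        """p=6, two clusters: the assembled block-diagonal equals the dense
        negative Hessian masked outside gene blocks and scaled."""
        model, st, _ = make_logistic_instance(2, n=40, sizes=(2, 1), n0=2)
        rng = np.random.default_rng(1)
        beta = 0.2 * rng.standard_normal(st.p)
        cfg = ScreeningConfig(q1=st.C, q2=1)
        W = build_block_W(model, beta, st, cfg)
        from trilevel.glm import hessian_block
        dense = np.zeros((st.p, st.p))
        q2 = cfg.resolve_q2(st)
        for g in range(st.G):
            cols = st.columns_of_gene[g]
            blk = -hessian_block(model, beta, 0.0, cols)
            dense[np.ix_(cols, cols)] = q2[st.cluster_of_gene[g]] * st.n0 * blk
        np.testing.assert_allclose(W.dense(st), dense, atol=1e-9)


class TestSurrogate:
    def test_zero_gradient_fixed_point(self):
        model, st, _ = make_logistic_instance(3)
        W = build_block_W(model, np.zeros(st.p), st, ScreeningConfig(q1=1))
        beta_g = np.ones((st.G, st.n0))
        omega = surrogate_argmax(beta_g, np.zeros((st.G, st.n0)), W, 1e5)
        np.testing.assert_array_equal(omega, beta_g)

    def test_step_inversely_proportional_to_u(self):
        model, st, _ = make_logistic_instance(4)
        W = build_block_W(model, np.zeros(st.p), st, ScreeningConfig(q1=1))
        grad = _grad_genes(model, st, np.zeros(st.p))
        beta_g = np.zeros((st.G, st.n0))
        step1 = surrogate_argmax(beta_g, grad, W, 1e3)
        step2 = surrogate_argmax(beta_g, grad, W, 2e3)
        np.testing.assert_allclose(step2, step1 / 2.0, atol=1e-12)

    def test_matches_numeric_optimizer(self):
        """On p=4 the closed form agrees with numerically maximising the
        quadratic surrogate."""
        from scipy.optimize import minimize

        model, st, _ = make_logistic_instance(5, n=30, sizes=(1, 1), n0=2)
        rng = np.random.default_rng(2)
        beta = 0.1 * rng.standard_normal(st.p)
        u = 50.0
        cfg = ScreeningConfig(q1=st.C, q2=1, u=u)
        W = build_block_W(model, beta, st, cfg)
        grad = _grad_genes(model, st, beta)
        beta_g = beta[st.columns_of_gene]
        omega = surrogate_argmax(beta_g, grad, W, u)
        Wd = W.dense(st)
        g_flat = gradient(model, beta, 0.0)

        def neg_g(w):
            d = w - beta
            return -(d @ g_flat - 0.5 * u * d @ Wd @ d)

        res = minimize(neg_g, beta, method="BFGS", tol=1e-12)
        omega_flat = np.zeros(st.p)
        omega_flat[st.columns_of_gene.reshape(-1)] = omega.reshape(-1)
        np.testing.assert_allclose(omega_flat, res.x, atol=1e-6)


class TestScores:
    def test_zero_block_zero_score(self):
        W = BlockWeightMatrix(np.eye(2)[None], np.ones(1), np.zeros(1, np.intp))
        assert gene_scores(np.zeros((1, 2)), W)[0] == 0.0

    def test_identity_weight_quadratic(self):
        W = BlockWeightMatrix(np.eye(3)[None], np.ones(1), np.zeros(1, np.intp))
        assert gene_scores(np.array([[1.0, 2.0, 2.0]]), W)[0] == pytest.approx(9.0)

    def test_random_psd_matches_quadratic_form(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((3, 3))
        M = M @ M.T
        v = rng.standard_normal(3)
        W = BlockWeightMatrix(M[None], np.array([2.5]), np.zeros(1, np.intp))
        assert gene_scores(v[None], W)[0] == pytest.approx(v @ M @ v)
        st = from_cluster_sizes([1], 3)
        assert cluster_scores(v[None], W, st)[0] == pytest.approx(2.5 * v @ M @ v)


def _surrogate_value(model, st, beta_flat, omega_genes, W, u):
    """g(omega | beta) evaluated directly."""
    omega_flat = np.zeros(st.p)
    omega_flat[st.columns_of_gene.reshape(-1)] = omega_genes.reshape(-1)
    d = omega_flat - beta_flat
    g_flat = gradient(model, beta_flat, 0.0)
    quad = 0.0
    for g in range(st.G):
        dg = d[st.columns_of_gene[g]]
        quad += W.scale[g] * dg @ W.blocks[g] @ dg
    return loglik(model, beta_flat, 0.0) + d @ g_flat - 0.5 * u * quad


def _feasible_supports(st, q1, q2):
    per_cluster = []
    for c in range(st.C):
        genes = st.genes_of_cluster(c)
        subsets = [frozenset()]
        for k in range(1, int(q2[c]) + 1):
            subsets += [frozenset(s) for s in combinations(genes.tolist(), k)]
        per_cluster.append(subsets)
    for combo in product(*per_cluster):
        used = sum(1 for s in combo if s)
        if used <= q1:
            yield frozenset().union(*combo)


class TestConstrainedSelect:
    def test_non_binding_keeps_everything(self):
        model, st, _ = make_logistic_instance(6)
        cfg = ScreeningConfig(q1=st.C, q2=st.Hc.copy())
        W = build_block_W(model, np.zeros(st.p), st, cfg)
        grad = _grad_genes(model, st, np.zeros(st.p))
        omega = surrogate_argmax(np.zeros((st.G, st.n0)), grad, W, cfg.u)
        selected, masked, _, _ = constrained_select(omega, W, st, cfg)
        assert np.array_equal(selected, np.arange(st.G))
        np.testing.assert_array_equal(masked, omega)

    def test_zero_omega_gene_never_beats_positive(self):
        st = from_cluster_sizes([2], 1)
        W = BlockWeightMatrix(np.ones((2, 1, 1)), np.ones(2),
                              st.cluster_of_gene)
        omega = np.array([[0.0], [0.7]])
        cfg = ScreeningConfig(q1=1, q2=1)
        selected, _, _, _ = constrained_select(omega, W, st, cfg)
        assert selected.tolist() == [1]

    @pytest.mark.parametrize("seed", range(50))
    def test_exhaustive_surrogate_optimality(self, seed):
        """The double ranking attains the exhaustive-search maximum of the
        surrogate over all supports satisfying both cardinality
        constraints (tiny instances, C<=3, Hc<=3, n0<=2)."""
        rng = np.random.default_rng(seed)
        C = int(rng.integers(2, 4))
        sizes = rng.integers(1, 4, size=C).tolist()
        n0 = int(rng.integers(1, 3))
        model, st, _ = make_logistic_instance(1000 + seed, n=30,
                                              sizes=sizes, n0=n0)
        q1 = int(rng.integers(1, st.C + 1))
        q2 = np.maximum(1, rng.integers(1, st.Hc.max() + 1, size=st.C))
        q2 = np.minimum(q2, st.Hc)
        u = 10.0 ** rng.uniform(0, 4)
        cfg = ScreeningConfig(q1=q1, q2=q2, u=u)
        # evaluate at zero and at a random nonzero expansion point
        for beta_flat in (np.zeros(st.p), 0.3 * rng.standard_normal(st.p)):
            W = build_block_W(model, beta_flat, st, cfg)
            grad = _grad_genes(model, st, beta_flat)
            beta_g = beta_flat[st.columns_of_gene]
            omega = surrogate_argmax(beta_g, grad, W, u)
            _, masked, _, _ = constrained_select(omega, W, st, cfg)
            achieved = _surrogate_value(model, st, beta_flat, masked, W, u)
            best = -np.inf
            for S in _feasible_supports(st, q1, q2):
                cand = np.zeros((st.G, st.n0))
                for g in S:
                    cand[g] = omega[g]
                best = max(best, _surrogate_value(model, st, beta_flat,
                                                  cand, W, u))
            assert achieved >= best - 1e-9 * (1 + abs(best))


class TestRefit:
    def test_full_mle_when_all_retained(self):
        model, st, _ = make_logistic_instance(7, n=80)
        fit = refit(model, np.arange(st.p))
        ref = sm.GLM(model.y, sm.add_constant(model.X),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params[1:], atol=1e-6)

    def test_empty_support_intercept_only(self):
        model, _, _ = make_logistic_instance(8)
        fit = refit(model, np.zeros(0, dtype=np.intp))
        ybar = model.y.mean()
        assert fit.beta0 == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-9)

    def test_too_many_columns_rejected(self):
        model, st, _ = make_logistic_instance(9, n=8)
        with pytest.raises(ValueError):
            refit(model, np.arange(st.p))


class TestJointScreening:
    def test_non_binding_reduces_to_full_mle(self):
        model, st, _ = make_logistic_instance(10, n=100)
        cfg = ScreeningConfig(q1=st.C, q2=st.Hc.copy())
        res = jsbd_screen(model, st, cfg)
        assert res.converged
        assert np.array_equal(res.support_genes, np.arange(st.G))
        ref = sm.GLM(model.y, sm.add_constant(model.X),
                     family=sm.families.Binomial()).fit()
        cols = st.columns_of_gene.reshape(-1)
        np.testing.assert_allclose(res.beta_hat[cols],
                                   ref.params[1:], atol=1e-5)

    def test_jsd_equals_jsbd_for_single_omics(self):
        model, st, _ = make_logistic_instance(11, sizes=(3, 2, 2), n0=1)
        cfg = ScreeningConfig(q1=2, q2=1)
        r1 = jsbd_screen(model, st, cfg)
        r2 = jsd_screen(model, st, cfg)
        assert np.array_equal(r1.support_genes, r2.support_genes)
        np.testing.assert_allclose(r1.beta_hat, r2.beta_hat, atol=1e-12)

    def test_orthogonal_within_gene_columns_same_ranking(self):
        """When each gene's omics columns are orthogonal the gene blocks
        are already diagonal, so JSBD and JSD select identically."""
        rng = np.random.default_rng(12)
        st = from_cluster_sizes([2, 2], n0=2)
        n = 32
        Qfull, _ = np.linalg.qr(rng.standard_normal((n, st.p)))
        X = Qfull * np.sqrt(n)
        eta = X[:, 0] - X[:, 5]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        model = GLMModel(X, y)
        cfg = ScreeningConfig(q1=2, q2=1)
        r1 = jsbd_screen(model, st, cfg)
        r2 = jsd_screen(model, st, cfg)
        assert np.array_equal(r1.support_genes, r2.support_genes)

    def test_scale_factor_does_not_change_within_cluster_ranking(self):
        model, st, _ = make_logistic_instance(13)
        for scale in (True, False):
            cfg = ScreeningConfig(q1=st.C, q2=1, scale_blocks=scale)
            W = build_block_W(model, np.zeros(st.p), st, cfg)
            grad = _grad_genes(model, st, np.zeros(st.p))
            omega = surrogate_argmax(np.zeros((st.G, st.n0)), grad, W, cfg.u)
            sel, _, _, _ = constrained_select(omega, W, st, cfg)
            kept = {c: np.intersect1d(sel, st.genes_of_cluster(c)).tolist()
                    for c in range(st.C)}
            if scale:
                kept_scaled = kept
        assert kept == kept_scaled

    @pytest.mark.parametrize("seed", range(100))
    def test_ascent_property(self, seed):
        """With u=1e5 the log-likelihood trace never decreases across
        iterations (the surrogate is a minorant whenever u dominates the
        curvature ratio)."""
        model, st, _ = make_logistic_instance(2000 + seed, n=50,
                                              sizes=(2, 3, 2), n0=2,
                                              signal=0.8)
        cfg = ScreeningConfig(q1=2, q2=1)
        res = jsbd_screen(model, st, cfg)
        assert np.all(np.diff(res.loglik_trace) >= -1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_tau_below_u_on_small_instances(self, seed):
        """The curvature ratio tau(k) (dense generalised-eigenvalue
        diagnostic) stays far below the default u = 1e5."""
        model, st, _ = make_logistic_instance(3000 + seed, n=50)
        cfg = ScreeningConfig(q1=2, q2=1, track_tau=True)
        res = jsbd_screen(model, st, cfg)
        assert res.tau_trace is not None and len(res.tau_trace) > 0
        assert np.all(res.tau_trace > 0)
        assert res.tau_trace.max() <= cfg.u


class TestMarginalScreening:
    def test_everything_retained_at_full_k(self):
        model, st, _ = make_logistic_instance(14)
        assert oms_screen(model, st, model.p).retained.size == model.p
        assert gms_screen(model, st, st.G).retained.size == st.G

    def test_strong_omics_ranks_first(self):
        rng = np.random.default_rng(15)
        st = from_cluster_sizes([2, 2], n0=2)
        n = 500
        X = rng.standard_normal((n, st.p))
        eta = 2.0 * X[:, 3]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        model = GLMModel(X, y)
        res = oms_screen(model, st, 1)
        assert res.retained.tolist() == [3]

    def test_oms_matches_reference_ranking(self):
        rng = np.random.default_rng(16)
        n, p = 90, 6
        st = from_cluster_sizes([3, 3], n0=1)
        X = rng.standard_normal((n, p))
        y = rng.binomial(1, 0.5, size=n).astype(float)
        model = GLMModel(X, y)
        res = oms_screen(model, st, 3)
        ref_p = [sm.GLM(y, sm.add_constant(X[:, j]),
                        family=sm.families.Binomial()).fit().pvalues[1]
                 for j in range(p)]
        expected = np.sort(np.argsort(ref_p)[:3])
        np.testing.assert_array_equal(res.retained, expected)


class TestRetention:
    def test_metrics_arithmetic(self):
        assert retention_metrics({1, 2, 3, 9}, {1, 2}) == (1, 1.0)
        assert retention_metrics({7}, {1, 2}) == (0, 0.0)
        assert retention_metrics({1, 2, 3, 4}, {1, 2, 3, 4, 5}) == (0, 0.8)

    def test_genes_from_omics_rules(self):
        st = from_cluster_sizes([2], n0=3)
        cols = np.array([0, 1, 2, 3])   # gene 0 fully, gene 1 partially
        assert genes_from_omics(cols, st, rule="any") == {0, 1}
        assert genes_from_omics(cols, st, rule="all") == {0}
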