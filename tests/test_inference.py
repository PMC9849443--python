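import numpy as np
import pytest
from scipy.special import logsumexp

from stmint.graph import LabelField, NeighborGraph, build_neighbor_graph, neighbor_counts, sample_potts
from stmint.inference import (
    FitOptions,
    compute_responsibilities,
    embedding_posterior,
    estimate_beta,
    fit_model,
    icm_update_labels,
    initialize_fit,
    m_step,
    select_num_clusters,
    update_v,
)
from stmint.model import LatentState, SlideData, emission_logliks
from tests.conftest import gaussian_slide, lattice_coords, random_params


@pytest.fixture()
def small_fit_setup():
    rng = np.random.default_rng(7)
    slide, y, Z, W = gaussian_slide(rng, n_rows=8, n_cols=8, p=20, q=2, K=3)
    opts = FitOptions(K=3, q=2, seed=1)
    params, state = initialize_fit([slide], opts)
    return slide, params, state, opts


class TestInitializeFit:
    def test_orthonormal_and_deterministic(self, small_fit_setup):
        slide, params, state, opts = small_fit_setup
        q = params.q
        assert np.allclose(params.W.T @ params.W, np.eye(q), atol=1e-8)
        params2, state2 = initialize_fit([slide], opts)
        assert np.array_equal(params.W, params2.W)
        assert np.array_equal(state.Y[0], state2.Y[0])

    def test_k_distinct_labels(self, small_fit_setup):
        slide, params, state, opts = small_fit_setup
        assert len(np.unique(state.Y[0])) == opts.K

    def test_too_few_spots(self):
        rng = np.random.default_rng(0)
        slide, *_ = gaussian_slide(rng, n_rows=2, n_cols=2, p=6, q=1, K=2)
        with pytest.raises(ValueError, match="< K"):
            initialize_fit([slide], FitOptions(K=10, q=1))

    def test_mismatched_gene_panels(self):
        rng = np.random.default_rng(0)
        s1, *_ = gaussian_slide(rng, p=10)
        s2, *_ = gaussian_slide(rng, p=12)
        with pytest.raises(ValueError, match="gene panel"):
            initialize_fit([s1, s2], FitOptions(K=2, q=2))


class TestResponsibilities:
    def test_rows_sum_to_one(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        R = compute_responsibilities([slide], params, state)[0]
        assert np.allclose(R.sum(axis=1), 1.0, atol=1e-12)
        assert (R >= 0).all()

    def test_beta_zero_is_pure_gaussian(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        params.beta = [0.0]
        R = compute_responsibilities([slide], params, state)[0]
        em = emission_logliks(slide.expr, state.V[0], params, 0)
        expected = np.exp(em - logsumexp(em, axis=1, keepdims=True))
        assert np.allclose(R, expected, atol=1e-12)

    def test_matches_bruteforce_product(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        params.beta = [0.8]
        R = compute_responsibilities([slide], params, state)[0]
        em = emission_logliks(slide.expr, state.V[0], params, 0)
        c = neighbor_counts(slide.graph, state.Y[0], params.K)
        for i in range(0, slide.n_spots, 7):
            w = np.exp(0.8 * c[i]) * np.exp(em[i] - em[i].max())
            assert np.allclose(R[i], w / w.sum(), atol=1e-10)


class TestIcmUpdateLabels:
    def test_beta_zero_argmax_marginal(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        params.beta = [0.0]
        Y = icm_update_labels([slide], params, state)[0]
        em = emission_logliks(slide.expr, state.V[0], params, 0)
        assert np.array_equal(Y, em.argmax(axis=1))

    def test_tie_breaks_toward_smallest(self):
        # 2 isolated-ish spots, emission engineered with an exact tie
        g = NeighborGraph.from_edges(2, np.array([[0, 1]]))
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        X = np.zeros((2, 3))
        slide = SlideData(expr=X, coords=coords, graph=g, slide_id="t")
        rng = np.random.default_rng(0)
        params = random_params(rng, p=3, q=1, K=6)
        params.beta = [0.0]
        em = np.zeros((2, 6))
        em[:, [1, 4]] = 5.0  # tie between k=1 and k=4 (0-based)
        state = LatentState(
            Z=[np.zeros((2, 1))], Zmom=[np.zeros((2, 1, 1))],
            V=[np.zeros((2, 1))], Y=[np.zeros(2, dtype=np.int64)],
            R=[np.full((2, 6), 1 / 6)],
        )
        Y = icm_update_labels([slide], params, state, emissions=[em])[0]
        assert list(Y) == [1, 1]

    def test_path_graph_matches_bruteforce_sweep(self):
        """Sequential sweep on a 6-spot path equals an explicit per-site
        coordinate-wise argmax that recomputes neighbor counts."""
        n, K = 6, 3
        edges = np.array([[i, i + 1] for i in range(n - 1)])
        g = NeighborGraph.from_edges(n, edges)
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        rng = np.random.default_rng(5)
        em = rng.standard_normal((n, K))
        beta = 1.3
        y0 = rng.integers(0, K, n)

        slide = SlideData(
            expr=np.zeros((n, 2)), coords=coords, graph=g, slide_id="p"
        )
        params = random_params(rng, p=2, q=1, K=K)
        params.beta = [beta]
        state = LatentState(
            Z=[np.zeros((n, 1))], Zmom=[np.zeros((n, 1, 1))],
            V=[np.zeros((n, 1))], Y=[y0.copy()], R=[np.full((n, K), 1 / K)],
        )
        got = icm_update_labels([slide], params, state, emissions=[em])[0]

        y = y0.copy()
        nbrs = g.neighbors
        for i in range(n):
            counts = np.bincount(y[nbrs[i]], minlength=K)
            y[i] = int(np.argmax(beta * counts + em[i]))
        assert np.array_equal(got, y)


class TestUpdateV:
    def test_large_lambda_pulls_to_neighbor_mean(self):
        rng = np.random.default_rng(2)
        slide, *_ = gaussian_slide(rng, n_rows=5, n_cols=5, p=8, q=2, K=2)
        params = random_params(rng, p=8, q=2, K=2)
        params.Lambda = [np.full(8, 1e8)]
        n = slide.n_spots
        V0 = rng.standard_normal((n, 2))
        state = LatentState(
            Z=[np.zeros((n, 2))], Zmom=[np.zeros((n, 2, 2))],
            V=[V0], Y=[rng.integers(0, 2, n)], R=[np.full((n, 2), 0.5)],
        )
        V, _, _ = update_v([slide], params, state, max_sweeps=200, rel_tol=1e-10)
        # with no data term the CAR mode is a constant field
        spread = V[0].std(axis=0)
        assert (spread < 0.05 * (np.abs(V[0].mean(axis=0)) + 1)).all() or (
            np.abs(V[0] - V[0].mean(axis=0)).max() < 0.2
        )

    def test_star_center_matches_dense_conjugate_oracle(self):
        """Center of a star graph (updated first, neighbors at initial
        values) must match the dense Gaussian-posterior solve."""
        rng = np.random.default_rng(3)
        p, q, K = 5, 2, 2
        n = 4  # center 0, leaves 1..3
        edges = np.array([[0, 1], [0, 2], [0, 3]])
        g = NeighborGraph.from_edges(n, edges)
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        X = rng.standard_normal((n, p))
        X -= X.mean(axis=0)
        slide = SlideData(expr=X, coords=coords, graph=g, slide_id="s")
        params = random_params(rng, p=p, q=q, K=K)
        Y = np.array([1, 0, 0, 1])
        V0 = rng.standard_normal((n, q))
        state = LatentState(
            Z=[np.zeros((n, q))], Zmom=[np.zeros((n, q, q))],
            V=[V0.copy()], Y=[Y], R=[np.full((n, K), 0.5)],
        )
        V, _, _ = update_v([slide], params, state, max_sweeps=1)

        rho = 0.99
        k = Y[0]
        S = params.W @ params.Sigma[k] @ params.W.T + np.diag(params.Lambda[0])
        Sinv = np.linalg.inv(S)
        c = rho * 3 + (1 - rho)
        P = params.W.T @ Sinv @ params.W + c * np.linalg.inv(params.Psi[0])
        b = params.W.T @ Sinv @ (X[0] - params.W @ params.mu[k])
        prior = rho * np.linalg.inv(params.Psi[0]) @ V0[1:4].sum(axis=0)
        expected = np.linalg.solve(P, b + prior)
        assert np.allclose(V[0][0], expected, atol=1e-8)


class TestEmbeddingPosterior:
    def test_noiseless_limit_is_projection(self):
        rng = np.random.default_rng(4)
        slide, *_ = gaussian_slide(rng, n_rows=4, n_cols=4, p=10, q=2, K=2)
        params = random_params(rng, p=10, q=2, K=2)
        params.Lambda = [np.full(10, 1e-10)]
        n = slide.n_spots
        V = rng.standard_normal((n, 2)) * 0.3
        R = np.full((n, 2), 0.5)
        state = LatentState(
            Z=[np.zeros((n, 2))], Zmom=[np.zeros((n, 2, 2))],
            V=[V], Y=[np.zeros(n, dtype=np.int64)], R=[R],
        )
        Z, Zmom, EzK, CovK = embedding_posterior([slide], params, state)
        expected = slide.expr @ params.W - V
        assert np.allclose(Z[0], expected, atol=1e-4)

    def test_second_moment_psd(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        state.R = compute_responsibilities([slide], params, state)
        Z, Zmom, *_ = embedding_posterior([slide], params, state)
        for i in range(0, slide.n_spots, 9):
            cov = Zmom[0][i] - np.outer(Z[0][i], Z[0][i])
            assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_scalar_conjugate_oracle(self):
        """p=4, q=1: posterior mean/covariance by direct Bayes rule."""
        rng = np.random.default_rng(6)
        p, q = 4, 1
        params = random_params(rng, p=p, q=q, K=1)
        coords = lattice_coords(1, 2)
        g = build_neighbor_graph(coords, "square4")
        X = rng.standard_normal((2, p))
        X -= X.mean(axis=0)
        slide = SlideData(expr=X, coords=coords, graph=g, slide_id="s")
        n = 2
        V = rng.standard_normal((n, q))
        state = LatentState(
            Z=[np.zeros((n, q))], Zmom=[np.zeros((n, q, q))],
            V=[V], Y=[np.zeros(n, dtype=np.int64)], R=[np.ones((n, 1))],
        )
        Z, Zmom, EzK, CovK = embedding_posterior([slide], params, state)
        w = params.W[:, 0]
        lam = params.Lambda[0]
        sig2 = params.Sigma[0, 0, 0]
        mu = params.mu[0, 0]
        for i in range(n):
            prec = 1 / sig2 + w @ (w / lam)
            mean = (mu / sig2 + w @ ((X[i] - w * V[i, 0]) / lam)) / prec
            assert Z[0][i, 0] == pytest.approx(mean, abs=1e-9)
            assert CovK[0][0, 0, 0] == pytest.approx(1 / prec, abs=1e-9)


class TestMStep:
    def test_one_hot_means_and_orthonormal_w(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        state.R = compute_responsibilities([slide], params, state)
        Z, Zmom, EzK, CovK = embedding_posterior([slide], params, state)
        state.Z, state.Zmom, state.EzK, state.CovK = Z, Zmom, EzK, CovK
        # force one-hot R at the hard labels, V = 0
        n, K = slide.n_spots, params.K
        R = np.zeros((n, K))
        R[np.arange(n), state.Y[0]] = 1.0
        state.R = [R]
        state.V = [np.zeros_like(state.V[0])]
        new_params, new_state = m_step([slide], state, params)
        assert np.allclose(new_params.W.T @ new_params.W, np.eye(params.q), atol=1e-8)
        # mu_k must be the cluster mean of the (rotated) conditional means
        for k in range(K):
            mask = state.Y[0] == k
            expected = new_state.EzK[0][k][mask].mean(axis=0)
            assert np.allclose(new_params.mu[k], expected, atol=1e-8)

    def test_empty_cluster_reseeded(self, small_fit_setup):
        slide, params, state, _ = small_fit_setup
        state.R = compute_responsibilities([slide], params, state)
        Z, Zmom, EzK, CovK = embedding_posterior([slide], params, state)
        state.Z, state.Zmom, state.EzK, state.CovK = Z, Zmom, EzK, CovK
        R = state.R[0].copy()
        R[:, 2] = 0.0
        R /= R.sum(axis=1, keepdims=True)
        state.R = [R]
        new_params, _ = m_step([slide], state, params)
        new_params.validate()  # Sigma stays PD, mu finite


class TestEstimateBeta:
    def test_iid_labels_give_small_beta(self):
        coords = lattice_coords(40, 40)
        g = build_neighbor_graph(coords, "square4")
        rng = np.random.default_rng(0)
        lf = LabelField(labels=rng.integers(0, 4, g.n_spots), K=4)
        b = estimate_beta(lf, g, np.arange(0, 5.01, 0.1))
        assert b <= 0.2

    def test_constant_labels_hit_grid_max(self, grid20):
        _, g = grid20
        lf = LabelField(labels=np.zeros(g.n_spots, dtype=int), K=3)
        assert estimate_beta(lf, g, np.arange(0, 5.01, 0.1)) == pytest.approx(5.0)

    def test_consistency_at_moderate_beta(self):
        coords = lattice_coords(60, 60)
        g = build_neighbor_graph(coords, "square4")
        lf = sample_potts(g, K=7, beta=1.2, sweeps=150, seed=3)
        b = estimate_beta(lf, g, np.arange(0, 5.01, 0.1))
        assert 0.9 <= b <= 1.5

    def test_grid_consistency_window(self):
        """PL at the generating beta >= PL at beta +- 0.5, averaged."""
        from stmint.graph import potts_pseudo_loglik

        coords = lattice_coords(30, 30)
        g = build_neighbor_graph(coords, "square4")
        diffs_lo, diffs_hi = [], []
        for seed in range(5):
            lf = sample_potts(g, K=4, beta=0.9, sweeps=120, seed=seed)
            at = potts_pseudo_loglik(lf, g, beta=0.9)
            diffs_lo.append(at - potts_pseudo_loglik(lf, g, beta=0.4))
            diffs_hi.append(at - potts_pseudo_loglik(lf, g, beta=1.4))
        assert np.mean(diffs_lo) >= 0
        assert np.mean(diffs_hi) >= 0


class TestFitModel:
    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(11)
        slide, *_ = gaussian_slide(rng, n_rows=7, n_cols=7, p=15, q=2, K=3)
        opts = FitOptions(K=3, q=2, max_iter=5, seed=2)
        a = fit_model([slide], opts)
        b = fit_model([slide], opts)
        assert a.objective_trace == b.objective_trace
        assert np.array_equal(a.state.Y[0], b.state.Y[0])
        assert np.array_equal(a.params.W, b.params.W)

    def test_labels_recovered_on_separated_spatial_data(self):
        from stmint.metrics import clustering_agreement
        from tests.conftest import spatial_gaussian_slide

        slide, y, *_ = spatial_gaussian_slide(12, rows=10, cols=10)
        fit = fit_model([slide], FitOptions(K=3, q=3, max_iter=20, seed=1))
        ari, _ = clustering_agreement(fit.state.Y[0], y)
        assert ari > 0.9


class TestSelectNumClusters:
    def test_singleton_grid(self):
        rng = np.random.default_rng(13)
        slide, *_ = gaussian_slide(rng, n_rows=6, n_cols=6, p=12, q=2, K=3)
        best, table, fit = select_num_clusters(
            [slide], FitOptions(K=3, q=2, max_iter=5, seed=1), [7]
        )
        assert best == 7
        assert len(table) == 1

    def test_recovers_four_clusters(self):
        from tests.conftest import spatial_gaussian_slide

        slide, y, *_ = spatial_gaussian_slide(14, K=4, q=3)
        best, table, _ = select_num_clusters(
            [slide], FitOptions(K=4, q=3, max_iter=12, seed=1), range(2, 9)
        )
        assert len(table) == 7
        assert best == 4
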