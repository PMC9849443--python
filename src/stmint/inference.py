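"""ICM-EM fitting of the multi-slide spatial factor model.

One outer iteration performs, in fixed order:

1. E-step responsibilities  R_rik  proportional to
   exp(beta_r * c_rik) * N(x_ri; W(mu_k + v_ri), W Sigma_k W^T + Lambda_r),
   where c_rik counts neighbors of spot i currently labeled k;
2. one sequential ICM sweep on the hard labels y (argmax of the same
   product, recomputing neighbor counts as labels change; ties toward the
   smallest k);
3. one sequential coordinate-ascent sweep on the slide-specific
   embeddings v (conditional Gaussian MAP, aligned embedding z
   marginalized out);
4. the embedding posterior (mean and second moment of z mixed over
   clusters);
5. a closed-form M-step for mu_k, Sigma_k, W (re-orthonormalized by SVD
   with the rotation propagated to all latent quantities), Lambda_r and
   Psi_r;
6. a pseudo-likelihood grid update of the Potts smoothing beta_r.

Hard labels drive the Potts/CAR couplings while soft responsibilities
drive the mixture moments; every update is closed-form and the whole loop
is deterministic given the seed.  All p-dimensional algebra goes through
the Woodbury identity.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, svd

from .graph import LabelField, icm_sweep, neighbor_counts, potts_pseudo_loglik
from .model import (
    LatentState,
    ModelParams,
    SlideData,
    WoodburyPieces,
    emission_logliks,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "initialize_fit",
    "compute_responsibilities",
    "icm_update_labels",
    "update_v",
    "embedding_posterior",
    "m_step",
    "estimate_beta",
    "fit_model",
    "select_num_clusters",
]

_LAMBDA_FLOOR = 1e-4
_SIGMA_FLOOR = 1e-6
_EMPTY_CLUSTER_TOL = 1e-8


def _default_beta_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)


@dataclass
class FitOptions:
    """Fitting controls; defaults follow the package's standard settings."""

    K: int = 7
    q: int = 10
    max_iter: int = 30
    tol: float = 1e-5
    beta_grid: np.ndarray = field(default_factory=_default_beta_grid)
    beta_init: float = 1.0
    seed: int = 1
    freeze: frozenset = frozenset()

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        if self.beta_grid.size and (
            self.beta_grid.min() < 0 or not np.all(np.isfinite(self.beta_grid))
        ):
            raise ValueError("beta_grid must lie in [0, beta_max]")
        self.freeze = frozenset(self.freeze)


@dataclass
class FitResult:
    """A fitted model: parameters, latent state, and diagnostics."""

    params: ModelParams
    state: LatentState
    objective_trace: list
    converged: bool
    emission_loglik: float = np.nan
    criterion: float | None = None
    runtime: float = np.nan

    @property
    def labels(self) -> list:
        return self.state.Y

    @property
    def embeddings(self) -> list:
        return self.state.Z


# ----------------------------------------------------------------------
# initialization


def initialize_fit(data: list[SlideData], opts: FitOptions):
    """SVD + k-means initialization, deterministic given the seed.

    W is the top-q right singular subspace of the row-concatenated
    expression; Z = X W per slide; labels from seeded k-means on pooled Z;
    cluster moments give mu/Sigma; per-gene residual variances give
    Lambda; Psi = I, beta = beta_init, V = 0.
    """
    from sklearn.cluster import KMeans
    from sklearn.utils.extmath import randomized_svd

    if not data:
        raise ValueError("need at least one slide")
    p = data[0].n_genes
    for s in data:
        if s.n_genes != p:
            raise ValueError("all slides must share the gene panel")
    n_total = sum(s.n_spots for s in data)
    if n_total < opts.K:
        raise ValueError(f"{n_total} pooled spots < K={opts.K}")

    X_cat = np.vstack([s.expr for s in data])
    _, _, Vt = randomized_svd(X_cat, n_components=opts.q, random_state=opts.seed)
    W = Vt.T
    # deterministic sign: largest-magnitude loading positive per column
    piv = np.argmax(np.abs(W), axis=0)
    W *= np.sign(W[piv, np.arange(opts.q)])

    Z = [s.expr @ W for s in data]
    Z_cat = X_cat @ W
    # k-means on variance-whitened scores: heteroscedastic embedding
    # dimensions otherwise dominate the Euclidean assignment
    km = KMeans(n_clusters=opts.K, n_init=10, random_state=opts.seed)
    y_cat = km.fit_predict(Z_cat / np.maximum(Z_cat.std(axis=0), 1e-12))

    q = opts.q
    mu = np.zeros((opts.K, q))
    Sigma = np.zeros((opts.K, q, q))
    for k in range(opts.K):
        mask = y_cat == k
        mu[k] = Z_cat[mask].mean(axis=0)
        if mask.sum() > q:
            Sigma[k] = np.cov(Z_cat[mask].T) + _SIGMA_FLOOR * np.eye(q)
        else:
            Sigma[k] = np.eye(q)
        Sigma[k] = _pd_floor(Sigma[k])

    Lambda = []
    for r, s in enumerate(data):
        resid = s.expr - Z[r] @ W.T
        Lambda.append(np.maximum(resid.var(axis=0), _LAMBDA_FLOOR))

    params = ModelParams(
        W=W,
        mu=mu,
        Sigma=Sigma,
        Lambda=Lambda,
        Psi=[np.eye(q) for _ in data],
        beta=[opts.beta_init for _ in data],
        slide_ids=[s.slide_id for s in data],
    )

    Y, R, V, Zmom = [], [], [], []
    offset = 0
    for s in data:
        n = s.n_spots
        y_r = y_cat[offset : offset + n].astype(np.int64)
        offset += n
        Y.append(y_r)
        one_hot = np.zeros((n, opts.K))
        one_hot[np.arange(n), y_r] = 1.0
        R.append(one_hot)
        V.append(np.zeros((n, q)))
    for z in Z:
        Zmom.append(np.einsum("ni,nj->nij", z, z))
    state = LatentState(Z=Z, Zmom=Zmom, V=V, Y=Y, R=R)
    state.EzK = None
    state.CovK = None
    return params, state


def _pd_floor(mat: np.ndarray, floor: float = _SIGMA_FLOOR) -> np.ndarray:
    """Symmetrize and clip eigenvalues from below."""
    mat = 0.5 * (mat + mat.T)
    w, U = np.linalg.eigh(mat)
    return (U * np.maximum(w, floor)) @ U.T


# ----------------------------------------------------------------------
# E-step pieces


def compute_responsibilities(data, params, state, emissions=None):
    """Responsibilities R_rik from Potts neighbor counts and emissions."""
    R = []
    for r, s in enumerate(data):
        em = (
            emissions[r]
            if emissions is not None
            else emission_logliks(s.expr, state.V[r], params, r)
        )
        c = neighbor_counts(s.graph, state.Y[r], params.K)
        logits = params.beta[r] * c + em
        logits -= logits.max(axis=1, keepdims=True)
        np.exp(logits, out=logits)
        logits /= logits.sum(axis=1, keepdims=True)
        R.append(logits)
    return R


def icm_update_labels(data, params, state, emissions=None):
    """One sequential ICM sweep per slide; returns new label arrays."""
    Y = []
    for r, s in enumerate(data):
        em = (
            emissions[r]
            if emissions is not None
            else emission_logliks(s.expr, state.V[r], params, r)
        )
        y = state.Y[r].copy()
        icm_sweep(s.graph, y, em, params.beta[r])
        Y.append(y)
    return Y


# propriety parameter of the CAR prior used during inference: the
# intrinsic CAR joint is improper, so the coordinate updates, the Psi
# estimator and the tracked objective all use the proper approximation
# with joint precision rho*(M - A) + (1-rho)*I (M = degree diagonal,
# A = adjacency), matching the simulator
CAR_RHO = 0.99


def update_v(data, params, state, max_sweeps: int = 10, rel_tol: float = 1e-3):
    """Conditional-MAP sweeps on the slide embeddings v.

    For a spot with hard label k and degree m, the conditional posterior
    of v under the (proper) CAR prior has precision
    W^T S_k^{-1} W + (rho*m + 1-rho) Psi^{-1} and mean
    P^{-1} (W^T S_k^{-1} (x - W mu_k) + rho Psi^{-1} sum_{neighbors} v),
    which for rho -> 1 is the intrinsic-CAR update (neighbor-average
    conditional mean, precision m Psi^{-1}).  Sequential site sweeps are
    repeated until the field changes by less than ``rel_tol`` (relative
    RMS) or ``max_sweeps`` is hit; the CAR field equilibrates by local
    diffusion, so a single sweep per outer iteration would leave a long
    drifting transient.  Isolated spots are set to the slide mean.

    Also accumulates, per slide, sum_i c_i P_i^{-1} (c_i = rho*m_i+1-rho;
    needed by the Psi update — estimating Psi from the MAP field alone
    collapses it, because a conditional-mode field is smoother than a
    draw from the same prior) and sum_i P_i^{-1} (needed by the W and
    Lambda moment updates).  Returns (V, Vcov, Vvar).
    """
    W = params.W
    q = params.q
    V_out = []
    Vcov_out = []
    Vvar_out = []
    for r, s in enumerate(data):
        pieces = WoodburyPieces(W, params.Lambda[r], params.Sigma)
        psi_chol = cho_factor(params.Psi[r], lower=True)
        psi_inv = cho_solve(psi_chol, np.eye(q))
        Y = state.Y[r]
        n = s.n_spots
        B = np.empty((n, q))
        A_k = {}
        for k in range(params.K):
            mask = Y == k
            if not mask.any():
                continue
            T_k = pieces.WtSinv(k)  # q x p
            A_k[k] = T_k @ W
            B[mask] = s.expr[mask] @ T_k.T - A_k[k] @ params.mu[k]
        deg = s.graph.degrees
        # cache (label, degree) -> conditional precision inverse
        P_inv: dict = {}
        V = state.V[r].copy()
        indptr, indices = s.graph.indptr, s.graph.indices
        active = np.flatnonzero(deg > 0)
        for sweep in range(max_sweeps):
            delta = 0.0
            for i in active:
                m = deg[i]
                k = Y[i]
                key = (k, m)
                if key not in P_inv:
                    c = CAR_RHO * m + (1.0 - CAR_RHO)
                    P_inv[key] = np.linalg.inv(A_k[k] + c * psi_inv)
                nbr_sum = V[indices[indptr[i] : indptr[i + 1]]].sum(axis=0)
                new = P_inv[key] @ (B[i] + CAR_RHO * (psi_inv @ nbr_sum))
                delta += float(np.sum((new - V[i]) ** 2))
                V[i] = new
            scale = float(np.sum(V[active] ** 2)) + 1e-12
            if delta < (rel_tol**2) * scale:
                break
        cov_sum = np.zeros((q, q))
        var_sum = np.zeros((q, q))
        for i in active:
            m = deg[i]
            c = CAR_RHO * m + (1.0 - CAR_RHO)
            pk = P_inv[(Y[i], m)]
            cov_sum += c * pk
            var_sum += pk
        iso = deg == 0
        if iso.any():
            V[iso] = V[~iso].mean(axis=0) if (~iso).any() else 0.0
        V_out.append(V)
        Vcov_out.append(cov_sum)
        Vvar_out.append(var_sum)
    return V_out, Vcov_out, Vvar_out


def embedding_posterior(data, params, state):
    """Posterior mean/second moment of the aligned embeddings z.

    Per cluster k, E[z | x, y=k] = mu_k + M_k^{-1} W^T Lambda^{-1}
    (x - W (mu_k + v)) with posterior covariance M_k^{-1}
    = (Sigma_k^{-1} + W^T Lambda^{-1} W)^{-1}; the mixture over k uses the
    responsibilities.  Also caches the per-cluster conditional means and
    covariances needed by the M-step.
    """
    W = params.W
    K, q = params.K, params.q
    Z_out, Zmom_out, EzK_out, CovK_out = [], [], [], []
    for r, s in enumerate(data):
        pieces = WoodburyPieces(W, params.Lambda[r], params.Sigma)
        A = s.expr - state.V[r] @ W.T
        n = s.n_spots
        EzK = np.empty((K, n, q))
        CovK = np.empty((K, q, q))
        for k in range(K):
            Minv = pieces.M_inv(k)
            CovK[k] = Minv
            gain = Minv @ pieces.WtLi  # q x p
            EzK[k] = params.mu[k] + (A - W @ params.mu[k]) @ gain.T
        R = state.R[r]
        Z = np.einsum("nk,knq->nq", R, EzK)
        Zmom = np.einsum("nk,knq,kns->nqs", R, EzK, EzK) + np.einsum(
            "nk,kqs->nqs", R, CovK
        )
        Z_out.append(Z)
        Zmom_out.append(Zmom)
        EzK_out.append(EzK)
        CovK_out.append(CovK)
    return Z_out, Zmom_out, EzK_out, CovK_out


# ----------------------------------------------------------------------
# M-step


def m_step(data, state, params):
    """Closed-form parameter updates from the current expected moments.

    Updates mu_k, Sigma_k (responsibility-weighted moments of the
    per-cluster embedding posterior, PD-floored), W (least squares on the
    expected second moments, re-orthonormalized by SVD with the rotation
    propagated to Z, V, mu, Sigma, Psi), Lambda_r (per-gene expected
    residual second moments, floored) and Psi_r (degree-weighted CAR
    pseudo-likelihood MLE over non-isolated spots).  beta_r is not
    touched here.  Returns (new_params, new_state).
    """
    K, q, p = params.K, params.q, params.p
    M = len(data)
    EzK, CovK = state.EzK, state.CovK
    if EzK is None:
        raise ValueError("run embedding_posterior before m_step")

    # mixture moments pooled across slides
    Nk = np.zeros(K)
    mu = np.zeros((K, q))
    for r in range(M):
        R = state.R[r]
        Nk += R.sum(axis=0)
        mu += np.einsum("nk,knq->kq", R, EzK[r])
    empty = Nk < _EMPTY_CLUSTER_TOL
    mu[~empty] /= Nk[~empty, None]

    Sigma = np.zeros((K, q, q))
    for r in range(M):
        R = state.R[r]
        D = EzK[r] - mu[:, None, :]
        Sigma += np.einsum("nk,knq,kns->kqs", R, D, D)
        Sigma += R.sum(axis=0)[:, None, None] * CovK[r]
    Sigma[~empty] /= Nk[~empty, None, None]

    if empty.any():
        # re-seed empty clusters at the spots with lowest max-responsibility
        conf = np.concatenate([state.R[r].max(axis=1) for r in range(M)])
        Z_cat = np.vstack(state.Z)
        order = np.argsort(conf)
        for j, k in enumerate(np.flatnonzero(empty)):
            mu[k] = Z_cat[order[j]]
            Sigma[k] = np.eye(q)
    for k in range(K):
        Sigma[k] = _pd_floor(Sigma[k])

    # loading matrix from least squares on expected moments
    A = np.zeros((p, q))
    B = np.zeros((q, q))
    for r, s in enumerate(data):
        U_mean = state.Z[r] + state.V[r]
        A += s.expr.T @ U_mean
        B += state.Zmom[r].sum(axis=0)
        cross = state.Z[r].T @ state.V[r]
        B += cross + cross.T + state.V[r].T @ state.V[r]
        if state.Vvar is not None:
            B += state.Vvar[r]
    W_ls = np.linalg.solve(B.T, A.T).T  # A @ B^{-1}
    Uw, sw, Vtw = svd(W_ls, full_matrices=False)
    W = Uw
    T = sw[:, None] * Vtw  # W @ T == W_ls

    # propagate the rotation to every latent quantity
    mu = mu @ T.T
    Sigma = np.einsum("ab,kbc,dc->kad", T, Sigma, T)
    for k in range(K):
        Sigma[k] = _pd_floor(Sigma[k])
    Z_new = [z @ T.T for z in state.Z]
    V_new = [v @ T.T for v in state.V]
    Zmom_new = [np.einsum("ab,nbc,dc->nad", T, zm, T) for zm in state.Zmom]
    EzK_new = [ez @ T.T for ez in EzK]
    CovK_new = [np.einsum("ab,kbc,dc->kad", T, ck, T) for ck in CovK]
    Vcov_new = (
        [T @ vc @ T.T for vc in state.Vcov] if state.Vcov is not None else None
    )
    Vvar_new = (
        [T @ vv @ T.T for vv in state.Vvar] if state.Vvar is not None else None
    )

    Lambda, Psi = [], []
    for r, s in enumerate(data):
        n = s.n_spots
        U_mean = Z_new[r] + V_new[r]
        Suu = Zmom_new[r].sum(axis=0)
        cross = Z_new[r].T @ V_new[r]
        Suu = Suu + cross + cross.T + V_new[r].T @ V_new[r]
        if Vvar_new is not None:
            Suu = Suu + Vvar_new[r]
        c1 = np.einsum("np,np->p", s.expr, s.expr)
        c2 = np.einsum("np,np->p", s.expr, U_mean @ W.T)
        c3 = np.einsum("pa,ab,pb->p", W, Suu, W)
        Lambda.append(np.maximum((c1 - 2.0 * c2 + c3) / n, _LAMBDA_FLOOR))

        V = V_new[r]
        Qmat = _car_precision(s.graph)
        S_psi = V.T @ (Qmat @ V)
        if Vcov_new is not None:
            S_psi = S_psi + Vcov_new[r]
        Psi.append(_pd_floor(S_psi / s.n_spots))

    new_params = ModelParams(
        W=W, mu=mu, Sigma=Sigma, Lambda=Lambda, Psi=Psi,
        beta=list(params.beta), slide_ids=params.slide_ids,
    )
    new_state = LatentState(Z=Z_new, Zmom=Zmom_new, V=V_new, Y=state.Y, R=state.R)
    new_state.EzK = EzK_new
    new_state.CovK = CovK_new
    new_state.Vcov = Vcov_new
    new_state.Vvar = Vvar_new
    return new_params, new_state


def _adjacency(graph) -> sp.csr_matrix:
    n = graph.n_spots
    return sp.csr_matrix(
        (np.ones(graph.indices.size), graph.indices, graph.indptr), shape=(n, n)
    )


def _car_precision(graph) -> sp.csr_matrix:
    """Proper-CAR among-spot precision rho*(M - A) + (1-rho)*I."""
    adj = _adjacency(graph)
    deg = graph.degrees.astype(float)
    return sp.diags(CAR_RHO * deg + (1.0 - CAR_RHO)) - CAR_RHO * adj


def estimate_beta(field: LabelField, graph, grid) -> float:
    """Pseudo-likelihood grid search for the Potts smoothing parameter.

    Returns the grid value maximizing sum_i log P(y_i | y_Ni; beta); ties
    break toward the smallest beta.
    """
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("beta grid must be nonempty")
    c = neighbor_counts(graph, field.labels, field.K)  # n x K
    own = c[np.arange(len(field.labels)), field.labels]
    best_beta, best_val = grid[0], -np.inf
    for b in grid:
        val = float(
            (b * own - _logsumexp_rows(b * c)).sum()
        )
        if val > best_val + 1e-12:
            best_val = val
            best_beta = b
    return float(best_beta)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=1, keepdims=True))).ravel()


# ----------------------------------------------------------------------
# objective & outer loop


def marginal_site_loglik(data, params, state) -> list:
    """Per-spot log-likelihood with z AND v marginalized out sitewise.

    Conditioning on the neighbors' current v field, spot i with degree m
    has v_i ~ N(rho/c_i * sum_neighbors v, Psi / c_i) with
    c_i = rho*m + 1-rho under the proper CAR, hence

        x_i | y_i = k  ~  N(W(mu_k + mu_v,i), W(Sigma_k + Psi/c_i)W^T + Lambda_r).

    Unlike any plug-in of v itself, this quantity is invariant under the
    joint reparameterization of the latent space performed by the M-step,
    which makes it the natural convergence monitor.  Returns one n x K
    array per slide.
    """
    out = []
    for r, s in enumerate(data):
        n, p = s.expr.shape
        K = params.K
        deg = s.graph.degrees
        c = CAR_RHO * deg + (1.0 - CAR_RHO)
        adj = _adjacency(s.graph)
        prior_mean = (CAR_RHO / c)[:, None] * (adj @ state.V[r])
        A = s.expr - prior_mean @ params.W.T
        em = np.empty((n, K))
        for m in np.unique(deg):
            mask = deg == m
            cm = CAR_RHO * m + (1.0 - CAR_RHO)
            Sig_eff = params.Sigma + params.Psi[r][None] / cm
            pieces = WoodburyPieces(params.W, params.Lambda[r], Sig_eff)
            for k in range(K):
                U = A[mask] - params.W @ params.mu[k]
                quad = pieces.quad_forms(U, k)
                em[mask, k] = -0.5 * (
                    p * np.log(2 * np.pi) + pieces.logdet_S[k] + quad
                )
        out.append(em)
    return out


def _trace_objective(data, params, state) -> tuple[float, float]:
    """(objective, marginal-likelihood part).

    The sitewise pseudo-marginal log-likelihood at the hard labels (z and
    v integrated out given the neighbors' field) plus the Potts
    pseudo-log-likelihood of the labels.
    """
    emis = 0.0
    rest = 0.0
    ems = marginal_site_loglik(data, params, state)
    for r, s in enumerate(data):
        emis += float(ems[r][np.arange(s.n_spots), state.Y[r]].sum())
        lf = LabelField(labels=state.Y[r], K=params.K, beta=params.beta[r])
        rest += potts_pseudo_loglik(lf, s.graph)
    return emis + rest, emis


def _warmup_v(data, params, state, rounds: int = 5):
    """Equilibrate the slide-embedding field at the initial parameters.

    Alternates conditional-mode sweeps of v with the matching Psi update
    before the first recorded iteration: starting the outer loop from a
    cold field (v = 0, Psi = I) otherwise produces a long transient in
    which the field and its prior scale co-inflate.
    """
    for _ in range(rounds):
        state.V, state.Vcov, state.Vvar = update_v(data, params, state)
        for r, s in enumerate(data):
            S = state.V[r].T @ (_car_precision(s.graph) @ state.V[r])
            S = S + state.Vcov[r]
            params.Psi[r] = _pd_floor(S / s.n_spots)
    return params, state


def fit_model(data: list[SlideData], opts: FitOptions) -> FitResult:
    """Run the ICM-EM loop until the objective stabilizes.

    Iterates responsibilities -> ICM labels -> v sweep -> embedding
    posterior -> M-step -> beta grid update, tracking a pseudo
    log-posterior (emission at the hard labels + Potts and CAR
    pseudo-log-likelihoods).  Stops when its relative change falls below
    ``opts.tol`` or after ``opts.max_iter`` iterations.
    """
    t0 = time.perf_counter()
    params, state = initialize_fit(data, opts)
    freeze = opts.freeze
    if "V" not in freeze and "Psi" not in freeze:
        params, state = _warmup_v(data, params, state)
    trace: list[float] = []
    converged = False
    emis_part = np.nan

    for it in range(opts.max_iter):
        emissions = [
            emission_logliks(s.expr, state.V[r], params, r)
            for r, s in enumerate(data)
        ]
        for r, em in enumerate(emissions):
            if not np.all(np.isfinite(em)):
                raise RuntimeError(
                    f"non-finite emission log-likelihood in slide "
                    f"{data[r].slide_id!r} at iteration {it}"
                )
        state.R = compute_responsibilities(data, params, state, emissions)
        if "labels" not in freeze:
            state.Y = icm_update_labels(data, params, state, emissions)
        if "V" not in freeze:
            state.V, state.Vcov, state.Vvar = update_v(data, params, state)
            # refresh the E-step so the M-step moments match the new v field
            state.R = compute_responsibilities(data, params, state)
        Z, Zmom, EzK, CovK = embedding_posterior(data, params, state)
        state.Z, state.Zmom, state.EzK, state.CovK = Z, Zmom, EzK, CovK
        params, state = m_step(data, state, params)
        if freeze:
            params = _restore_frozen(params, data, opts, freeze)
        if "beta" not in freeze:
            params.beta = [
                estimate_beta(
                    LabelField(labels=state.Y[r], K=params.K, beta=params.beta[r]),
                    s.graph,
                    opts.beta_grid,
                )
                for r, s in enumerate(data)
            ]
        obj, emis_part = _trace_objective(data, params, state)
        if not np.isfinite(obj):
            raise RuntimeError(f"non-finite objective at iteration {it}")
        trace.append(obj)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if abs(trace[-1] - trace[-2]) < opts.tol * denom:
                converged = True
                break

    return FitResult(
        params=params,
        state=state,
        objective_trace=trace,
        converged=converged,
        emission_loglik=float(emis_part),
        runtime=time.perf_counter() - t0,
    )


def _restore_frozen(params, data, opts, freeze):
    """Reset frozen parameter blocks to their initial values."""
    q = params.q
    if "Psi" in freeze:
        params.Psi = [np.eye(q) for _ in data]
    if "beta" in freeze:
        params.beta = [opts.beta_init for _ in data]
    return params


def select_num_clusters(data, opts: FitOptions, K_grid, penalty_const=None):
    """Fit every K in the grid and pick the MBIC-style minimizer.

    criterion(K) = -2 * emission log-likelihood
                   + df(K) * log(n_total) * c,
    df(K) = K q + K q (q+1)/2 + p q + sum_r p, with
    c = log(log(p + n_total)) by default.  Returns (best_K, table) where
    table is a list of dicts with K, criterion and convergence flag.
    """
    K_grid = sorted(int(k) for k in K_grid)
    if not K_grid:
        raise ValueError("K grid must be nonempty")
    n_total = sum(s.n_spots for s in data)
    p = data[0].n_genes
    q = opts.q
    M = len(data)
    c = penalty_const if penalty_const is not None else np.log(np.log(p + n_total))

    table = []
    fits = {}
    for K in K_grid:
        o = FitOptions(
            K=K, q=opts.q, max_iter=opts.max_iter, tol=opts.tol,
            beta_grid=opts.beta_grid, beta_init=opts.beta_init,
            seed=opts.seed, freeze=opts.freeze,
        )
        fit = fit_model(data, o)
        df = K * q + K * q * (q + 1) / 2 + p * q + M * p
        crit = -2.0 * fit.emission_loglik + df * np.log(n_total) * c
        fit.criterion = float(crit)
        fits[K] = fit
        table.append(
            {"K": K, "criterion": float(crit), "converged": fit.converged}
        )
    best = min(table, key=lambda row: row["criterion"])["K"]
    return best, table, fits[best]
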