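"""Generative model for multi-slide spatial transcriptomics integration.

The model ties together, for each slide r and spot i with centered
normalized expression x_ri (p genes):

* a probabilistic factor layer  x_ri = W (z_ri + v_ri) + eps_ri,
  eps_ri ~ N(0, Lambda_r) with Lambda_r diagonal and W a p x q loading
  matrix with orthonormal columns shared across slides;
* a Gaussian mixture layer on the aligned embeddings,
  z_ri | y_ri = k ~ N(mu_k, Sigma_k);
* a Potts Markov random field on the labels y_ri with slide smoothing
  parameter beta_r;
* an intrinsic conditional autoregressive (CAR) field on the
  slide-specific embeddings, v_ri | v_(-i) ~ N(mean of neighbor v's,
  Psi_r / m_ri), whose non-zero conditional mean is what lets v absorb
  slide-level (batch and other non-cellular) effects after projecting
  them onto the column space of W.  No per-slide loading or batch factor
  is ever estimated; the projection is implicit in v.

This module houses the containers and the component densities; the
fitting algorithm lives in :mod:`stmint.inference`.  All p-dimensional
Gaussian evaluations go through the Woodbury identity so no p x p matrix
is ever formed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .graph import LabelField, NeighborGraph

__all__ = [
    "SlideData",
    "ModelParams",
    "LatentState",
    "marginal_label_loglik",
    "emission_logliks",
    "potts_energy",
    "car_conditional",
    "complete_objective",
]

_CENTER_TOL = 1e-8


@dataclass
class SlideData:
    """One slide: centered normalized expression, coordinates, graph."""

    expr: np.ndarray  # spots x genes, per-gene centered within slide
    coords: np.ndarray  # spots x 2
    graph: NeighborGraph
    slide_id: str = "slide"
    barcodes: np.ndarray | None = None
    gene_ids: np.ndarray | None = None

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.expr)):
            raise ValueError(f"{self.slide_id}: expression contains non-finite values")
        if self.expr.shape[0] != self.graph.n_spots:
            raise ValueError(f"{self.slide_id}: expression rows != graph spots")
        col_means = self.expr.mean(axis=0)
        if np.abs(col_means).max(initial=0.0) > _CENTER_TOL:
            raise ValueError(
                f"{self.slide_id}: expression not per-gene centered "
                f"(max |mean| = {np.abs(col_means).max():.3g})"
            )


@dataclass
class ModelParams:
    """Model parameters: shared (W, mu, Sigma) and per-slide (Lambda, Psi, beta)."""

    W: np.ndarray  # p x q, orthonormal columns
    mu: np.ndarray  # K x q
    Sigma: np.ndarray  # K x q x q, each SPD
    Lambda: list[np.ndarray]  # per slide, length-p positive diagonals
    Psi: list[np.ndarray]  # per slide, q x q SPD
    beta: list[float]  # per slide, >= 0
    slide_ids: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    @property
    def n_slides(self) -> int:
        return len(self.Lambda)

    def validate(self) -> None:
        q = self.q
        gram = self.W.T @ self.W
        if np.abs(gram - np.eye(q)).max() > 1e-6:
            raise ValueError("W does not have orthonormal columns")
        for lam in self.Lambda:
            if (lam <= 0).any():
                raise ValueError("Lambda entries must be positive")
        for k in range(self.K):
            _assert_spd(self.Sigma[k], f"Sigma[{k}]")
        for r, psi in enumerate(self.Psi):
            _assert_spd(psi, f"Psi[{r}]")
        if any(b < 0 for b in self.beta):
            raise ValueError("beta must be nonnegative")

    def save(self, path) -> None:
        """Write all parameters into one HDF5 container."""
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("mu", data=self.mu)
            f.create_dataset("Sigma", data=self.Sigma)
            f.create_dataset("beta", data=np.asarray(self.beta))
            for r, sid in enumerate(self._ids()):
                f.create_dataset(f"Lambda/{sid}", data=self.Lambda[r])
                f.create_dataset(f"Psi/{sid}", data=self.Psi[r])
            f.attrs["meta"] = json.dumps(
                {
                    "K": int(self.K),
                    "q": int(self.q),
                    "p": int(self.p),
                    "slide_ids": list(self._ids()),
                    "version": 1,
                }
            )

    @classmethod
    def load(cls, path) -> "ModelParams":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            sids = meta["slide_ids"]
            return cls(
                W=f["W"][()],
                mu=f["mu"][()],
                Sigma=f["Sigma"][()],
                Lambda=[f[f"Lambda/{s}"][()] for s in sids],
                Psi=[f[f"Psi/{s}"][()] for s in sids],
                beta=[float(b) for b in f["beta"][()]],
                slide_ids=sids,
            )

    def _ids(self) -> list[str]:
        if self.slide_ids:
            return self.slide_ids
        return [f"slide{r}" for r in range(self.n_slides)]


@dataclass
class LatentState:
    """Per-slide latent quantities of a (partially) fitted model."""

    Z: list[np.ndarray]  # aligned embedding posterior means, n_r x q
    Zmom: list[np.ndarray]  # posterior second moments E[z z^T], n_r x q x q
    V: list[np.ndarray]  # slide-specific embeddings (MAP), n_r x q
    Y: list[np.ndarray]  # hard labels, 0-based, n_r
    R: list[np.ndarray]  # responsibilities, n_r x K
    # per-cluster posterior caches filled by the E-step (optional)
    EzK: list | None = None
    CovK: list | None = None
    # per-slide sum of m_i * Cov(v_i | rest), filled by the v sweep
    Vcov: list | None = None
    # per-slide sum of Cov(v_i | rest) (unweighted), for the W/Lambda moments
    Vvar: list | None = None

    def validate(self) -> None:
        for r, resp in enumerate(self.R):
            if (resp < -1e-12).any():
                raise ValueError(f"slide {r}: negative responsibilities")
            if np.abs(resp.sum(axis=1) - 1.0).max() > 1e-10:
                raise ValueError(f"slide {r}: responsibility rows do not sum to 1")


def _assert_spd(mat: np.ndarray, name: str) -> None:
    if np.abs(mat - mat.T).max() > 1e-8:
        raise ValueError(f"{name} is not symmetric")
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


class WoodburyPieces:
    """Cached factorizations for S_k = W Sigma_k W^T + Lambda_r.

    Provides the quantities needed by every density/update at O(p q^2)
    cost: the q x q capacitance M_k = Sigma_k^{-1} + W^T Lambda^{-1} W,
    its Cholesky factor, and log|S_k| via the determinant lemma.
    """

    def __init__(self, W: np.ndarray, Lambda: np.ndarray, Sigma: np.ndarray):
        self.W = W
        self.lam_inv = 1.0 / Lambda
        self.WtLi = W.T * self.lam_inv  # q x p
        self.G = self.WtLi @ W  # q x q
        K = Sigma.shape[0]
        q = W.shape[1]
        self.M_chol = []
        self.logdet_S = np.empty(K)
        sum_log_lam = float(np.log(Lambda).sum())
        for k in range(K):
            _assert_spd(Sigma[k], f"Sigma[{k}]")
            sig_chol = cho_factor(Sigma[k], lower=True)
            sig_inv = cho_solve(sig_chol, np.eye(q))
            M = sig_inv + self.G
            c = cho_factor(M, lower=True)
            self.M_chol.append(c)
            logdet_sig = 2.0 * np.log(np.diag(sig_chol[0])).sum()
            logdet_M = 2.0 * np.log(np.diag(c[0])).sum()
            self.logdet_S[k] = logdet_M + logdet_sig + sum_log_lam

    def quad_forms(self, U: np.ndarray, k: int) -> np.ndarray:
        """Row-wise u^T S_k^{-1} u for U of shape (n, p)."""
        t = U @ self.WtLi.T  # n x q
        solved = cho_solve(self.M_chol[k], t.T).T
        return np.einsum("np,np->n", U * self.lam_inv, U) - np.einsum(
            "nq,nq->n", t, solved
        )

    def WtSinv(self, k: int) -> np.ndarray:
        """W^T S_k^{-1}, a q x p matrix."""
        return self.WtLi - self.G @ cho_solve(self.M_chol[k], self.WtLi)

    def M_inv(self, k: int) -> np.ndarray:
        q = self.G.shape[0]
        return cho_solve(self.M_chol[k], np.eye(q))


def emission_logliks(
    X: np.ndarray, V: np.ndarray, params: ModelParams, slide: int
) -> np.ndarray:
    """n x K matrix of log N(x_i; W(mu_k + v_i), W Sigma_k W^T + Lambda_r).

    The aligned embedding z is marginalized out.  Computed through the
    Woodbury identity in O(n p q + p q^2) per cluster.
    """
    W = params.W
    pieces = WoodburyPieces(W, params.Lambda[slide], params.Sigma)
    n, p = X.shape
    K = params.K
    A = X - V @ W.T
    out = np.empty((n, K))
    for k in range(K):
        U = A - W @ params.mu[k]
        quad = pieces.quad_forms(U, k)
        out[:, k] = -0.5 * (p * np.log(2 * np.pi) + pieces.logdet_S[k] + quad)
    return out


def marginal_label_loglik(
    x: np.ndarray, k: int, v: np.ndarray, params: ModelParams, slide: int
) -> float:
    """log N(x; W(mu_k + v), W Sigma_k W^T + Lambda_r) for one spot."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return float(emission_logliks(x, v, params, slide)[0, k])


def potts_energy(field: LabelField, graph: NeighborGraph) -> float:
    """Unnormalized Potts log-probability -(beta/2) sum_i sum_{i' in N_i} (1 - delta).

    Equals -beta times the number of discordant undirected neighbor pairs.
    """
    if field.labels.shape[0] != graph.n_spots:
        raise ValueError("label field and graph sizes disagree")
    edges = graph.edge_array()
    if edges.size == 0:
        return 0.0
    discordant = int((field.labels[edges[:, 0]] != field.labels[edges[:, 1]]).sum())
    return -field.beta * discordant


def car_conditional(v_neighbors, Psi: np.ndarray):
    """Intrinsic CAR full conditional: (neighbor mean, Psi / m)."""
    arr = np.asarray(v_neighbors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    m = arr.shape[0]
    if m == 0:
        raise ValueError("intrinsic CAR undefined for isolated spot")
    return arr.mean(axis=0), Psi / m


def _gauss_loglik_diag(U: np.ndarray, lam: np.ndarray) -> float:
    """sum_i log N(u_i; 0, diag(lam)) for U of shape (n, p)."""
    n, p = U.shape
    quad = float(np.einsum("np,np->", U / lam, U))
    return -0.5 * (n * (p * np.log(2 * np.pi) + float(np.log(lam).sum())) + quad)


def complete_objective(
    data: list[SlideData], params: ModelParams, state: LatentState
) -> float:
    """Pseudo complete-data log-posterior with plug-in latent values.

    Sums, over slides and spots, the factor-layer Gaussian with z at its
    posterior mean, the mixture-layer Gaussian at the hard label, and the
    CAR full-conditional Gaussian for v (isolated spots contribute no CAR
    term), plus the unnormalized Potts energy of each slide's labels.
    """
    total = 0.0
    q = params.q
    for r, slide in enumerate(data):
        Z, V, Y = state.Z[r], state.V[r], state.Y[r]
        lam = params.Lambda[r]
        resid = slide.expr - (Z + V) @ params.W.T
        total += _gauss_loglik_diag(resid, lam)
        # mixture layer at the hard label
        for k in range(params.K):
            mask = Y == k
            if not mask.any():
                continue
            D = Z[mask] - params.mu[k]
            chol = cho_factor(params.Sigma[k], lower=True)
            solved = cho_solve(chol, D.T).T
            logdet = 2.0 * np.log(np.diag(chol[0])).sum()
            quad = float(np.einsum("nq,nq->", D, solved))
            total += -0.5 * (
                mask.sum() * (q * np.log(2 * np.pi) + logdet) + quad
            )
        # CAR full conditionals for non-isolated spots
        deg = slide.graph.degrees
        psi_chol = cho_factor(params.Psi[r], lower=True)
        logdet_psi = 2.0 * np.log(np.diag(psi_chol[0])).sum()
        nbrs = slide.graph
        for i in np.flatnonzero(deg > 0):
            neigh = nbrs.indices[nbrs.indptr[i] : nbrs.indptr[i + 1]]
            m = len(neigh)
            d = V[i] - V[neigh].mean(axis=0)
            quad = m * float(d @ cho_solve(psi_chol, d))
            total += -0.5 * (
                q * np.log(2 * np.pi) + logdet_psi - q * np.log(m) + quad
            )
        total += potts_energy(
            LabelField(labels=Y, K=params.K, beta=params.beta[r]), slide.graph
        )
    return float(total)
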