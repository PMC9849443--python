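"""Self-contained EM for a mixture of factor analyzers.

Independent oracle used by the acceptance suite: classic alternating EM
(per-component loadings and means, shared diagonal noise, free mixing
weights) with dense p x p covariances — deliberately sharing no code
with the package's Woodbury-based implementation.
"""

import numpy as np
from scipy.stats import multivariate_normal


def mfa_loglik(X, pi, means, loadings, psi):
    n, p = X.shape
    K = len(pi)
    comp = np.empty((n, K))
    for k in range(K):
        cov = loadings[k] @ loadings[k].T + np.diag(psi)
        comp[:, k] = np.log(pi[k]) + multivariate_normal.logpdf(
            X, mean=means[k], cov=cov
        )
    m = comp.max(axis=1, keepdims=True)
    return float((m + np.log(np.exp(comp - m).sum(axis=1, keepdims=True))).sum())


def fit_mfa(X, K, q, n_iter=200, seed=0, tol=1e-8):
    """Returns (final log-likelihood, responsibilities)."""
    from sklearn.cluster import KMeans

    n, p = X.shape
    rng = np.random.default_rng(seed)
    labels = KMeans(K, n_init=10, random_state=seed).fit_predict(X)
    pi = np.bincount(labels, minlength=K) / n
    means = np.stack([X[labels == k].mean(axis=0) for k in range(K)])
    loadings = [rng.standard_normal((p, q)) * 0.1 for k in range(K)]
    psi = X.var(axis=0)

    prev = -np.inf
    for _ in range(n_iter):
        # E-step
        comp = np.empty((n, K))
        post_z = []
        post_cov = []
        for k in range(K):
            L = loadings[k]
            cov = L @ L.T + np.diag(psi)
            comp[:, k] = np.log(pi[k]) + multivariate_normal.logpdf(
                X, mean=means[k], cov=cov
            )
            G = np.linalg.solve(cov, L).T  # q x p, = L^T cov^{-1}
            post_z.append((X - means[k]) @ G.T)  # n x q
            post_cov.append(np.eye(q) - G @ L)
        m = comp.max(axis=1, keepdims=True)
        R = np.exp(comp - m)
        R /= R.sum(axis=1, keepdims=True)
        ll = float((m + np.log(np.exp(comp - m).sum(axis=1, keepdims=True))).sum())

        # M-step
        Nk = R.sum(axis=0) + 1e-12
        pi = Nk / n
        psi_acc = np.zeros(p)
        for k in range(K):
            w = R[:, k]
            Ez = post_z[k]
            # joint regression of x on [z, 1] weighted by responsibilities
            Ezz = post_cov[k] * Nk[k] + (Ez * w[:, None]).T @ Ez
            B = np.zeros((q + 1, q + 1))
            B[:q, :q] = Ezz
            B[:q, q] = (Ez * w[:, None]).sum(axis=0)
            B[q, :q] = B[:q, q]
            B[q, q] = Nk[k]
            A = np.column_stack([(X * w[:, None]).T @ Ez, (X * w[:, None]).sum(axis=0)])
            sol = np.linalg.solve(B.T, A.T).T  # p x (q+1)
            loadings[k] = sol[:, :q]
            means[k] = sol[:, q]
            resid = X - means[k] - Ez @ loadings[k].T
            psi_acc += (w[:, None] * resid**2).sum(axis=0) + np.einsum(
                "pa,ab,pb->p", loadings[k], post_cov[k] * Nk[k], loadings[k]
            )
        psi = np.maximum(psi_acc / n, 1e-6)

        if abs(ll - prev) < tol * abs(prev):
            break
        prev = ll
    return mfa_loglik(X, pi, means, loadings, psi), R
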