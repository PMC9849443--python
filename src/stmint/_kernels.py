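"""Numba kernels for the discrete Markov random field operations.

All kernels take the neighbor graph in flattened CSR form (``indptr``,
``indices``) so that the hot loops are free of Python objects.  Randomness
is injected as pre-drawn uniform variates, which keeps the kernels purely
deterministic functions of their inputs.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _site_counts(indptr, indices, labels, i, K):
    counts = np.zeros(K, dtype=np.float64)
    for jj in range(indptr[i], indptr[i + 1]):
        counts[labels[indices[jj]]] += 1.0
    return counts


@njit(cache=True)
def potts_gibbs_sweeps(indptr, indices, labels, K, beta, uniforms):
    """Sequential single-site Gibbs sweeps for a K-state Potts field.

    ``uniforms`` has shape (sweeps, n); ``labels`` is updated in place.
    The site conditional is P(y_i = k) proportional to exp(beta * c_ik)
    with c_ik the number of neighbors of i currently carrying label k.
    """
    n = labels.shape[0]
    sweeps = uniforms.shape[0]
    probs = np.empty(K, dtype=np.float64)
    for s in range(sweeps):
        for i in range(n):
            counts = _site_counts(indptr, indices, labels, i, K)
            m = counts[0]
            for k in range(1, K):
                if counts[k] > m:
                    m = counts[k]
            tot = 0.0
            for k in range(K):
                probs[k] = np.exp(beta * (counts[k] - m))
                tot += probs[k]
            u = uniforms[s, i] * tot
            acc = 0.0
            new = K - 1
            for k in range(K):
                acc += probs[k]
                if u <= acc:
                    new = k
                    break
            labels[i] = new


@njit(cache=True)
def potts_pseudo_loglik_kernel(indptr, indices, labels, K, beta):
    """Sum over sites of log P(y_i | y_neighbors; beta)."""
    n = labels.shape[0]
    total = 0.0
    for i in range(n):
        counts = _site_counts(indptr, indices, labels, i, K)
        m = counts[0]
        for k in range(1, K):
            if counts[k] > m:
                m = counts[k]
        denom = 0.0
        for k in range(K):
            denom += np.exp(beta * (counts[k] - m))
        total += beta * (counts[labels[i]] - m) - np.log(denom)
    return total


@njit(cache=True)
def icm_label_sweep(indptr, indices, labels, emission, beta):
    """One sequential ICM sweep: y_i <- argmax_k [beta*c_ik + emission_ik].

    Neighbor counts are recomputed as labels change within the sweep.
    Ties break toward the smallest k. Returns the number of sites changed.
    """
    n, K = emission.shape
    changed = 0
    for i in range(n):
        best_k = 0
        best_val = -np.inf
        counts = _site_counts(indptr, indices, labels, i, K)
        for k in range(K):
            val = beta * counts[k] + emission[i, k]
            if val > best_val:
                best_val = val
                best_k = k
        if best_k != labels[i]:
            labels[i] = best_k
            changed += 1
    return changed


@njit(cache=True)
def neighbor_label_counts(indptr, indices, labels, K):
    """n x K matrix of neighbor label counts c_ik."""
    n = labels.shape[0]
    out = np.zeros((n, K), dtype=np.float64)
    for i in range(n):
        for jj in range(indptr[i], indptr[i + 1]):
            out[i, labels[indices[jj]]] += 1.0
    return out
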