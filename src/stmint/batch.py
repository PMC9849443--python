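"""Recovery of batch-corrected expression via negative-control regression.

Housekeeping genes are assumed untouched by the biology of interest, so
the leading principal components of their expression estimate the
unwanted (batch/technical) variation h.  With the model's posterior
cluster probabilities r-hat spanning the biological variation between
cell/domain types, each gene is regressed as

    x = alpha r-hat + gamma h + (condition covariates) + eps

without an intercept (the r-hat block rows sum to 1 and already span the
constant), and the corrected expression is x - gamma-hat h.  Condition
covariates, when supplied, are retained in the corrected matrix unless
explicitly listed for removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RemovalDesign", "housekeeping_pcs", "remove_unwanted_variation"]


@dataclass
class RemovalDesign:
    """Design for the unwanted-variation regression."""

    H: np.ndarray  # spots x (<=10) unwanted-variation covariates
    Rhat: np.ndarray  # spots x K responsibilities (rows sum to 1)
    condition: np.ndarray | None = None  # optional spots x c covariates

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if self.H.shape[0] == 1 and self.Rhat.shape[0] != 1:
            self.H = self.H.T
        self.Rhat = np.asarray(self.Rhat, dtype=float)
        if np.abs(self.Rhat.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("Rhat rows must sum to 1")
        if self.H.shape[0] != self.Rhat.shape[0]:
            raise ValueError("H and Rhat row counts disagree")


def housekeeping_pcs(expr, n_pcs: int = 10) -> np.ndarray:
    """Principal-component scores of housekeeping-gene expression.

    ``expr`` is spots x L for the L housekeeping genes matched to the
    post-QC panel (pooled across slides, centered per column here).
    Returns the first min(n_pcs, rank) column-centered PC scores with a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.  Fewer than ``n_pcs`` available components
    triggers a warning.
    """
    X = np.asarray(expr, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("no housekeeping genes matched the panel")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    n_comp = min(n_pcs, rank)
    if n_comp < n_pcs:
        warnings.warn(
            f"housekeeping matrix rank {rank} < requested {n_pcs} PCs; "
            f"returning {n_comp}"
        )
    if n_comp == 0:
        raise ValueError("housekeeping expression has zero rank")
    piv = np.argmax(np.abs(Vt[:n_comp]), axis=1)
    signs = np.sign(Vt[np.arange(n_comp), piv])
    return (U[:, :n_comp] * s[:n_comp]) * signs


def remove_unwanted_variation(expr, design: RemovalDesign):
    """Per-gene OLS on [Rhat | H | condition]; corrected x = x - H @ gamma^T.

    Returns (corrected expression, alpha (p x K), gamma (p x n_H)).
    Collinear design columns are dropped with a warning (no intercept is
    used since the Rhat block spans the constant).
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[0] != design.Rhat.shape[0]:
        raise ValueError("expression and design row counts disagree")
    blocks = [design.Rhat, design.H]
    if design.condition is not None:
        cond = np.atleast_2d(np.asarray(design.condition, dtype=float))
        if cond.shape[0] != X.shape[0]:
            cond = cond.T
        blocks.append(cond)
    D = np.column_stack(blocks)
    rank = np.linalg.matrix_rank(D)
    keep = np.arange(D.shape[1])
    if rank < D.shape[1]:
        # greedy QR-based column selection
        _, _, piv = _qr_pivot(D)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"design is rank deficient; dropping columns "
            f"{sorted(set(range(D.shape[1])) - set(keep))}"
        )
        D = D[:, keep]
    coef = np.linalg.lstsq(D, X, rcond=None)[0]  # n_cols x p

    K = design.Rhat.shape[1]
    nH = design.H.shape[1]
    full = np.zeros((design.Rhat.shape[1] + design.H.shape[1] + (
        0 if design.condition is None else blocks[2].shape[1]
    ), X.shape[1]))
    full[keep] = coef
    alpha = full[:K].T  # p x K
    gamma = full[K : K + nH].T  # p x nH
    corrected = X - design.H @ gamma.T
    return corrected, alpha, gamma


def _qr_pivot(D: np.ndarray):
    from scipy.linalg import qr

    return qr(D, mode="economic", pivoting=True)
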