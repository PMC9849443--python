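"""Evaluation metrics for integration and clustering quality.

Clustering agreement (adjusted Rand index, normalized mutual
information), the silhouette F1 score that balances cluster separation
against batch mixing, local inverse Simpson's index scores (cLISI for
cluster purity, iLISI for batch mixing), the mean canonical correlation
between estimated and true embeddings, and the mean conditional
correlation between labels and expression residualized on the estimated
embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import qr, svd
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MetricReport",
    "clustering_agreement",
    "silhouette_f1",
    "lisi_scores",
    "canonical_correlation_mean",
    "conditional_correlation_mean",
    "evaluate_integration",
]


@dataclass
class MetricReport:
    """Evaluation summary of a fitted model against ground truth."""

    ari: float = np.nan
    nmi: float = np.nan
    f1_silhouette: float = np.nan
    silh_cluster: float = np.nan
    silh_batch: float = np.nan
    clisi: float = np.nan
    ilisi: float = np.nan
    ccor: float = np.nan
    concor: float = np.nan
    concor_abs: float = np.nan

    def to_dict(self) -> dict:
        return {k: (None if np.isnan(v) else float(v)) for k, v in asdict(self).items()}


def clustering_agreement(labels_a, labels_b) -> tuple[float, float]:
    """(ARI, NMI) between two partitions.

    ARI is the Hubert-Arabie adjusted Rand index; NMI uses the
    arithmetic-mean normalization.  Both equal 1 when the partitions agree
    up to a relabeling.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 spots")
    return (
        float(adjusted_rand_score(a, b)),
        float(normalized_mutual_info_score(a, b, average_method="arithmetic")),
    )


def silhouette_f1(embeddings, cluster_labels, batch_labels):
    """Silhouette-based integration F1.

    Computes Euclidean average silhouette widths with cluster and batch
    groupings, rescales each to [0, 1] via s' = (1 + s) / 2, and returns

        F1 = 2 (1 - s'_batch) s'_cluster / (s'_cluster + 1 - s'_batch)

    together with the raw cluster and batch silhouettes.  Large values
    mean biological clusters remain separated while batches mix.
    """
    X = np.asarray(embeddings, dtype=float)
    cl = np.asarray(cluster_labels).ravel()
    ba = np.asarray(batch_labels).ravel()
    if len(np.unique(cl)) < 2 or len(np.unique(ba)) < 2:
        raise ValueError("silhouette undefined: need >=2 clusters and >=2 batches")
    s_cl = float(silhouette_score(X, cl, metric="euclidean"))
    s_ba = float(silhouette_score(X, ba, metric="euclidean"))
    return _silhouette_f1_from_pair(s_cl, s_ba), s_cl, s_ba


def _silhouette_f1_from_pair(silh_cluster: float, silh_batch: float) -> float:
    sc = (1.0 + silh_cluster) / 2.0
    sb = (1.0 + silh_batch) / 2.0
    denom = sc + (1.0 - sb)
    if denom == 0.0:
        return 0.0
    return float(2.0 * (1.0 - sb) * sc / denom)


def lisi_scores(embeddings, labels, perplexity: int = 30) -> np.ndarray:
    """Per-spot local inverse Simpson's index under Gaussian-kernel weights.

    For each spot, neighbor weights over its k = 3 * perplexity nearest
    neighbors are calibrated so the kernel entropy matches
    log(perplexity), label probabilities are accumulated, and the inverse
    Simpson's index 1 / sum_l p_l^2 is returned.  With cluster labels this
    is cLISI (1 = pure neighborhoods); with batch labels it is iLISI
    (-> number of batches under perfect mixing).
    """
    X = np.asarray(embeddings, dtype=float)
    lab = np.asarray(labels)
    n = X.shape[0]
    if n <= perplexity:
        raise ValueError("need more spots than the perplexity")
    codes, inv = np.unique(lab, return_inverse=True)
    L = len(codes)
    k = min(n - 1, 3 * perplexity)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    target = np.log(perplexity)
    scores = np.empty(n)
    d2 = dist**2
    for i in range(n):
        beta = _calibrate_beta(d2[i], target)
        w = np.exp(-beta * (d2[i] - d2[i].min()))
        w /= w.sum()
        probs = np.bincount(inv[idx[i]], weights=w, minlength=L)
        scores[i] = 1.0 / float((probs**2).sum())
    return scores


def _calibrate_beta(d2: np.ndarray, target: float, iters: int = 50) -> float:
    """Binary search the Gaussian precision so entropy matches log(perplexity)."""
    lo, hi = 0.0, np.inf
    beta = 1.0 / max(d2.mean(), 1e-12)
    for _ in range(iters):
        w = np.exp(-beta * (d2 - d2.min()))
        s = w.sum()
        h = np.log(s) + beta * float((w * (d2 - d2.min())).sum()) / s
        if abs(h - target) < 1e-5:
            break
        if h > target:  # too spread out -> sharpen
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (beta + hi)
        else:
            hi = beta
            beta = 0.5 * (beta + lo)
    return beta


def canonical_correlation_mean(Z_est, Z_true) -> float:
    """Mean of the canonical correlation coefficients between two embeddings.

    Both matrices are column-centered; the canonical correlations are the
    singular values of Q_est^T Q_true from thin QR factorizations.  The
    mean runs over min(q_est, q_true) coefficients.  1 means the true
    embedding space is perfectly recovered (up to any invertible linear
    map); independent embeddings give values near 0.
    """
    A = np.asarray(Z_est, dtype=float)
    B = np.asarray(Z_true, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError("row counts differ")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    for name, Mt in (("Z_est", A), ("Z_true", B)):
        if (Mt.std(axis=0) < 1e-12).any():
            raise ValueError(f"{name} has zero-variance columns")
    Qa, _ = qr(A, mode="economic")
    Qb, _ = qr(B, mode="economic")
    svals = svd(Qa.T @ Qb, compute_uv=False)
    ncc = min(A.shape[1], B.shape[1])
    return float(np.clip(svals[:ncc], 0.0, 1.0).mean())


def conditional_correlation_mean(expr, labels, Z_est):
    """Mean Pearson correlation between labels and expression residuals.

    Each gene is residualized on the estimated embeddings (least squares
    with intercept); the label vector, taken as its given numeric codes,
    is correlated with each residual column.  Returns (signed mean,
    mean of absolute correlations); the absolute version is reported
    because the signed one depends on how labels are coded.  Constant
    residual columns contribute 0 with a warning.
    """
    X = np.asarray(expr, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    Z = np.asarray(Z_est, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if X.shape[0] != y.size or X.shape[0] != Z.shape[0]:
        raise ValueError("shapes disagree")
    D = np.column_stack([np.ones(X.shape[0]), Z])
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ coef
    yc = y - y.mean()
    y_sd = yc.std()
    r_sd = resid.std(axis=0)
    const = r_sd < 1e-12
    if const.any():
        warnings.warn(f"{int(const.sum())} constant residual columns contribute 0")
    cors = np.zeros(X.shape[1])
    ok = ~const
    if y_sd > 0:
        cov = yc @ resid[:, ok] / X.shape[0]
        cors[ok] = cov / (y_sd * r_sd[ok])
    return float(cors.mean()), float(np.abs(cors).mean())


def evaluate_integration(
    embeddings,
    cluster_labels,
    batch_labels,
    truth_labels=None,
    truth_embeddings=None,
    expr=None,
    perplexity: int = 30,
) -> MetricReport:
    """Assemble the full metric report for one embedding/labeling."""
    rep = MetricReport()
    if truth_labels is not None:
        rep.ari, rep.nmi = clustering_agreement(cluster_labels, truth_labels)
    try:
        rep.f1_silhouette, rep.silh_cluster, rep.silh_batch = silhouette_f1(
            embeddings, cluster_labels, batch_labels
        )
    except ValueError:
        pass
    rep.clisi = float(lisi_scores(embeddings, cluster_labels, perplexity).mean())
    rep.ilisi = float(lisi_scores(embeddings, batch_labels, perplexity).mean())
    if truth_embeddings is not None:
        rep.ccor = canonical_correlation_mean(embeddings, truth_embeddings)
    if expr is not None:
        rep.concor, rep.concor_abs = conditional_correlation_mean(
            expr, cluster_labels, embeddings
        )
    return rep
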