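"""Spot neighborhood graphs and Potts label fields.

Spatial transcriptomics platforms place capture spots on square lattices
(ST, binned Slide-seqV2), hexagonal lattices (Visium) or irregular bead
arrays.  The spatial priors of the integration model — the Potts field on
cluster labels and the conditional autoregressive field on slide-specific
embeddings — are both defined on a symmetric neighbor graph over these
spots.  This module builds such graphs, samples Potts label fields on them
by Gibbs sampling, and scores label fields by the Potts pseudo-likelihood
(the normalizing constant of the Potts joint has no closed form, so the
product of full conditionals is used wherever a likelihood value is
needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._kernels import (
    icm_label_sweep,
    neighbor_label_counts,
    potts_gibbs_sweeps,
    potts_pseudo_loglik_kernel,
)

__all__ = [
    "NeighborGraph",
    "LabelField",
    "build_neighbor_graph",
    "sample_potts",
    "potts_pseudo_loglik",
    "read_coords_tsv",
]


@dataclass
class NeighborGraph:
    """Symmetric spot adjacency in flattened CSR form.

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbors N_i of spot i and
    ``degrees[i] = m_i`` their count.  The graph never contains self loops
    and is symmetric: j in N_i iff i in N_j.
    """

    n_spots: int
    indptr: np.ndarray
    indices: np.ndarray

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def neighbors(self) -> list[np.ndarray]:
        return [
            self.indices[self.indptr[i] : self.indptr[i + 1]]
            for i in range(self.n_spots)
        ]

    @property
    def isolated(self) -> np.ndarray:
        """Boolean mask of spots with no neighbors (m_i = 0)."""
        return self.degrees == 0

    @property
    def n_edges(self) -> int:
        return int(self.indices.size // 2)

    def edge_array(self) -> np.ndarray:
        """Undirected edges as an (n_edges, 2) array with i < j."""
        src = np.repeat(np.arange(self.n_spots), self.degrees)
        mask = src < self.indices
        return np.column_stack([src[mask], self.indices[mask]])

    def to_edge_tsv(self, path) -> None:
        """Each undirected edge once, 0-based, i < j, tab separated."""
        pd.DataFrame(self.edge_array(), columns=["i", "j"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_edges(cls, n_spots: int, edges: np.ndarray) -> "NeighborGraph":
        """Build from an (m, 2) array of undirected edges (any order)."""
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            both = np.vstack([edges, edges[:, ::-1]])
            both = np.unique(both, axis=0)
            both = both[both[:, 0] != both[:, 1]]
        else:
            both = np.empty((0, 2), dtype=np.int64)
        counts = np.bincount(both[:, 0], minlength=n_spots)
        indptr = np.zeros(n_spots + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return cls(n_spots=n_spots, indptr=indptr, indices=both[:, 1].copy())


@dataclass
class LabelField:
    """Cluster labels on a spot graph with Potts smoothing parameter beta.

    Labels are stored 0-based internally; ``K`` is the number of states.
    """

    labels: np.ndarray
    K: int
    beta: float = 0.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min(initial=0) < 0 or (
            self.labels.size and self.labels.max() >= self.K
        ):
            raise ValueError("labels must lie in 0..K-1")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")


# relative tolerance on the minimal center-to-center distance when linking
# lattice neighbors; robust to floating point jitter in array coordinates
# while excluding the next lattice shell (sqrt(2) for square, sqrt(3) for hex)
_LATTICE_TOL = 1.2


def _lattice_edges(coords: np.ndarray, max_degree: int) -> np.ndarray:
    tree = cKDTree(coords)
    # nearest nontrivial neighbor distance defines the lattice pitch
    d, _ = tree.query(coords, k=2)
    pitch = d[:, 1].min()
    pairs = tree.query_pairs(r=pitch * _LATTICE_TOL, output_type="ndarray")
    return pairs


def build_neighbor_graph(coords, scheme: str = "square4", param=None) -> NeighborGraph:
    """Build a symmetric spot neighbor graph.

    Parameters
    ----------
    coords : array-like, shape (n, 2)
        Spot centers. Must be finite with no duplicated positions.
    scheme : {"square4", "hex6", "knn", "radius"}
        ``square4`` links the 4 axis-adjacent sites of a square lattice and
        ``hex6`` the 6 nearest sites of a hexagonal lattice; both link all
        pairs within 1.2x the minimal pairwise distance.  ``knn`` links
        each spot to its ``param`` nearest neighbors, symmetrized by union.
        ``radius`` links all pairs within distance ``param``.
    param : int or float, optional
        Neighbor count for ``knn``, distance cutoff for ``radius``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    n = coords.shape[0]
    if n < 2:
        raise ValueError("graph undefined: need at least 2 spots")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")

    uniq, inv, cnt = np.unique(
        coords, axis=0, return_inverse=True, return_counts=True
    )
    if (cnt > 1).any():
        dup = np.flatnonzero(cnt[inv] > 1)[:10]
        raise ValueError(f"duplicate coordinates at spot indices {dup.tolist()}")

    if scheme in ("square4", "hex6"):
        edges = _lattice_edges(coords, 4 if scheme == "square4" else 6)
    elif scheme == "knn":
        if param is None:
            raise ValueError("knn scheme requires param (neighbor count)")
        k = int(param)
        if k < 1 or k >= n:
            raise ValueError("knn param must be in [1, n_spots)")
        tree = cKDTree(coords)
        _, idx = tree.query(coords, k=k + 1)
        src = np.repeat(np.arange(n), k)
        dst = idx[:, 1:].ravel()
        edges = np.column_stack([src, dst])
    elif scheme == "radius":
        if param is None:
            raise ValueError("radius scheme requires param (distance)")
        tree = cKDTree(coords)
        edges = tree.query_pairs(r=float(param), output_type="ndarray")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    return NeighborGraph.from_edges(n, edges)


def sample_potts(
    graph: NeighborGraph,
    K: int,
    beta: float,
    sweeps: int = 100,
    seed: int = 0,
) -> LabelField:
    """Draw a label field from the K-state Potts model by Gibbs sampling.

    Starts from an i.i.d. uniform configuration and performs ``sweeps``
    full sequential single-site Gibbs sweeps of the conditional
    P(y_i = k | y_{N_i}) proportional to exp(beta * #{i' in N_i: y_i' = k}).
    Identical (seed, K, beta, sweeps, graph) give identical labels.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if beta < 0:
        raise ValueError("beta must be nonnegative")
    if sweeps < 1:
        raise ValueError("sweeps must be at least 1")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=graph.n_spots).astype(np.int64)
    uniforms = rng.random((sweeps, graph.n_spots))
    potts_gibbs_sweeps(graph.indptr, graph.indices, labels, K, float(beta), uniforms)
    return LabelField(labels=labels, K=K, beta=float(beta))


def potts_pseudo_loglik(field: LabelField, graph: NeighborGraph, beta=None) -> float:
    """Potts pseudo-log-likelihood sum_i log P(y_i | y_{N_i}; beta).

    If ``beta`` is None the field's own smoothing parameter is used.
    """
    if field.labels.shape[0] != graph.n_spots:
        raise ValueError("label field and graph sizes disagree")
    b = field.beta if beta is None else float(beta)
    return float(
        potts_pseudo_loglik_kernel(
            graph.indptr, graph.indices, field.labels, field.K, b
        )
    )


def neighbor_counts(graph: NeighborGraph, labels: np.ndarray, K: int) -> np.ndarray:
    """n x K matrix c_ik = #{i' in N_i with label k}."""
    return neighbor_label_counts(
        graph.indptr, graph.indices, np.asarray(labels, dtype=np.int64), K
    )


def icm_sweep(graph: NeighborGraph, labels, emission, beta) -> int:
    """In-place sequential ICM sweep on ``labels``; returns #changed."""
    return int(
        icm_label_sweep(graph.indptr, graph.indices, labels, emission, float(beta))
    )


def read_coords_tsv(path) -> pd.DataFrame:
    """Read a coordinates table with columns (barcode, x, y)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"barcode", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinates TSV missing columns {sorted(missing)}")
    return df
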