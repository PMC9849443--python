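"""Reading, quality control and normalization of per-slide count data.

The pipeline mirrors standard spatial transcriptomics practice: read a
genes x spots count matrix (Matrix Market plus features/barcodes TSVs, or
dense TSV) with a per-spot coordinate table; drop genes expressed in
fewer than 20 spots and spots expressing fewer than 20 genes (iterated to
a fixpoint); library-size normalize to the slide median depth, log1p
transform, and center each gene within its slide; optionally collapse
high-resolution beads onto a coarse square grid; and assemble the shared
gene panel across slides from externally supplied ranked gene lists.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .graph import build_neighbor_graph
from .model import SlideData

__all__ = [
    "RawSlide",
    "load_slide",
    "qc_filter",
    "log_normalize_center",
    "select_genes_by_frequency",
    "bin_spots",
    "export_fit",
]


@dataclass
class RawSlide:
    """One slide's raw counts (genes x spots) with identifiers and coordinates."""

    counts: sp.csr_matrix  # genes x spots, nonnegative integers
    gene_ids: np.ndarray
    barcodes: np.ndarray
    coords: np.ndarray  # spots x 2
    slide_id: str = "slide"

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids)
        self.barcodes = np.asarray(self.barcodes)
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(f"{self.slide_id}: label counts do not match matrix shape")
        if len(np.unique(self.barcodes)) != len(self.barcodes):
            raise ValueError(f"{self.slide_id}: barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError(f"{self.slide_id}: negative counts")
        if self.coords.shape != (self.n_spots, 2):
            raise ValueError(f"{self.slide_id}: coords shape mismatch")

    def subset(self, gene_mask=None, spot_mask=None) -> "RawSlide":
        counts = self.counts
        gene_ids, barcodes, coords = self.gene_ids, self.barcodes, self.coords
        if gene_mask is not None:
            counts = counts[gene_mask]
            gene_ids = gene_ids[gene_mask]
        if spot_mask is not None:
            counts = counts[:, spot_mask]
            barcodes = barcodes[spot_mask]
            coords = coords[spot_mask]
        return RawSlide(counts.tocsr(), gene_ids, barcodes, coords, self.slide_id)


def load_slide(matrix_path, features_path=None, barcodes_path=None,
               coords_path=None, slide_id=None) -> RawSlide:
    """Read one slide from Matrix Market (.mtx) or dense TSV plus sidecar files.

    The matrix is genes x spots.  For MTX input, ``features_path`` and
    ``barcodes_path`` are required one-column (or first-column) TSVs whose
    line counts must match the matrix dimensions.  ``coords_path`` is a TSV
    with columns (barcode, x, y); its barcodes must match the matrix
    barcodes exactly (set-wise), and rows are re-ordered to the matrix.
    """
    matrix_path = str(matrix_path)
    if matrix_path.endswith(".mtx"):
        if features_path is None or barcodes_path is None:
            raise ValueError("MTX input requires features and barcodes files")
        counts = sp.csr_matrix(mmread(matrix_path))
        gene_ids = pd.read_csv(features_path, sep="\t", header=None).iloc[:, 0].to_numpy()
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].to_numpy()
        if counts.shape[0] != len(gene_ids):
            raise ValueError(
                f"features file has {len(gene_ids)} lines but matrix has "
                f"{counts.shape[0]} rows"
            )
        if counts.shape[1] != len(barcodes):
            raise ValueError(
                f"barcodes file has {len(barcodes)} lines but matrix has "
                f"{counts.shape[1]} columns"
            )
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts = sp.csr_matrix(df.to_numpy())
        gene_ids = df.index.to_numpy()
        barcodes = df.columns.to_numpy()

    if coords_path is None:
        raise ValueError("a coordinates TSV (barcode, x, y) is required")
    cdf = pd.read_csv(coords_path, sep="\t")
    missing_cols = {"barcode", "x", "y"} - set(cdf.columns)
    if missing_cols:
        raise ValueError(f"coordinates TSV missing columns {sorted(missing_cols)}")
    cdf = cdf.set_index("barcode")
    mat_set = set(map(str, barcodes))
    coord_set = set(map(str, cdf.index))
    only_coords = sorted(coord_set - mat_set)[:5]
    only_matrix = sorted(mat_set - coord_set)[:5]
    if only_coords or only_matrix:
        raise ValueError(
            "barcode mismatch between matrix and coordinates; "
            f"first offenders only-in-coords={only_coords}, "
            f"only-in-matrix={only_matrix}"
        )
    coords = cdf.loc[[str(b) for b in barcodes], ["x", "y"]].to_numpy(dtype=float)

    if slide_id is None:
        slide_id = matrix_path.rsplit("/", 1)[-1].split(".")[0]
    slide = RawSlide(counts, gene_ids, barcodes, coords, slide_id)
    slide.validate()
    return slide


def qc_filter(slide: RawSlide, min_spots_per_gene: int = 20,
              min_genes_per_spot: int = 20) -> RawSlide:
    """Iterative QC to a fixpoint.

    Removes genes with nonzero expression in fewer than
    ``min_spots_per_gene`` spots, then spots with nonzero expression of
    fewer than ``min_genes_per_spot`` genes, repeating until stable.
    """
    out = slide
    while True:
        nz = out.counts.copy()
        nz.data = (nz.data > 0).astype(np.int64)
        gene_ok = np.asarray(nz.sum(axis=1)).ravel() >= min_spots_per_gene
        if not gene_ok.all():
            out = out.subset(gene_mask=gene_ok)
            nz = nz[gene_ok]
        spot_ok = np.asarray(nz.sum(axis=0)).ravel() >= min_genes_per_spot
        if out.n_spots and not spot_ok.any():
            raise ValueError(f"QC eliminated slide {out.slide_id!r}")
        if not spot_ok.all():
            out = out.subset(spot_mask=spot_ok)
        if gene_ok.all() and spot_ok.all():
            break
        if out.n_spots == 0 or out.n_genes == 0:
            raise ValueError(f"QC eliminated slide {out.slide_id!r}")
    return out


def log_normalize_center(slide: RawSlide, scheme: str = "square4",
                         graph_param=None) -> SlideData:
    """Normalize counts and build the model-ready slide.

    Per-spot counts are scaled to the slide's median library size,
    log1p-transformed, and each gene is centered within the slide.  The
    returned expression matrix is spots x genes, as consumed by the model,
    together with a neighbor graph built from the coordinates.
    """
    depths = np.asarray(slide.counts.sum(axis=0)).ravel().astype(float)
    if (depths == 0).any():
        bad = np.flatnonzero(depths == 0)[:5]
        raise ValueError(
            f"{slide.slide_id}: zero-depth spots at indices {bad.tolist()} "
            "(run qc_filter first)"
        )
    target = float(np.median(depths))
    X = slide.counts.T.toarray().astype(float)  # spots x genes
    X *= (target / depths)[:, None]
    np.log1p(X, out=X)
    X -= X.mean(axis=0, keepdims=True)
    graph = build_neighbor_graph(slide.coords, scheme=scheme, param=graph_param)
    data = SlideData(
        expr=X,
        coords=slide.coords,
        graph=graph,
        slide_id=slide.slide_id,
        barcodes=slide.barcodes,
        gene_ids=slide.gene_ids,
    )
    data.validate()
    return data


def log_normalize_matrix(slide: RawSlide) -> np.ndarray:
    """Spots x genes median-depth-scaled log1p expression, NOT centered.

    This is the 'uncorrected' representation: per-slide intercepts and
    other batch structure remain, so pooling it across slides is the
    natural baseline against which integration and batch removal are
    judged (per-gene centering within slide already removes slide-level
    shifts and is part of the model input preparation, not a neutral
    baseline).
    """
    depths = np.asarray(slide.counts.sum(axis=0)).ravel().astype(float)
    if (depths == 0).any():
        raise ValueError(f"{slide.slide_id}: zero-depth spots (run qc_filter first)")
    X = slide.counts.T.toarray().astype(float)
    X *= (float(np.median(depths)) / depths)[:, None]
    return np.log1p(X)


def select_genes_by_frequency(per_slide_gene_lists, top_n: int = 2000) -> list:
    """Prioritize genes by how many per-slide ranked lists contain them.

    Genes are ordered by (number of lists containing them, descending),
    then mean within-list rank (ascending, 0-based), then identifier.
    The first ``top_n`` are returned; if the union is smaller than
    ``top_n`` the whole union is returned with a warning.
    """
    lists = [list(lst) for lst in per_slide_gene_lists]
    if not lists or any(len(lst) == 0 for lst in lists):
        raise ValueError("gene lists must be nonempty")
    freq: dict = {}
    rank_sum: dict = {}
    for lst in lists:
        for rank, g in enumerate(lst):
            freq[g] = freq.get(g, 0) + 1
            rank_sum[g] = rank_sum.get(g, 0.0) + rank
    ordered = sorted(
        freq, key=lambda g: (-freq[g], rank_sum[g] / freq[g], str(g))
    )
    if len(ordered) < top_n:
        warnings.warn(
            f"union of gene lists has {len(ordered)} genes < top_n={top_n}; "
            "returning the union"
        )
        return ordered
    return ordered[:top_n]


def bin_spots(slide: RawSlide, grid: tuple[int, int]) -> RawSlide:
    """Collapse beads onto a rows x cols square grid.

    The coordinate bounding box is partitioned into ``grid`` cells; counts
    of all beads in a cell are summed and the cell centroid becomes the new
    coordinate.  Empty cells are dropped.  Total counts are conserved.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    x, y = slide.coords[:, 0], slide.coords[:, 1]
    # right-closed last bin so max-coordinate beads stay inside the grid
    cx = np.minimum(((x - x.min()) / max(np.ptp(x), 1e-12) * cols).astype(int), cols - 1)
    cy = np.minimum(((y - y.min()) / max(np.ptp(y), 1e-12) * rows).astype(int), rows - 1)
    cell = cy * cols + cx
    used, inv = np.unique(cell, return_inverse=True)
    n_cells = len(used)
    assign = sp.csr_matrix(
        (np.ones(slide.n_spots), (np.arange(slide.n_spots), inv)),
        shape=(slide.n_spots, n_cells),
    )
    counts = (slide.counts @ assign).tocsr()
    new_coords = np.column_stack(
        [
            np.bincount(inv, weights=x) / np.bincount(inv),
            np.bincount(inv, weights=y) / np.bincount(inv),
        ]
    )
    barcodes = np.array([f"{slide.slide_id}_bin{c}" for c in used])
    return RawSlide(counts, slide.gene_ids, barcodes, new_coords, slide.slide_id)


def write_slide(slide: RawSlide, out_dir) -> None:
    """Write a slide as matrix.mtx + features.tsv + barcodes.tsv + coords.tsv."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(slide.counts))
    pd.Series(slide.gene_ids).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(slide.barcodes).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.DataFrame(
        {"barcode": slide.barcodes, "x": slide.coords[:, 0], "y": slide.coords[:, 1]}
    ).to_csv(os.path.join(out_dir, "coords.tsv"), sep="\t", index=False)


def export_fit(fit, data, out_dir) -> None:
    """Write the result file set of a fitted model.

    Produces embeddings.tsv, v_embeddings.tsv, labels.tsv,
    responsibilities.tsv, model.h5 and fit_log.json under ``out_dir``.
    Labels are written 1-based.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    q = fit.params.q
    K = fit.params.K
    rows_z, rows_v, rows_y, rows_r = [], [], [], []
    for r, slide in enumerate(data):
        bc = (
            slide.barcodes
            if slide.barcodes is not None
            else np.array([f"spot{i}" for i in range(slide.n_spots)])
        )
        base = pd.DataFrame({"slide": slide.slide_id, "barcode": bc})
        rows_z.append(
            pd.concat(
                [base, pd.DataFrame(fit.state.Z[r], columns=[f"z{j+1}" for j in range(q)])],
                axis=1,
            )
        )
        rows_v.append(
            pd.concat(
                [base, pd.DataFrame(fit.state.V[r], columns=[f"v{j+1}" for j in range(q)])],
                axis=1,
            )
        )
        rows_y.append(base.assign(label=fit.state.Y[r] + 1))
        rows_r.append(
            pd.concat(
                [base, pd.DataFrame(fit.state.R[r], columns=[f"r{k+1}" for k in range(K)])],
                axis=1,
            )
        )
    fmt = dict(sep="\t", index=False, float_format="%.17g")
    pd.concat(rows_z).to_csv(os.path.join(out_dir, "embeddings.tsv"), **fmt)
    pd.concat(rows_v).to_csv(os.path.join(out_dir, "v_embeddings.tsv"), **fmt)
    pd.concat(rows_y).to_csv(os.path.join(out_dir, "labels.tsv"), sep="\t", index=False)
    pd.concat(rows_r).to_csv(os.path.join(out_dir, "responsibilities.tsv"), **fmt)
    fit.params.save(os.path.join(out_dir, "model.h5"))
    with open(os.path.join(out_dir, "fit_log.json"), "w") as fh:
        json.dump(
            {
                "objective_trace": [float(v) for v in fit.objective_trace],
                "beta": [float(b) for b in fit.params.beta],
                "criterion": None if fit.criterion is None else float(fit.criterion),
                "converged": bool(fit.converged),
                "n_iter": len(fit.objective_trace),
            },
            fh,
            indent=2,
        )
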