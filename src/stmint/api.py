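"""Model / Results interface for multi-slide spatial integration.

``SpatialFactorModel`` holds the prepared slides and fitting
configuration; ``fit()`` runs the ICM-EM algorithm and returns a
``SpatialFactorResults`` carrying aligned embeddings, slide-specific
embeddings, cluster labels, responsibilities, parameter estimates and
diagnostics, with ``summary()``, ``save()``, ``evaluate()`` and
``remove_batch()`` hanging off the results object.
"""

from __future__ import annotations

import numpy as np

from . import inference
from .batch import RemovalDesign, housekeeping_pcs, remove_unwanted_variation
from .inference import FitOptions, FitResult
from .metrics import MetricReport, evaluate_integration
from .model import SlideData
from .preprocess import RawSlide, export_fit, log_normalize_center, qc_filter

__all__ = ["SpatialFactorModel", "SpatialFactorResults"]


class SpatialFactorModel:
    """Joint spatial dimension reduction, clustering and alignment model.

    Parameters
    ----------
    slides : list of SlideData
        Prepared slides sharing one gene panel (centered normalized
        expression + coordinates + neighbor graph).
    K : int
        Number of clusters (spatial domains / cell types).
    q : int
        Embedding dimension (default 10).
    """

    def __init__(self, slides: list[SlideData], K: int, q: int = 10):
        if not slides:
            raise ValueError("need at least one slide")
        panel = slides[0].n_genes
        for s in slides:
            s.validate()
            if s.n_genes != panel:
                raise ValueError("slides do not share a gene panel")
        self.slides = list(slides)
        self.K = int(K)
        self.q = int(q)

    @classmethod
    def from_counts(
        cls,
        raw_slides: list[RawSlide],
        K: int,
        q: int = 10,
        min_spots_per_gene: int = 20,
        min_genes_per_spot: int = 20,
        scheme: str = "square4",
        graph_param=None,
        gene_panel=None,
    ) -> "SpatialFactorModel":
        """Build from raw counts: QC, shared panel, normalization, graphs.

        After per-slide QC, only genes surviving QC in *every* slide (and
        present in ``gene_panel``, if given) are kept, so the shared
        loading matrix is defined over a common panel.
        """
        qced = [
            qc_filter(s, min_spots_per_gene, min_genes_per_spot) for s in raw_slides
        ]
        shared = set(map(str, qced[0].gene_ids))
        for s in qced[1:]:
            shared &= set(map(str, s.gene_ids))
        if gene_panel is not None:
            keep_order = [g for g in map(str, gene_panel) if g in shared]
        else:
            keep_order = [g for g in map(str, qced[0].gene_ids) if g in shared]
        if not keep_order:
            raise ValueError("no genes shared across slides after QC")
        slides = []
        for s in qced:
            pos = {str(g): i for i, g in enumerate(s.gene_ids)}
            idx = np.array([pos[g] for g in keep_order])
            slides.append(
                log_normalize_center(
                    s.subset(gene_mask=idx), scheme=scheme, graph_param=graph_param
                )
            )
        return cls(slides, K=K, q=q)

    def fit(
        self,
        max_iter: int = 30,
        tol: float = 1e-5,
        seed: int = 1,
        beta_grid=None,
        beta_init: float = 1.0,
        freeze=(),
    ) -> "SpatialFactorResults":
        """Fit by ICM-EM and wrap the outcome in a results object."""
        opts = FitOptions(
            K=self.K,
            q=self.q,
            max_iter=max_iter,
            tol=tol,
            seed=seed,
            beta_init=beta_init,
            freeze=frozenset(freeze),
        )
        if beta_grid is not None:
            opts.beta_grid = np.asarray(beta_grid, dtype=float)
        fit = inference.fit_model(self.slides, opts)
        return SpatialFactorResults(self, fit)

    def select_K(self, K_grid, max_iter: int = 30, tol: float = 1e-5, seed: int = 1):
        """Fit each K in the grid; return (best_K, table, results for best)."""
        opts = FitOptions(K=self.K, q=self.q, max_iter=max_iter, tol=tol, seed=seed)
        best, table, fit = inference.select_num_clusters(self.slides, opts, K_grid)
        return best, table, SpatialFactorResults(self, fit)


class SpatialFactorResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    def __init__(self, model: SpatialFactorModel, fit: FitResult):
        self.model = model
        self._fit = fit

    # --- primary estimates -------------------------------------------------
    @property
    def params(self):
        return self._fit.params

    @property
    def state(self):
        return self._fit.state

    @property
    def labels(self) -> list[np.ndarray]:
        """Per-slide 0-based hard cluster labels."""
        return self._fit.state.Y

    @property
    def embeddings(self) -> list[np.ndarray]:
        """Per-slide aligned embeddings (posterior means of z)."""
        return self._fit.state.Z

    @property
    def slide_embeddings(self) -> list[np.ndarray]:
        """Per-slide slide-specific embeddings v (MAP)."""
        return self._fit.state.V

    @property
    def responsibilities(self) -> list[np.ndarray]:
        return self._fit.state.R

    @property
    def objective_trace(self) -> list[float]:
        return self._fit.objective_trace

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def beta(self) -> list[float]:
        """Estimated per-slide Potts smoothing parameters."""
        return self._fit.params.beta

    @property
    def criterion(self):
        return self._fit.criterion

    def pooled(self, attr: str) -> np.ndarray:
        """Row-concatenate a per-slide quantity across slides."""
        return np.concatenate(getattr(self, attr), axis=0)

    def batch_index(self) -> np.ndarray:
        """Slide index per pooled spot."""
        return np.concatenate(
            [np.full(s.n_spots, r) for r, s in enumerate(self.model.slides)]
        )

    # --- reporting ---------------------------------------------------------
    def summary(self) -> str:
        fit = self._fit
        p = fit.params
        lines = [
            "Spatial factor integration model",
            "=" * 48,
            f"slides: {len(self.model.slides)}   "
            f"spots: {sum(s.n_spots for s in self.model.slides)}   "
            f"genes: {p.p}",
            f"K (clusters): {p.K}   q (embedding dim): {p.q}",
            f"iterations: {len(fit.objective_trace)}   converged: {fit.converged}",
            f"final objective: {fit.objective_trace[-1]:.4f}",
            f"emission log-likelihood: {fit.emission_loglik:.4f}",
            "-" * 48,
            f"{'slide':<12}{'n_spots':>9}{'beta':>8}{'mean_deg':>10}",
        ]
        for r, s in enumerate(self.model.slides):
            lines.append(
                f"{s.slide_id:<12}{s.n_spots:>9}{p.beta[r]:>8.2f}"
                f"{s.graph.degrees.mean():>10.2f}"
            )
        occupancy = np.bincount(
            np.concatenate(self.labels), minlength=p.K
        )
        lines.append("-" * 48)
        lines.append(
            "cluster sizes: " + " ".join(str(int(c)) for c in occupancy)
        )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write embeddings/labels/responsibilities/model.h5/fit_log.json."""
        export_fit(self._fit, self.model.slides, out_dir)

    # --- downstream --------------------------------------------------------
    def evaluate(
        self,
        truth_labels=None,
        truth_embeddings=None,
        expr=None,
        perplexity: int = 30,
    ) -> MetricReport:
        """Metric report on the pooled aligned embeddings.

        ``truth_labels`` / ``truth_embeddings`` are per-slide lists or
        pooled arrays; batches are the slide indices.
        """
        emb = self.pooled("embeddings")
        lab = self.pooled("labels")
        return evaluate_integration(
            emb,
            lab,
            self.batch_index(),
            truth_labels=_pool(truth_labels),
            truth_embeddings=_pool(truth_embeddings),
            expr=_pool(expr),
            perplexity=perplexity,
        )

    def remove_batch(
        self, housekeeping_genes, n_pcs: int = 10, condition=None,
        per_slide_pca: bool = False,
    ):
        """Batch-corrected expression via negative-control regression.

        ``housekeeping_genes`` are matched (case-insensitively) against
        the fitted gene panel; their leading PCs (pooled across slides by
        default) and the responsibilities form the regression design.
        Returns (list of per-slide corrected matrices, alpha, gamma).
        """
        slides = self.model.slides
        gene_ids = slides[0].gene_ids
        if gene_ids is None:
            raise ValueError("slides carry no gene identifiers")
        panel = {str(g).upper(): i for i, g in enumerate(gene_ids)}
        idx = sorted(
            {panel[str(g).upper()] for g in housekeeping_genes if str(g).upper() in panel}
        )
        if not idx:
            raise ValueError("no housekeeping genes matched the fitted panel")
        X = np.vstack([s.expr for s in slides])
        if per_slide_pca:
            H = np.vstack(
                [housekeeping_pcs(s.expr[:, idx], n_pcs) for s in slides]
            )
        else:
            H = housekeeping_pcs(X[:, idx], n_pcs)
        design = RemovalDesign(
            H=H, Rhat=self.pooled("responsibilities"), condition=_pool(condition)
        )
        corrected, alpha, gamma = remove_unwanted_variation(X, design)
        out, ofs = [], 0
        for s in slides:
            out.append(corrected[ofs : ofs + s.n_spots])
            ofs += s.n_spots
        return out, alpha, gamma


def _pool(x):
    if x is None:
        return None
    if isinstance(x, (list, tuple)):
        return np.concatenate([np.asarray(v) for v in x], axis=0)
    return np.asarray(x)
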