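import numpy as np
import pytest

from stmint.graph import build_neighbor_graph
from stmint.model import ModelParams, SlideData


def lattice_coords(rows, cols):
    xx, yy = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    return np.column_stack([xx.ravel(), yy.ravel()])


@pytest.fixture(scope="session")
def grid20():
    """20x20 unit square lattice with 4-neighborhoods."""
    coords = lattice_coords(20, 20)
    return coords, build_neighbor_graph(coords, "square4")


def random_params(rng, p=6, q=2, K=3, n_slides=1):
    """A valid random ModelParams instance."""
    A = rng.standard_normal((p, q))
    W = np.linalg.qr(A)[0]
    mu = rng.standard_normal((K, q))
    Sigma = np.empty((K, q, q))
    for k in range(K):
        B = rng.standard_normal((q, q))
        Sigma[k] = B @ B.T + 0.5 * np.eye(q)
    Lambda = [rng.uniform(0.5, 2.0, size=p) for _ in range(n_slides)]
    Psi = []
    for _ in range(n_slides):
        B = rng.standard_normal((q, q))
        Psi.append(B @ B.T + 0.5 * np.eye(q))
    return ModelParams(
        W=W, mu=mu, Sigma=Sigma, Lambda=Lambda, Psi=Psi,
        beta=[1.0] * n_slides,
        slide_ids=[f"s{r}" for r in range(n_slides)],
    )


def spatial_gaussian_slide(seed, rows=12, cols=12, p=30, q=3, K=3, sep=8.0,
                           noise=0.6, beta=1.0):
    """Slide with Potts-smooth labels and simplex-separated Gaussian
    clusters observed through a shared loading (no counts, no v field)."""
    from stmint.graph import sample_potts
    from stmint.simulate import simplex_means

    rng = np.random.default_rng(seed)
    coords = lattice_coords(rows, cols)
    graph = build_neighbor_graph(coords, "square4")
    y = sample_potts(graph, K, beta, sweeps=80, seed=seed).labels
    W = np.linalg.qr(rng.standard_normal((p, q)))[0]
    mu = simplex_means(K, q, distance=sep)
    Z = mu[y] + rng.standard_normal((len(y), q))
    X = Z @ W.T + rng.standard_normal((len(y), p)) * noise
    X -= X.mean(axis=0)
    slide = SlideData(expr=X, coords=coords, graph=graph, slide_id="sp")
    return slide, y, Z, W


def gaussian_slide(rng, n_rows=8, n_cols=8, p=20, q=2, K=3, sep=4.0, noise=0.7):
    """One slide drawn exactly from the factor-mixture layer (no counts)."""
    coords = lattice_coords(n_rows, n_cols)
    graph = build_neighbor_graph(coords, "square4")
    n = coords.shape[0]
    W = np.linalg.qr(rng.standard_normal((p, q)))[0]
    mu = rng.standard_normal((K, q)) * sep
    y = rng.integers(0, K, n)
    Z = mu[y] + rng.standard_normal((n, q))
    X = Z @ W.T + rng.standard_normal((n, p)) * noise
    X -= X.mean(axis=0)
    slide = SlideData(expr=X, coords=coords, graph=graph, slide_id="g")
    return slide, y, Z, W
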