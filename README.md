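# stmint — multi-slide spatial transcriptomics integration

Spatially resolved transcriptomics (SRT) experiments routinely span
several tissue slides — serial sections, replicate arrays, multiple
donors.  Analyzing them jointly requires three things at once: a shared
low-dimensional representation of expression, spatially coherent cluster
(domain) labels, and removal of the slide-level technical and
non-cellular variation that would otherwise masquerade as biology.
Doing these steps separately (PCA, then batch correction, then
clustering) lets errors in each stage contaminate the next.  `stmint`
fits a single hierarchical probabilistic model that performs spatial
dimension reduction, spatial clustering and cross-slide embedding
alignment simultaneously, for spot-level data on square or hexagonal
lattices and for binned bead arrays.

It is aimed at computational biologists who have per-slide count
matrices (Matrix Market + barcodes/features, or dense TSV) with spot
coordinates, and want aligned embeddings, spatial-domain labels and
batch-corrected expression out the other end.

## Model

For slide *r* and spot *i* with centered normalized expression
*x*<sub>*ri*</sub> ∈ ℝ<sup>*p*</sup>:

* factor layer: *x*<sub>*ri*</sub> = **W**(*z*<sub>*ri*</sub> + *v*<sub>*ri*</sub>) + *ε*<sub>*ri*</sub>,
  *ε*<sub>*ri*</sub> ~ N(0, Λ<sub>*r*</sub>) with Λ<sub>*r*</sub> diagonal and
  **W** (p×q, orthonormal columns) shared by all slides;
* mixture layer: *z*<sub>*ri*</sub> | *y*<sub>*ri*</sub>=k ~ N(μ<sub>k</sub>, Σ<sub>k</sub>) —
  the *aligned embeddings*, carrying only the biology shared across slides;
* Potts layer: the labels *y*<sub>*r*</sub> form a K-state Potts Markov
  random field on the spot neighbor graph with slide smoothing β<sub>*r*</sub>,
  favouring spatially contiguous domains;
* CAR layer: the *slide-specific embeddings* *v*<sub>*ri*</sub> follow a
  conditional autoregressive field — conditional mean equal to the
  neighbor average, conditional covariance Ψ<sub>*r*</sub>/m<sub>*ri*</sub>.
  Because this conditional mean is not forced to zero, *v* absorbs the
  projection of slide-level (batch, microenvironment) effects onto the
  biological subspace span(**W**); no per-slide loading is ever estimated.

Fitting is by an ICM-EM scheme: hard labels and conditional-mode v
sweeps drive the two spatial fields, soft responsibilities drive the
mixture moments, every parameter update is closed-form, and all
p-dimensional algebra goes through the Woodbury identity (no p×p matrix
is formed).  After fitting, batch-corrected expression is recovered by
regressing expression on the label posteriors plus the top principal
components of user-supplied housekeeping (negative-control) genes and
subtracting the housekeeping component.

## Worked example

```python
import numpy as np
from stmint import SpatialFactorModel, Scenario1Config, simulate_scenario1
from stmint.metrics import clustering_agreement, canonical_correlation_mean

# three simulated slides (20x20 spots each, 200 genes) with ground truth
cfg = Scenario1Config(lattice_sizes=[(20, 20)] * 3, p=200, b_scale=1.0, seed=11)
ds = simulate_scenario1(cfg)

model = SpatialFactorModel.from_counts(ds.slides, K=7, q=10)
res = model.fit(max_iter=30, tol=1e-5, seed=1)
print(res.summary())

ari, _ = clustering_agreement(np.concatenate(res.labels),
                              np.concatenate(ds.labels))
ccor = canonical_correlation_mean(res.pooled("embeddings"), np.vstack(ds.Z))
print(f"ARI = {ari:.3f}, mean canonical correlation = {ccor:.3f}")
```

Output (abridged):

```
Spatial factor integration model
================================================
slides: 3   spots: 1200   genes: 194
K (clusters): 7   q (embedding dim): 10
...
slide         n_spots    beta  mean_deg
slide1            400    0.80      3.80
slide2            400    1.10      3.80
slide3            400    1.20      3.80
...
ARI = 0.963, mean canonical correlation = 0.752
```

The adjusted Rand index of 0.96 says the recovered spatial domains agree
almost perfectly with the simulated truth; the mean canonical
correlation of 0.75 measures how much of the true 10-dimensional latent
embedding survives the Poisson count observation layer (an oracle using
the true loading reaches about 0.8 on this data).  The fitted β values
track the per-slide smoothing used by the generator (0.8, 1.0, 1.2).

A command-line interface mirrors the library:

```bash
stmint simulate --scenario 1 --b-scale 1 --seed 1 --out sim/
stmint fit --counts sim/slide1/matrix.mtx,... --coords sim/slide1/coords.tsv,... \
           --k 7 --q 10 --out fit/
stmint evaluate --embeddings fit/embeddings.tsv --labels fit/labels.tsv --out report.json
stmint remove-batch --expr expr.tsv --fit fit/model.h5 --housekeeping hk.txt --out corrected.tsv
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
simulates a reduced three-slide count dataset from scratch, fits the
full model, evaluates domain recovery and embedding recovery against the
generator's ground truth (printed to stderr), and writes the JSON
manifest to `--out`.
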