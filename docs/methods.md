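# Methods

## Model

`stmint` fits a four-layer hierarchical model to M slides of centered,
normalized spot-level expression (n_r spots, p shared genes):

1. **Factor layer.** x_ri = W (z_ri + v_ri) + eps_ri, eps_ri ~ N(0,
   Lambda_r) with Lambda_r = diag(lambda_r1..lambda_rp).  W (p×q) has
   orthonormal columns and is shared across slides, which is what makes
   the embeddings comparable between slides in the first place.
2. **Mixture layer.** z_ri | y_ri = k ~ N(mu_k, Sigma_k): a Gaussian
   mixture over K cell/domain types, common to all slides (uniform
   mixing weights; the Potts field supplies the label prior).
3. **Potts layer.** P(y_r) ∝ exp{−(β_r/2) Σ_i Σ_{i'∈N_ri} (1 −
   δ(y_ri, y_ri'))} on the spot neighbor graph; β_r ≥ 0 is per slide.
   The normalizing constant is intractable, so everywhere a likelihood
   value in β is needed the pseudo-likelihood (product of sitewise full
   conditionals) is used.
4. **CAR layer.** v_ri | v_(-i) ~ N(neighbor mean, Psi_r / m_ri), an
   intrinsic conditional autoregressive field.  Its non-zero conditional
   mean is deliberate: slide-level effects with loadings outside span(W)
   project approximately onto span(W), and v absorbs that projected
   component plus the local-microenvironment signal.  No per-slide
   loading matrix or batch factor is ever estimated — this implicit
   projection is the alignment mechanism.  Because the intrinsic joint
   is improper, all inference-side computations use the proper
   approximation with precision rho(M − A) + (1 − rho) I, rho = 0.99
   (M = degree diagonal, A = adjacency); at lattice degrees this is
   numerically indistinguishable from the intrinsic conditionals but
   gives a well-defined joint, which both the simulator and the Psi
   estimator rely on.

## Fitting: ICM-EM

One outer iteration, in order: (1) responsibilities R_rik ∝
exp(β_r c_rik) N(x_ri; W(mu_k + v_ri), W Sigma_k Wᵀ + Lambda_r), c_rik
the neighbor label counts; (2) one sequential ICM sweep on the hard
labels (ties toward the smallest index); (3) sequential conditional-mode
sweeps on v, repeated within the iteration until the field moves less
than 0.1% RMS (cap 10 sweeps) — the CAR field relaxes by local
diffusion, and a single sweep per outer iteration leaves a long drifting
transient; (4) the embedding posterior per cluster, E[z|x,y=k] and its
covariance (Sigma_k⁻¹ + WᵀLambda⁻¹W)⁻¹; (5) closed-form M-step; (6) a
pseudo-likelihood grid search for each β_r over 0:0.1:5 (ties to the
smallest candidate).  Every p-dimensional Gaussian goes through the
Woodbury identity and the matrix-determinant lemma in O(p q²); no p×p
matrix is ever materialized.

Details that matter in practice:

* **Initialization.** W = top-q right singular subspace of the
  row-concatenated expression (randomized SVD, seeded, deterministic
  sign); labels by k-means on the **variance-whitened** pooled scores
  (heteroscedastic embedding dimensions otherwise dominate the Euclidean
  assignment and cost ~0.3 ARI on realistic data); cluster moments from
  the partition; Lambda from residual variances; Psi = I, β = 1, v = 0.
  A short warm-up (5 rounds of v sweeps alternated with the Psi update)
  then equilibrates the spatial field before the first recorded
  iteration.
* **Psi update.** Psi_r = (V̂ᵀQV̂ + Σ_i c_i P_i⁻¹)/n_r, with Q the
  proper-CAR precision, c_i = rho·m_i + 1 − rho and P_i the conditional
  precision of v_i.  The second term — the summed conditional
  covariances — is essential: a conditional-mode field is smoother than
  a draw from its own prior, so estimating Psi from the plug-in scatter
  alone collapses Psi (and then v) geometrically to zero.  The same
  covariances (unweighted) enter the W and Lambda moment equations so
  that the latent scale does not inflate along the z/v ridge.
* **W orthonormalization.** The least-squares loading A B⁻¹ is split by
  SVD into an orthonormal W and a q×q transform T applied to every
  latent quantity (z, v, mu, Sigma, Psi, second moments), so the fit is
  invariant to the constraint.
* **Empty clusters** (sum of responsibilities < 1e−8) are re-seeded at
  the spot with the lowest maximum responsibility; K is preserved.
* **Floors.** Lambda ≥ 1e−4; Sigma_k and Psi_r eigenvalue-clipped at
  1e−6.

**Convergence monitor.** The recorded objective is the sitewise
pseudo-marginal log-likelihood — z *and* v integrated out given the
neighbors' current field, evaluated at the hard labels — plus the Potts
pseudo-log-likelihood.  Plug-in alternatives (v held fixed) are not
invariant under the M-step's latent reparameterization T and show
spurious decreases of order n·log|det T| during the field's growth
transient; the marginal form is invariant and empirically nondecreasing
to within 1e−4 relative slack.  A hybrid ICM/EM scheme has no exact
Lyapunov function: individual label flips can still move the recorded
value by O(1), which is why the monotonicity contract carries that
slack.  Convergence is declared when the relative change drops below
`tol` (default 1e−5; default max_iter 30, q = 10, seed 1).

**Model selection.** For a K grid, criterion(K) = −2·(pseudo-marginal
log-likelihood) + df(K)·log(n_total)·c with df(K) = Kq + Kq(q+1)/2 + pq
+ Mp and c = log(log(p + n_total)) by default (an MBIC flavor; the
constant is exposed because the literature pins no unique choice).

## Synthetic data

`simulate_scenario1` generates M slides of raw counts on rectangular
lattices with full ground truth: Potts labels (β_r = 0.8 + 0.2(r−1),
sequential Gibbs, seeded), CAR microenvironment features ν with
among-dimension covariance Ψ'_r[i,j] = r(0.2r)^|i−j| and among-spot
precision rho(M−A)+(1−rho)I, cluster-conditional embeddings z, a shared
QR-orthonormalized loading W, per-slide batch loadings W_r (shared
normal core perturbed with sd σ̄_r ∈ {0.5, 0.8, 1.0}, re-orthogonalized),
batch factors ζ ~ N(0, b²σ_r²) with σ_r ∈ {1, 2, 0.5} and b ∈ {1,2,3}
the low/middle/high batch-effect scale, per-gene intercepts τ ~ N(0, 4),
heteroscedastic residuals (λ_1j = 2(1+1.5|z|), z~N(0,3); λ_2j = 2(1+u);
λ_3j = 2(1+2u), u~U[0,1]) and finally counts ~ Poisson(exp(x)).  The
default lattice sizes 65², 60², 60² give 11,425 spots with p = 2000
genes, K = 7, q = 10, q_r = 2.

**Cluster-moment tables.** The defaults place the K means on a regular
simplex (pairwise distance 18) spanning the first K−1 embedding
dimensions, with diagonal covariances: variance 1 on the mean
dimensions, 16 on the rest.  These tables are free parameters of the
simulation design, chosen once and calibrated at
the observable level: the exp/Poisson/log1p observation chain attenuates
latent amplitude roughly twofold and floors low-baseline genes, and
with these values an oracle linear readout of the counts (true loading,
k-means) recovers domains at ARI ≈ 0.9 while non-spatial clustering of
PCA embeddings does not — the strong-signal regime the simulation is
meant to represent.
Means can only span K−1 ≤ 6 dimensions, so the remaining embedding
dimensions are identifiable from counts solely through within-cluster
variance; variance 16 makes them recoverable but a measured information
ceiling remains: even the oracle projection attains mean canonical
correlation ≈ 0.8 at the reduced test scale (p = 200), and the fitted
model lands a few points below.  Both tables are constructor arguments
(`mu`, `Sigma`) and can be replaced wholesale.

What a green simulation test does establish: the estimation machinery
recovers labels, embeddings and smoothing parameters from data generated
by its own model family observed through a realistic count layer, and
integration metrics beat uncorrected pooled-PCA baselines.  What it does
not establish: performance on real tissue, where expression is not
log-Gaussian, domains are not Potts fields, the gene panel is selected
by spatially-aware screens, and batch effects are not linear factors.

**Baselines.** "Uncorrected" in all comparisons means pooled
median-depth log1p expression with *global* centering only — per-slide
per-gene centering already removes slide-level shifts (the τ_r
intercepts) and is part of model input preparation, not a neutral
baseline.

## Preprocessing and batch removal

QC drops genes with nonzero expression in fewer than 20 spots, then
spots with fewer than 20 expressed genes, iterated to a fixpoint.
Normalization scales each spot to the slide's median library size,
applies log1p, and centers each gene within its slide (the target is the
median rather than a fixed constant so slides of different depth stay on
one scale).  The shared panel across slides can be built from externally
ranked per-slide gene lists by selection frequency, then mean in-list
rank, then identifier (deterministic ties); high-resolution bead arrays
can be collapsed onto a rows×cols grid (counts summed per cell, centroid
coordinates).  Batch removal regresses each gene on [label posteriors |
top-10 housekeeping PCs | optional condition covariates] without an
intercept (the posterior block spans the constant) and subtracts only
the housekeeping component; housekeeping PCA is pooled across slides by
default (`per_slide_pca` switches).  The bundled housekeeping list is a
test fixture, not a curated biological resource.

## Evaluation metrics

ARI (Hubert–Arabie) and NMI (arithmetic normalization) for partition
agreement; the silhouette F1 combining cluster-separation and
batch-mixing silhouettes via F1 = 2(1−s'_b)s'_c/(s'_c+1−s'_b),
s' = (1+s)/2; local inverse Simpson's index scores with Gaussian-kernel
weights calibrated to perplexity 30 over 3×perplexity nearest neighbors
(cLISI → 1 is pure, iLISI → M is mixed); mean canonical correlation
between estimated and true embeddings (QR/SVD route); and the mean
Pearson correlation between labels (as numeric codes) and per-gene
residuals after regressing expression on the estimated embeddings.  The
label/residual correlation is reported both signed — as conventionally
printed — and in absolute value, because for K > 2 the signed version
depends on an arbitrary label coding.

## Known limitations

* The ICM-EM hybrid has no global ascent guarantee; the recorded
  pseudo-objective can dip by a few flips' worth during early
  iterations (within the documented slack) and the fit can inherit a
  poor k-means basin on weakly separated data.
* The canonical-correlation recovery of embedding dimensions beyond the
  span of the cluster means is bounded by the count observation layer,
  not by the optimizer (see the ceiling discussion above).
* Runtime is dominated by the per-cluster Woodbury passes,
  O(K n p q) per iteration; the v sweep is a sequential Python loop over
  spots and becomes noticeable beyond ~10⁵ spots.
* Graphs are strictly 2-D; slides are never spatially registered onto a
  common coordinate system (alignment happens in embedding space only).
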