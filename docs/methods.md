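# Methods

## Spatial graph

Spots are connected when each is among the other's k nearest neighbors by
Euclidean distance (mutual kNN), with weight 1. k defaults to 6 on hexagonal
grids (each interior Visium spot has six equidistant neighbors), 4 on square
grids, 6 otherwise. Distance ties are broken by (distance, spot index) so the
graph is identical across platforms; whether any particular tie-break matches
other implementations is unknowable and irrelevant for the estimators, which
only consume the weights matrix.

Boundary information scales edges down, never up:

- *soft, expression*: cosine similarity of per-spot feature vectors
  (conventionally the first 10 expression PCs — `reduce_features` computes
  them from a count matrix via median library-size normalization, log1p, and
  gene centering), negatives clamped to 0;
- *soft, histology*: Gaussian kernel `exp(−d²/2·0.1²)` on the Euclidean
  distance between feature vectors after per-dimension z-scoring. The
  normalization of the feature space before the bandwidth-0.1 kernel is a
  design choice (z-score rather than min–max): it makes the kernel scale
  independent of the features' units;
- *hard labels*: 1 within a domain, `leak` across domains. `leak=0`
  (default) removes the edge; `leak=0.01` keeps a nominal connection that
  lets weak information flow across annotated boundaries.

The graph module takes any precomputed per-spot feature matrix; it performs
no PCA or image I/O itself, keeping image processing out of scope.

## Priors and losses

Five stationary processes map W to a precision matrix: CAR `Q = I − ρW`,
SAR `Q = (I−ρW)ᵀ(I−ρW)`, ICAR `Q = D − ρW` with D the diagonal of row sums,
ISAR the SAR form on the row-normalized W̃, and SMA with covariance
`Σ = (I+ρW̃)(I+ρW̃)ᵀ` whose precision is applied through sparse triangular
solves rather than ever being formed (its explicit inverse is nearly dense,
which is also why SMA is not recommended for large slides). ρ ∈ [0,1] for
the weights-scaled processes and strictly inside the reciprocal spectral
range of W for CAR/SAR (validated against the actual spectrum, with the
admissible interval reported in the error).

Conditional variances are fixed at 1, so the CAR precision is exactly the
symmetric `I − ρW`; per-spot variance rescaling is deliberately omitted
(the implied prior variances are not constant across spots) because the loss
is only ever used up to the global factor absorbed by λ_sp, and a
standardized Σ would have a dense diagonal correction.

Singularity (ICAR/ISAR at ρ=1, or isolated spots) is handled by adding
`jitter·I` (default 1e−5) only when needed; `jitter=0` exposes the exact
intrinsic null space, in which the loss of a constant field is zero and the
loss is invariant to adding constants.

The spatial loss is the sparse quadratic form summed over variable rows.
The contrastive loss draws one independent uniform permutation of spot
labels per negative sample from a single seed; since a permuted graph's
precision is the conjugated matrix, each negative term is evaluated as the
quadratic form of the inversely permuted variable — no refactorization.
The negative weight α multiplies the *average* of the T negatives (defaults
T=20, α=0.05); with α=1 the expression reduces to the plain
positive-minus-mean-negative contrast.

## Smoothing, imputation, enhancement

The observation model is a hidden Markov random field with i.i.d. Gaussian
noise at observed spots; the MAP estimate solves `(M + λ_sp Q)x = My`
by sparse LU with a residual guard at 1e−8. λ_sp ∝ σ₀²/σ₁² defaults to 1.
With `fix_observed` the observed entries are clamped and only the unobserved
block is solved (`Q_uu x_u = −Q_uo y_o`), which is the mode used by
resolution enhancement. Multi-row inputs share the factorization.

Resolution enhancement inserts new spots at the midpoints of existing graph
edges (repeated `factor−1` times, coincident points merged at 1e−9),
rebuilds graph and prior on the enlarged slide, and imputes the new spots
with originals fixed. Edge midpoints (not Delaunay triangle centers) define
the insertion rule; on a hexagonal lattice this reproduces the natural
finer hex packing. Enhancement defaults to the intrinsic prior ρ=1: with
ρ<1 the zero-centered prior visibly shrinks inserted values toward zero
(≈3% at ρ=0.99 on a constant field), whereas the intrinsic prior performs
exact harmonic interpolation and preserves constants.

## Deconvolution

`Y ≈ RX` with X ≥ 0, after intersecting genes between data and reference.
Scale conventions: log1p-transformed data and reference for NNLS, DWLS and
SVR; raw scale for LNR, which compares log1p(Y) to log1p(RX) internally.
Data-fit losses:

- NNLS: ‖Y−RX‖²_F;
- DWLS (*modified*): per-gene weights `w_g = 1/max(ŷ_g, 1e−3)²` from the
  fitted means of an NNLS warm start, normalized to mean 1 and capped at
  100, a single reweighting pass. The cap replaces the original
  cross-validated dampening constant, keeping the estimator deterministic;
- SVR: joint ε-insensitive hinge `Σ max(0, |Y−RX|−ε)` (ε=0.1) plus a small
  ridge on X (1e−4). The joint form (rather than per-spot dual ν-SVR) is
  required for compatibility with the additive spatial penalty;
- LNR: ‖log1p(Y) − log1p(RX)‖²_F on raw inputs.

The spatial penalty `λ_sp Σ_c X_c Q X_cᵀ` places the prior on each cell
type's abundance row and couples spots, so the problem is solved jointly by
projected Adam (learning rate 1e−3, clamp at zero each step, stop when the
relative loss change stays below 1e−5 for 10 iterations or at 10,000
iterations), warm-started from per-spot active-set NNLS, returning the best
iterate seen. λ_sp defaults to 1 for spatially aware NNLS/SVR/LNR and 3 for
DWLS (whose mean-normalized weights inflate the data-fit term), and to 0
when no prior is supplied. Output abundances are clamped at 0 and per-spot
proportions renormalized to 1 (all-zero columns become uniform, with a
warning).

Marker selection ranks genes per cell type by one-vs-rest log2 fold change
of mean library-normalized expression and takes the union of the top n
(default 20) per type; the reference signature is the per-type mean over
those genes, log1p-transformed when the downstream model is log-scale.

## Dimensionality reduction

*Spatial PCA* ties encoder and decoder (`Ŷ = WᵀWY`), adds soft
orthogonality `λ_orth‖WWᵀ−I‖²` and the spatial loss on every latent row of
Z = WY with equal weight. W is initialized from the SVD of the centered
data (exact below 512 min-dimension, seeded randomized above) and refined by
Adam on the joint objective; a new iterate is accepted only on a real
improvement so that at λ_sp=0 the solution is exactly the top-H PCA
subspace rather than a numerically drifted copy. Plain SGD remains available
(`optimizer="sgd"`); Adam is the default because fixed-step SGD needs
per-dataset learning-rate tuning to converge within the default 1000
iterations.

*attach_spatial_loss* wraps any objective that can report the embedding its
parameters induce on the spatial spots, returning
`L_m + λ_sp·L_sp(Z[:, spatial columns])` (contrastive optional, seeded).
Non-spatial samples contribute nothing, so a model can train jointly on
spatial and non-spatial data; a variational objective is wrapped the same
way with the latent mean as the reported embedding.

*Regularized autoencoder*: fully connected encoder G→128→H and mirrored
decoder with full-batch batch normalization and ELU, manual backpropagation,
Adam (lr 1e−3, 100 epochs default), deterministic per seed. The loss is
per-spot mean squared reconstruction + λ_sp·spatial (or contrastive) on the
post-activation latent Z + an orthogonality penalty `λ_orth‖ZZᵀ/S − I‖²`
that discourages degenerate latents. A collapse monitor flags runs whose
mean latent row standard deviation falls below 1% of its value at
initialization.

Collapse behavior, demonstrated in the tests on spatially structured data:
an overwhelming plain spatial loss (λ_sp=1e3) drives Z to zero (the prior
is zero-centered and the decoder's batch norm makes reconstruction
scale-invariant), while the contrastive loss makes smooth non-constant
embeddings profitable and keeps variance. A caveat discovered during
development: because the encoder maps spots independently, on *i.i.d.* input
data a spatially smooth embedding is only reachable by memorizing the noise
realization, which is too slow for the escape to materialize — both variants
collapse. The anti-collapse property of the contrastive loss is therefore a
statement about data that contain spatial structure, which is the intended
regime.

## Simulator

The study conditions are built in as defaults: a 50×50 grid; 5 high-density
(mean 4 cells per occupied spot) and 10 low-density (0.4) cell types, each
assigned a unique but overlapping doughnut-shaped zone; per-zone expected
abundance = softplus of a 2-D RBF Gaussian-process draw (lengthscale 10 grid
units by default — unstated in the source material, chosen so zones contain
visible internal gradients), masked to the zone and rescaled so the mean
over in-zone spots equals the density target; integer cell counts are
Poisson draws of the field. Zone geometry is parametrized (random centers,
outer radii 0.35–0.6 of the grid, inner radii up to half the outer) rather
than copied; the union of the high-density zones is patched to cover the
grid, because the emulated slides are fully tissue-covered and completely
empty spots would be removed by quality control in any real pipeline.

Expression at a spot is the sum of count vectors of cells drawn uniformly
with replacement from the matching reference type. The synthetic single-cell
reference uses a shared baseline (per-gene mean uniform on 0.05–0.5 counts),
disjoint marker blocks at fold change 4, and negative-binomial cells at
dispersion 2 — sparse and weakly separable on purpose, so that per-spot
deconvolution has realistic difficulty rather than being trivially solvable.

Noise: lateral diffusion (spot bleeding) moves a fraction p of each spot's
counts, split equally among rook (4-) neighbors — boundary spots split p
among existing neighbors so totals are conserved exactly; per-gene
multiplicative gamma noise (shape 0.4586, scale 1/0.6992) models sampling
error. The benchmark values are p ∈ {0, 0.1, 0.5}.

The sci-Space-style pipeline pools cells by barcode: per-spot target cell
counts are gamma-Poisson (mean 10; the gamma shape is exposed as
`dispersion`, default 2, since the original dispersion is unstated), cells
are resampled with replacement from the spot's own pool or a uniformly
chosen adjacent pool with probability ½ each, and spots above 5,000 total
UMI are thinned to exactly 5,000 by multivariate-hypergeometric sampling,
which preserves per-gene proportions in expectation.

Ground truth records both views: the realized integer cell counts and the
generative expected-abundance fields. Benchmarks score against the *field*
proportions — the discrete Poisson cell draw is part of the observation
process, and at 0.4–4 cells per spot its sampling noise would otherwise
dominate the quantity being estimated.

## Benchmark and problem sizes

The packaged doughnut benchmark is a reduced version of the full simulation
study: 20×20 grid, 5 types (2 high-, 3 low-density), 3 replicates, GP
lengthscale scaled with the grid (10·20/50 = 4) to preserve pattern
sharpness, deconvolution on the full 150-gene panel with the ICAR(0.99)
prior on the transcriptomic soft-scaled graph. At this size the whole
λ × bleeding grid runs in seconds. These sizes are the package's test
configuration; the generators accept the full-scale settings unchanged.

## Evaluation

Deconvolution: per-cell-type MSE, Pearson r, and average precision of the
binary presence call (truth proportion ≥ 0.05) with the predicted proportion
as score; types never present in truth are excluded from AP, constant
predictions are flagged and excluded from Pearson aggregation. AP is the
standard step-interpolated precision-at-each-positive definition.
Embeddings: silhouette against known labels and adjusted Rand index after
seeded k-means (10 restarts) into the true number of groups — k-means is
used instead of a Gaussian-mixture clusterer to keep the metric
deterministic and dependency-light.

## Known limitations

- The spatial prior is zero-centered: under ρ<1 it shrinks levels as well as
  differences. This is intended for deconvolution (abundances not supported
  by data decay to zero) but is why enhancement defaults to ρ=1.
- SMA smoothing solves a non-symmetric sparse system (ΣM + λI); it is
  supported for completeness but ICAR/ISAR are preferred.
- The autoencoder trains full-batch on dense arrays; it targets slides of a
  few thousand spots, not atlas-scale data.
- Empirical-Bayes or cross-validated selection of ρ and λ_sp is out of
  scope; both are exposed as parameters with the defaults above.
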