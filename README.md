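# smoothkit

Spatial omics data — Visium spots, Slide-seq beads, spatial-CUT&Tag pixels —
carry a structural signal that most single-cell methods ignore: physically
adjacent locations tend to share similar profiles. `smoothkit` turns that
dependency into a **reusable, boundary-aware prior** that can be attached to
essentially any downstream estimator, instead of being hard-coded into one
task-specific model.

It is aimed at computational biologists who want to make an existing
analysis spatially aware: smoothing and imputing per-spot scores, enhancing
slide resolution, deconvolving cell-type mixtures against a single-cell
reference, or learning spatially coherent low-dimensional embeddings.

## The model

1. **Graph.** Spots are connected by a mutual k-nearest-neighbor rule
   (k = 6 on hexagonal Visium-style grids, 4 on square grids), giving a
   binary spatial weights matrix W. Edges crossing putative domain
   boundaries are down-weighted by transcriptomic or histological similarity
   (soft scaling) or by domain labels (hard scaling): W′ = W ∘ D.

2. **Prior.** W is translated into the sparse precision matrix Q = Σ⁻¹ of a
   zero-centered multivariate normal prior under a choice of spatial
   process — CAR (Q = I − ρW), SAR, ICAR (Q = D − ρW, the default with
   ρ = 0.99), ISAR, or SMA — where the autocorrelation ρ sets how fast
   implied correlations decay with graph distance.

3. **Loss.** The prior enters any objective as a detachable quadratic
   penalty, L_sp(x) = xᵀQx, so the maximum-a-posteriori estimate of a model
   with loss L_m is `argmin L_m + λ_sp·L_sp`. A contrastive variant
   subtracts the same quadratic form evaluated under spot-permuted
   ("corrupted") graphs, L_csp = xᵀQ₀x − (α/T)Σₜ xᵀQₜx, which rewards
   genuinely spatial structure and averts embedding collapse.

On top of this, the package ships spatially aware versions of:

- **Smoothing / imputation / resolution enhancement** — the Tikhonov solve
  (M + λ_sp Q)x = My, with midpoint interpolation for super-resolution;
- **Cell-type deconvolution** — Y ≈ RX with X ≥ 0, four data-fit losses
  (NNLS, modified DWLS, ε-insensitive SVR, log-normal regression) solved by
  projected Adam with the per-cell-type spatial penalty;
- **Dimensionality reduction** — an exact spatial PCA, a regularized deep
  autoencoder (128→H layers, batch-norm, ELU), and a generic
  `attach_spatial_loss` wrapper for any embedding objective;
- **A ground-truthed simulator** — doughnut-patterned zones × 2-D Gaussian
  process abundance, Poisson cell counts, expression resampled from a
  synthetic single-cell reference, spot bleeding (lateral diffusion), per-
  gene gamma noise, and a pooled-barcode ("sci-Space"-style) variant with
  gamma-Poisson cell counts and UMI down-sampling.

## Worked example

Simulate a 20×20 doughnut benchmark slide with 10% spot bleeding, build the
soft-scaled ICAR prior, and compare non-spatial and spatially regularized
NNLS deconvolution (3 replicates, scored against the generative abundance
fields):

```python
from smoothkit.benchmark import doughnut_deconv_benchmark

res = doughnut_deconv_benchmark(diffusion_rate=0.1)
for lam, r in res.items():
    print(f"lambda_sp={lam:>4}: mean per-type Pearson r = {r:.3f}")
```

```
lambda_sp= 0.0: mean per-type Pearson r = 0.316
lambda_sp= 0.3: mean per-type Pearson r = 0.318
lambda_sp= 1.0: mean per-type Pearson r = 0.323
lambda_sp= 3.0: mean per-type Pearson r = 0.345
```

The non-spatial NNLS baseline recovers the planted cell-type maps with mean
per-type Pearson r = 0.316; adding the spatial prior improves recovery at
every tested strength, up to r = 0.345 at λ_sp = 3. The same machinery is
available piecewise (`build_knn_graph`, `scale_edges`, `build_prior`,
`deconvolve`, `eval_deconv`) and from the command line:

```bash
smoothkit simulate --preset doughnut --grid 20x20 --seed 0 --out-dir sim/
smoothkit graph   --coords sim/coords.tsv --k 4 --out graph.tsv
smoothkit prior   --graph graph.tsv --process icar --rho 0.99 --out prior
smoothkit deconv  --counts sim/counts --ref sim/reference.tsv \
                  --model nnls --prior prior --lambda 1.0 --out props.tsv
smoothkit eval    --pred props.tsv --truth sim/truth_proportions.tsv --out report.tsv
```

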