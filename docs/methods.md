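# Methods

## Model

Each cell's expression is generated hierarchically: a categorical cell type
`y` (prior concentrations α₀, all ones by default, over the L types in the
label vocabulary), a Gaussian nuisance factor `z₁ ~ N(μ₀, Σ₀)` absorbing
batch and other technical variation (μ₀ = 0, Σ₀ = I, dimension d₁ = 10),
and the complete hidden state `z_y ~ N(μ(y,z₁), Σ(y,z₁))` of dimension
d = 50, whose mean and diagonal covariance are produced by a neural network
from the one-hot type and the nuisance factor. A decoder network maps `z_y`
to Dirichlet concentrations α over the G genes; gene usage `η ~ Dirichlet(α)`
and counts `X ~ Multinomial(n, η)` at the observed library size n.

Two modeling choices depart from a naive transcription of that process:

* **η is marginalized analytically.** The compound of the Dirichlet and the
  multinomial is the Dirichlet-multinomial, so the count likelihood is
  evaluated in closed form instead of sampling a G-dimensional simplex
  variable. This is exact and removes the dominant source of gradient
  variance.
* **The multinomial conditions on the observed per-cell total.** Library
  size is treated as ancillary, not modeled.

## Inference

Variational factorization `q(z_y|X) q(y|z_y) q(z₁|y,z_y)`:

* encoder: normalized count row → (μ_q, σ_q) of `q(z_y|X)`;
* classifier: `z_y` → softmax over L types;
* nuisance encoder: (one-hot y, z_y) → (μ, σ) of `q(z₁|y,z_y)`.

All maps (including the generative conditional prior and decoder) are
2-hidden-layer perceptrons of width 128 with tanh activations. Positivity is
enforced by softplus; standard deviations are clamped to [1e-3, 10] and
decoder concentrations to [1e-6, 1e6] for numerical safety. The encoder
input is each row scaled to the median training library size and log1p
transformed. The factor `q(X)` in the variational family is the empirical
data distribution and is constant in the objective; it plays no
computational role.

The ELBO uses reparameterized samples of `z_y` and `z₁` (one by default).
For labeled cells the label is observed and a supervised term
`−w · log q(y = y_obs | z_y)` (w = 1 per cell) is added so the classifier
trains even when the ELBO routes around it. For unlabeled cells the label is
enumerated over all L classes weighted by `q(y|z_y)`, plus the entropy of
that distribution — exact discrete marginalization, affordable because L is
small. Whether real training sets include unlabeled cells is a user
decision; both paths are exercised by the benchmarks (80% labeled).

Optimization is minibatch Adam (learning rate 1e-3, batch 128, 200 epochs
by default) with a linear KL warm-up over the first 50 epochs to avoid
posterior collapse. Minibatches permute a canonical cell order (cells
sorted by id), which makes the fit exactly invariant to the order cells
arrive in. All randomness derives from a single integer seed; identical
seeds give bitwise-identical fits.

Gradients are computed by a small in-package reverse-mode autodiff engine
over numpy arrays (`scfactor.autodiff`): a tape of ~20 primitives
(broadcasted arithmetic, matmul, tanh/softplus/exp/log, log-gamma,
reductions, log-sum-exp, slicing/concatenation, bounds clip with zero
gradient outside the bounds). Every primitive is verified against central
finite differences in the test suite.

## Post-training operations

* **Embedding** — the posterior mean of `q(z_y|X)`; the mean (not a sample)
  is used so downstream results are deterministic.
* **Annotation** — classifier applied to the embedding mean; argmax with
  ties broken toward the lowest vocabulary index.
* **Batch-corrected expression** — each cell re-decoded at reference
  nuisance conditions: usage = Decoder(μ(y = ŷ, z₁ = μ₀)) normalized.
  Rows are simplex points ("usage scale"); multiply by observed totals if a
  count-scale matrix is needed. By construction the output depends only on
  the predicted type, so all nuisance variation is removed.
* **Visualization** — UMAP to 2-D with fixed parameters (15 neighbors,
  min_dist 0.1, Euclidean, seeded; the neighbor count auto-shrinks with a
  warning on tiny inputs).
* **Subclustering** — a truncated stick-breaking variational
  Dirichlet-process Gaussian mixture (scikit-learn) on the 2-D coordinates,
  full covariances, truncation 20, concentration 1/truncation. The number
  of subpopulations is the count of components with weight ≥ 0.01 and at
  least one assigned cell. `mean_precision_prior` is set to 10 because the
  scikit-learn default lets the variational fit split one tight isotropic
  mode into two equal-weight overlapping components; the stronger mean
  prior removes that artifact while leaving well-separated clusters
  recovered exactly (verified under rigid rotations/translations).
  All-identical coordinates return a single cluster with a warning.

## Synthetic benchmarks

The generator mirrors the model's assumptions: L per-type gene-usage
profiles (gamma draws; a `sparsity` fraction of genes per type is forced
near zero, giving distinct, separable signatures), B batches perturbing
profiles by elementwise lognormal(0, `batch_strength`) factors
(multiplicative on usage, renormalized — this keeps profiles on the simplex
and matches the Dirichlet-multinomial machinery), per-cell usage drawn from
a Dirichlet at concentration 50 × perturbed profile (so data exercise the
compound likelihood, not a plain multinomial), and multinomial counts at
lognormal library sizes (σ = 0.3 around the mean). Defaults — 3 types, 2
batches, 600 cells, 200 genes, batch strength 1.0, mean library 2000, 80%
labeled — define the standard benchmark; 2000 cells are used for the
usage-recovery experiment. These sizes keep a full benchmark fit around a
minute on one CPU while leaving hundreds of cells per (type, batch) group.

What the generator does **not** emulate: real marker-gene structure,
zero-inflation beyond the Dirichlet's, doublets, ambient RNA, or
batch-by-type interactions. Passing benchmarks therefore demonstrate
correct inference under the model's own assumptions, not performance on
real tissue atlases.

Batch identity is never shown to the model; batch labels are used only for
evaluation. Evaluation metrics: exact-match accuracy, an adjusted Rand
index implemented from the pair-counting contingency formula (scikit-learn's
implementation serves as an independent cross-check in tests, never as the
implementation), and batch-mixing entropy — the mean per-cell Shannon
entropy (base = number of batches, hence in [0,1]) of batch labels among
each cell's k = 15 Euclidean nearest neighbors, self excluded.

## Known limitations

* The decoder reconstructs counts from `z_y` alone, so `z_y` necessarily
  retains some batch information (the nuisance factor is inferred
  *downstream* of `z_y`). Under strong simulated batch effects the
  posterior-mean embedding can keep (type, batch) groups locally separated
  even though type clusters dominate; the batch-free outputs of the model
  are the label posterior and the corrected usage, not the raw embedding.
  On the standard benchmark the embedding's batch-mixing entropy is never
  below the truncated-SVD baseline's, but both can sit at the metric's
  floor of zero, where the comparison loses resolution.
* The Dirichlet likelihood models no gene-level overdispersion beyond the
  compound's; heavily zero-inflated platforms are out of scope.
* Training is single-CPU minibatch SVI; no early stopping (fixed epochs for
  reproducibility) and no hyperparameter search.
* The 2-D UMAP coordinates, not the 50-dim embedding, are what the DP
  mixture clusters; the estimated component count therefore inherits
  UMAP's tendency to shatter clusters that the embedding separates.
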