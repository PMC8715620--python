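# Methods

## Generative model

A cell *c* has a latent vector z_c ∈ R^K and category proportions
θ_c = softmax(z_c). Each modality i has a category-by-feature logit matrix
B^(i) (K × d_i); counts for cell *c* in modality i are a single multinomial
draw of the cell's library size with probabilities

    π_c^(i) = Σ_k θ_ck · softmax_features(β_k^(i) + o_b(c)^(i)).

This is a mixed-membership (topic-model-like) view of sparse count data:
categories are shared across modalities through θ, while each modality has
its own feature distributions. It deliberately avoids per-gene dispersion
parameters (as in ZINB models), which scale poorly to the very wide, very
sparse feature spaces of accessibility data.

**Batch adjustment.** The only statement the model makes about batches is
an additive per-batch offset o_b on the feature logits inside each
category's softmax, shared across categories, with the reference batch
pinned at zero. This preserves the simplex exactly, models multiplicative
capture-efficiency effects, and costs d_i parameters per extra batch. Other
parameterizations (per-category offsets, encoder-side batch covariates) are
plausible; this is the smallest one that can absorb a global shift in
feature detection rates, and it is the single place where the package
commits to a choice the underlying model family leaves open.

**Prior.** θ_c would classically receive a Dirichlet prior. To keep the
model inside the VAE family the Dirichlet(α), with symmetric α_k = 50/K, is
replaced by its Laplace approximation in the softmax basis (the ProdLDA
construction), a diagonal Gaussian with

    mu_k  = log α_k − (1/K) Σ_i log α_i
    var_k = (1/α_k)(1 − 2/K) + (1/K²) Σ_i 1/α_i.

For symmetric α the mean is exactly zero. Note these forms use 1/α and
log α where the exact moments of centered log-Dirichlet draws involve
trigamma and digamma functions; the construction is a large-α
approximation, accurate to roughly 1/(2α) in relative variance (10% at
α = 5, i.e. K = 10 under the default total concentration 50). The unit
tests check agreement with Monte-Carlo draws at exactly this
approximation-order tolerance; agreement at Monte-Carlo precision is not a
property this construction has.

## Inference

One encoder per modality maps log1p(counts) through a single 128-unit ReLU
layer to diagonal-Gaussian (mean, log-variance) heads. The posterior for an
arbitrary observed subset A is the product of experts (PoE) of the prior
and the |A| modality factors: precisions add, means combine
precision-weighted. Two properties follow directly and are tested: the PoE
variance never exceeds any member's, and with zero experts the posterior is
the prior.

**Objective.** For each cell, every observed singleton {i} contributes one
ELBO term, and cells with ≥2 modalities contribute one joint term over
their full subset. A term for subset A is

    λ_A [ Σ_{i∈A} η·log p(x^(i) | z) − γ·KL(q_A ‖ prior) ],  z ~ q_A,

with λ_A = 1/n_A (n_A = number of cells contributing that term: all cells
observing modality i for singletons, exactly-A cells for joint terms),
η = 1, and one reparameterized Monte-Carlo sample per term per step. This
realizes the sub-sampled multimodal-VAE objective: every encoder is trained
both alone and inside the joint posterior, which is what makes
single-modality embedding work at test time. The multinomial likelihood
omits its parameter-free normalizing constant, so reported ELBO values are
comparable within this package but not across likelihood
parameterizations.

**Training.** Adam (lr 0.005, default betas), minibatches of 128 cells,
100 epochs, KL weight γ ramped linearly from 0 to 1 over the first 30
epochs (mitigating posterior collapse while the decoder is still random).
The engine is plain numpy with hand-derived gradients; an automated
finite-difference check over every parameter tensor is part of the test
suite. A fixed seed makes training bitwise reproducible at a fixed thread
count (initialization, shuffling and sampling all derive from one
generator).

Numerical choices: probabilities are floored at 1e-10 before logs;
encoder log-variances are clamped to ±10 (gradients masked at the clamp);
encoder weights use fan-in uniform initialization, decoder logits and batch
offsets N(0, 0.1²); a non-finite loss aborts with the offending term and
minibatch identified rather than continuing.

## Missing-modality correction

Posterior means conditioned on different subsets (joint, mRNA-only,
ATAC-only) sit in subtly different regions even for the same cells —
nothing in the objective forces them to coincide. Since softmax is
shift-invariant, all latents are first centered to column mean zero; the
offset is computed globally over every cell's primary estimate and applied
to all views, preserving the between-view displacements the regression must
learn. Gradient-boosted trees (squared loss, learning rate 0.8, max depth
3, 100 rounds, one regressor per latent coordinate) are then trained on the
paired cells to predict the joint-posterior mean from each modality-specific
mean, and applied to the single-modality cells. With these settings the
identity map is learned to RMSE ≈ 1e-3 (the plateau set by the trees'
default L2 leaf shrinkage). A k-NN regressor (15 neighbors) is an
equivalent backend and the recommended fallback below ~50 paired cells.
The prediction target is the joint space; targeting a single-modality space
instead is exposed as an option but makes little practical difference.

## Synthetic data

The simulator draws from the generative model itself, so every estimate has
a known target. Defaults (the benchmark conditions):

| parameter | default | rationale |
|---|---|---|
| K_true | 3 | few enough to visualize; clusters are θ-profiles |
| n_cells | 2000 | desk-scale; ~20 s fit on one core |
| clusters | 5 | 3 simplex corners + 2 two-corner blends, scale 3.0 |
| z spread | 0.5 | true-label silhouette on true z ≈ 0.50: separable but overlapping |
| d (mRNA-like) | 300, logit sd 1.0 | moderate skew, ~6% zeros |
| d (ATAC-like) | 1000, logit sd 6.5 | strong skew → ≥90% zeros at the default library |
| libraries | LogNormal(log 2000, 0.3) / LogNormal(log 5000, 0.3) | mRNA vs ATAC count regimes |
| paired fraction | 0.2 | benchmark split: 20% paired, 80% single-modality |

For the unpaired 80%, the two modality rows are presented under distinct
cell IDs while the true map is recorded — the dataset then contains
n_paired + 2·n_unpaired cells, exactly the situation of joint- plus
single-modality experiments. The confounded-batch variant assigns all
paired cells to batch 0 and all singles to batch 1 (offset sd 0.8, milder
logits (1.0, 3.0), 1000 cells), mimicking joint- and single-modality data
generated as separate runs.

What the simulator does **not** emulate: per-gene overdispersion and
zero inflation beyond the multinomial, doublets, nested batch structure,
feature-space mismatch between datasets (peaks called per dataset), and
any misspecification of the decoder family — the fitted model shares the
simulator's functional form. Passing benchmarks here therefore demonstrate
correct inference and alignment under the model's own assumptions, not
robustness to real-data artifacts.

## Evaluation

Paired-cell k-NN recovery: Euclidean distances in the corrected latent
space, k nearest reference cells per query (stable index order on
distance ties), fraction of queries whose true partner is included; chance
level is k/n, and the curve over k is monotone, reaching 1 at k = n−1. The
reverse direction swaps query and reference roles. Silhouette widths of
external labels are computed on a 2-D UMAP (30 neighbors) to match how such
scores are usually read off embeddings; a K-dimensional variant is a flag
away. Louvain clustering runs on a 30-NN graph of the corrected latents.

## Problem sizes and measured behavior

The test suite and the acceptance script run entirely on simulated data:
the main benchmark at 2000 generative cells (3600 dataset cells, 100
epochs, ~20 s), the batch-efficacy comparison at 1000 cells × 10 seeds × 2
fits (150 epochs each), and the ELBO/evidence bound on a 20-cell instance
with a wide prior (total concentration 2), where the untrained variational
gap is well away from zero. On the main benchmark, k-means on corrected
latents recovers the planted clusters with ARI ≈ 0.8–0.85 and ~1%-k
pairing recovery 12–30× chance, but cluster recovery is seed-sensitive:
for some simulation seeds two of the five overlapping clusters merge in
the learned space and ARI drops to ~0.6. With K fixed at 10 and a fixed
100-epoch budget this is genuine method variance under the benchmark's
cluster overlap, not measurement noise, and the acceptance script reports
whatever the requested seed produces.

## Known limitations

- Encoders are not depth-normalized; total-count differences reach the
  posterior (log1p damps but does not remove them).
- K is a config input; marginal-likelihood-based selection is out of scope.
- Feature harmonization across datasets is exact-ID join only; callers must
  pre-map peaks/genes to a shared vocabulary.
- The Laplace prior is a large-α approximation (see above).
- CPU only, single-threaded by design for reproducibility; the numpy engine
  is adequate at 10³–10⁴ cells but is not built for 10⁵+.
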