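# omicfuse

Joint embedding of single-cell multi-omic count data with a multimodal
variational autoencoder.

Single-cell experiments increasingly measure several molecular modalities —
mRNA expression and chromatin accessibility being the common pair — but most
cells in a typical analysis come from single-modality platforms (scRNA-seq,
scATAC-seq), with only a minority profiled jointly (SNARE-seq, 10x
Multiome). `omicfuse` places **all** of these cells into one shared latent
space: cells with both modalities, cells with only one, and cells from
different technical batches, so that clustering, visualization and label
transfer can operate on everything at once. It is aimed at computational
biologists integrating paired and unpaired transcriptome/accessibility
datasets, and at methodologists who want a compact, fully inspectable
reference implementation with a ground-truth-known simulator.

## Model

Each cell *c* carries a latent vector *z<sub>c</sub>* ∈ ℝ<sup>K</sup> with a
Gaussian prior obtained as the Laplace approximation (in the softmax basis)
of a symmetric Dirichlet with concentration 50/K. Its mixing proportions
over K latent categories are θ<sub>c</sub> = softmax(z<sub>c</sub>). For
modality *i* with feature-logit matrix B<sup>(i)</sup> (rows
β<sub>k</sub>), counts are one multinomial draw

&nbsp;&nbsp;&nbsp;&nbsp;x<sub>c</sub><sup>(i)</sup> ~ Multinomial(N<sub>c</sub><sup>(i)</sup>, π<sub>c</sub><sup>(i)</sup>), &nbsp; π<sub>c</sub><sup>(i)</sup> = Σ<sub>k</sub> θ<sub>ck</sub> · softmax(β<sub>k</sub><sup>(i)</sup> + o<sub>b(c)</sub><sup>(i)</sup>),

where o<sub>b</sub><sup>(i)</sup> is an additive per-batch logit offset
(reference batch fixed at zero) absorbing technical effects. Modalities are
conditionally independent given *z*: p(x, z) = p(z) ∏<sub>i∈S<sub>c</sub></sub> p(x<sup>(i)</sup> | z),
where S<sub>c</sub> is the subset of modalities observed on cell *c*.

Inference uses one encoder per modality (log1p counts → 128-unit ReLU layer
→ mean and log-variance heads) and combines any subset of encoders with the
prior by a **product of experts**: precisions add, so M encoders serve all
2<sup>M</sup>−1 modality combinations. Training maximizes a subset-weighted
ELBO — one term per observed singleton per cell plus a joint term for
paired cells, each weighted by λ<sup>A</sup> = 1/n<sub>A</sub> — with the
KL weight γ annealed linearly over the first 30 epochs, Adam (lr 0.005),
minibatches of 128, 100 epochs. The whole engine is plain numpy with
hand-derived, finite-difference-verified gradients.

Because posteriors conditioned on different modality subsets occupy subtly
different regions, a post-hoc **missing-modality correction** trains
gradient-boosted trees (squared loss, lr 0.8, depth 3; or a k-NN regressor)
on the paired cells to map modality-specific posterior means into the joint
frame, after centering all latents to column mean zero.

Integration quality is quantified by **paired-cell k-NN recovery**: hiding
the true pairing between mRNA-only and ATAC-only cells, the fraction of
query cells whose partner lies within their k nearest neighbors in the
shared space (chance level k/n).

## Worked example

Everything below is simulated from the package's own generative model, so
the true clusters and the true cell pairing are known:

```python
import numpy as np
import omicfuse as of
from sklearn.cluster import KMeans

spec = of.SimulationSpec(K_true=3, n_cells=500, feature_dims=(120, 300),
                         n_clusters=4, paired_fraction=0.25, seed=7)
dataset, truth = of.simulate(spec)
print("cells per modality subset:", dataset.subset_counts())

config = of.TrainingConfig(K=5, epochs=150, annealing_epochs=30, seed=7)
model = of.fit(dataset, config)
print(f"final epoch ELBO: {model.epoch_elbo[-1]:.2f}")

latents = of.posterior_means(model, dataset, subset_policy="with_singles")
ids, Z, groups, _ = of.integrate(latents, seed=7)

labels = truth.labels_for(ids)
pred = KMeans(n_clusters=4, n_init=10, random_state=0).fit_predict(Z)
print(f"cluster ARI vs ground truth: {of.cluster_agreement(pred, labels):.3f}")

index = {c: i for i, c in enumerate(ids)}
rna_ids = list(truth.pairing)
atac_ids = [truth.pairing[c] for c in rna_ids]
Zq, Zr = Z[[index[c] for c in rna_ids]], Z[[index[c] for c in atac_ids]]
n, k = len(rna_ids), max(1, len(rna_ids) // 100)
rec = of.knn_pairing_recovery(Zq, Zr, np.arange(n), k)
print(f"pairing recovery at k={k} of n={n}: {rec:.3f} (chance {k/n:.4f})")
```

Output:

```
cells per modality subset: {(0,): 375, (0, 1): 125, (1,): 375}
final epoch ELBO: -54.65
cluster ARI vs ground truth: 0.877
pairing recovery at k=3 of n=375: 0.048 (chance 0.0080)
```

125 of the 500 cells are paired; the other 375 appear twice, once per
modality, under distinct IDs. After training, k-means on the corrected
latents recovers the 4 planted clusters with ARI 0.88, and 4.8% of the
hidden mRNA-only cells find their true ATAC partner among their 3 nearest
neighbors — six times the 0.8% expected by chance.

The same workflow is available from the shell:

```bash
omicfuse --seed 3 simulate --out-dir sim --n-cells 500
omicfuse --seed 0 fit config.yaml --out model.npz
omicfuse --seed 0 embed config.yaml --model model.npz --out latents.csv
omicfuse evaluate-pairing --query latents.csv --reference latents.csv \
    --pairing sim/pairing.csv --k 5
```

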