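"""Ground-truth-known simulation of two-modality single-cell count data.

Data are drawn from the package's own generative model: each cell has a
cluster label, a Gaussian latent z around its cluster mean, mixing
proportions theta = softmax(z), and per-modality multinomial counts with
mixture probabilities softmax-mixed from category feature logits B, plus
additive per-batch logit offsets.  Modality 1 mimics mRNA counts (moderate
library over ~hundreds of genes); modality 2 mimics chromatin accessibility
(larger library spread over many more, strongly skewed peaks — hence much
sparser per feature).

A configurable fraction of cells keeps both modality rows under one cell ID
("paired", as from a joint-modality platform); for the rest the two rows are
presented under distinct IDs while the true map is recorded, emulating
single-modality datasets with known hidden pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import softmax
import scipy.sparse as sp

from .data_io import ModalityMatrix, MultiOmicDataset, assemble_dataset
from .generative import ModalityDecoder, sample_counts


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the two-modality simulation.

    cluster_scale / cluster_spread control separability of the true clusters
    in latent space; defaults give overlapping-but-separable clusters
    (silhouette of true labels on true z around 0.5).  beta_scales are the
    standard deviations of the category feature logits: the larger value for
    modality 2 concentrates probability on few peak-like features, producing
    the >=90% sparsity typical of accessibility counts.
    """

    K_true: int = 3
    n_cells: int = 2000
    feature_dims: tuple[int, int] = (300, 1000)
    n_clusters: int = 5
    cluster_scale: float = 3.0
    cluster_spread: float = 0.5
    beta_scales: tuple[float, float] = (1.0, 6.5)
    library_log_means: tuple[float, float] = (np.log(2000.0), np.log(5000.0))
    library_log_sds: tuple[float, float] = (0.3, 0.3)
    n_batches: int = 1
    batch_offset_scale: float = 0.0
    batch_assignment: str = "random"  # or "by_subset" (paired=batch0, singles=batch1)
    paired_fraction: float = 0.2
    modality_names: tuple[str, str] = ("rna", "atac")
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        if not (0.0 <= self.paired_fraction <= 1.0):
            raise ValueError("paired_fraction must lie in [0, 1]")
        if any(d < self.K_true for d in self.feature_dims):
            raise ValueError("feature dims must be >= K_true")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.batch_assignment == "by_subset" and self.n_batches != 2:
            raise ValueError("by_subset batch design requires exactly 2 batches")
        if self.batch_assignment not in ("random", "by_subset"):
            raise ValueError(f"unknown batch_assignment {self.batch_assignment!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows, for oracle tests.

    ``pairing`` maps the modality-1 (rna-half) cell ID of every hidden pair
    to its modality-2 (atac-half) ID.  ``cell_of_id`` maps every dataset
    cell ID back to its generative cell index, so z / theta / labels can be
    looked up for half-cells too.
    """

    z: np.ndarray
    theta: np.ndarray
    labels: np.ndarray
    decoders: list[ModalityDecoder]
    batch_indices: np.ndarray
    paired_ids: np.ndarray
    pairing: dict[str, str]
    cell_of_id: dict[str, int]

    def labels_for(self, cell_ids) -> np.ndarray:
        return np.array([self.labels[self.cell_of_id[c]] for c in cell_ids])

    def z_for(self, cell_ids) -> np.ndarray:
        return np.vstack([self.z[self.cell_of_id[c]] for c in cell_ids])


def _cluster_means(K: int, n_clusters: int, scale: float) -> np.ndarray:
    """Cluster means at scaled simplex-corner directions; clusters beyond K
    sit on normalized two-corner blends so every cluster maps to an
    interpretable category profile."""
    means = np.zeros((n_clusters, K))
    for g in range(n_clusters):
        if g < K:
            means[g, g] = scale
        else:
            a, b = (g - K) % K, (g - K + 1) % K
            means[g, a] = means[g, b] = scale / np.sqrt(2.0)
    return means


def simulate(spec: SimulationSpec) -> tuple[MultiOmicDataset, GroundTruth]:
    """Draw one dataset (and its ground truth) from the generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, n = spec.K_true, spec.n_cells
    batch_levels = tuple(f"batch{b}" for b in range(spec.n_batches))

    decoders = []
    for m in range(2):
        d = spec.feature_dims[m]
        B = rng.normal(0.0, spec.beta_scales[m], size=(K, d))
        off = np.zeros((spec.n_batches, d))
        if spec.n_batches > 1 and spec.batch_offset_scale > 0:
            off[1:] = rng.normal(0.0, spec.batch_offset_scale, size=(spec.n_batches - 1, d))
        decoders.append(ModalityDecoder(B=B, batch_offsets=off, batch_levels=batch_levels))

    means = _cluster_means(K, spec.n_clusters, spec.cluster_scale)
    labels = rng.integers(0, spec.n_clusters, size=n)
    z = means[labels] + rng.normal(0.0, spec.cluster_spread, size=(n, K))
    theta = softmax(z, axis=1)

    n_paired = int(round(spec.paired_fraction * n))
    order = rng.permutation(n)
    paired_set = np.zeros(n, dtype=bool)
    paired_set[order[:n_paired]] = True

    if spec.batch_assignment == "by_subset":
        batch_idx = np.where(paired_set, 0, 1)
    else:
        batch_idx = rng.integers(0, spec.n_batches, size=n)

    libraries = [
        np.maximum(
            1, np.round(rng.lognormal(spec.library_log_means[m], spec.library_log_sds[m], n))
        ).astype(int)
        for m in range(2)
    ]

    counts = [
        np.vstack(
            [
                sample_counts(z[c], decoders[m], batch_levels[batch_idx[c]], libraries[m][c], rng)
                for c in range(n)
            ]
        )
        for m in range(2)
    ]

    ids_mod: list[list[str]] = [[], []]
    rows_mod: list[list[int]] = [[], []]
    pairing: dict[str, str] = {}
    cell_of_id: dict[str, int] = {}
    paired_ids = []
    half_suffix = spec.modality_names
    for c in range(n):
        if paired_set[c]:
            cid = f"cell{c:05d}"
            paired_ids.append(cid)
            cell_of_id[cid] = c
            for m in range(2):
                ids_mod[m].append(cid)
                rows_mod[m].append(c)
        else:
            hid = [f"cell{c:05d}_{half_suffix[m]}" for m in range(2)]
            pairing[hid[0]] = hid[1]
            for m in range(2):
                cell_of_id[hid[m]] = c
                ids_mod[m].append(hid[m])
                rows_mod[m].append(c)

    matrices = []
    for m in range(2):
        rows = np.array(rows_mod[m], dtype=int)
        matrices.append(
            ModalityMatrix(
                modality_name=spec.modality_names[m],
                counts=sp.csr_matrix(counts[m][rows]),
                cell_ids=np.array(ids_mod[m], dtype=object),
                feature_ids=np.array(
                    [f"{spec.modality_names[m]}_f{j}" for j in range(spec.feature_dims[m])],
                    dtype=object,
                ),
                batch_labels=np.array([batch_levels[batch_idx[c]] for c in rows], dtype=object),
            )
        )

    dataset = assemble_dataset(matrices)
    truth = GroundTruth(
        z=z,
        theta=theta,
        labels=labels,
        decoders=decoders,
        batch_indices=batch_idx,
        paired_ids=np.array(paired_ids, dtype=object),
        pairing=pairing,
        cell_of_id=cell_of_id,
    )
    return dataset, truth


def default_benchmark_spec(seed: int = 0) -> SimulationSpec:
    """Desk-scale benchmark: 2000 cells, 5 clusters over 3 latent categories,
    300 gene-like + 1000 peak-like features, 20% paired / 80% single."""
    return SimulationSpec(seed=seed)


def confounded_batch_spec(seed: int = 0, offset_scale: float = 0.8) -> SimulationSpec:
    """Smaller two-batch design where batch is confounded with platform:
    paired cells come from batch 0 and all single-modality cells from batch 1,
    as when joint-modality and single-modality experiments are separate runs.
    Feature logits are milder than the main benchmark's so the batch shift is
    comparable in size to the biological signal."""
    return replace(
        default_benchmark_spec(seed),
        n_cells=1000,
        feature_dims=(150, 300),
        beta_scales=(1.0, 3.0),
        n_batches=2,
        batch_offset_scale=offset_scale,
        batch_assignment="by_subset",
    )
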