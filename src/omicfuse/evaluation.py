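"""Quantitative evaluation of the integration.

The headline metric is paired-cell k-NN recovery: with the true pairing
between (say) mRNA-only and ATAC-only cells hidden from the model, count the
fraction of query cells whose true partner appears among their k nearest
neighbors in the shared latent space.  Chance level for a random embedding
is k/n.  Also here: average silhouette width of external labels on a 2-D
embedding, adjusted-Rand cluster agreement, and thin wrappers for Louvain
clustering and 2-D neighbor embedding of the corrected latents.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_samples


def _knn_indices(query: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Indices of each query's k nearest reference rows (Euclidean).

    Ties in distance are broken by stable (ascending) reference index via a
    partial partition followed by a stable sort of the candidate block.
    """
    D = cdist(query, reference)
    if k >= D.shape[1]:
        raise ValueError("k must be < number of reference cells")
    part = np.argpartition(D, k, axis=1)[:, : k + 1]
    out = np.empty((D.shape[0], k), dtype=int)
    for r in range(D.shape[0]):
        cand = np.sort(part[r])  # ascending index for stable tie-breaks
        order = np.argsort(D[r, cand], kind="stable")
        out[r] = cand[order[:k]]
    return out


def knn_pairing_recovery(
    query: np.ndarray,
    reference: np.ndarray,
    pairing: np.ndarray,
    k: int,
) -> float:
    """Fraction of query cells whose true partner is within their k nearest
    reference cells.

    ``pairing[r]`` gives the reference row paired with query row r and must
    be a bijection.  The reverse-direction metric is this same function with
    the roles of query and reference swapped.
    """
    query = np.atleast_2d(np.asarray(query, dtype=np.float64))
    reference = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    pairing = np.asarray(pairing, dtype=int)
    n = query.shape[0]
    if reference.shape[0] != n or pairing.shape[0] != n:
        raise ValueError("query, reference and pairing must have equal length")
    if len(set(pairing.tolist())) != n:
        raise ValueError("pairing must be a bijection")
    if not (1 <= k < n):
        raise ValueError("require 1 <= k < n")
    nn = _knn_indices(query, reference, k)
    return float(np.mean([pairing[r] in nn[r] for r in range(n)]))


def recovery_curve(
    query: np.ndarray,
    reference: np.ndarray,
    pairing: np.ndarray,
    ks,
) -> list[tuple[float, float]]:
    """Recovery at several k, returned as (k/n, proportion) points.

    Monotone non-decreasing in k by the superset property; reaches 1.0 at
    k = n - 1.
    """
    n = np.atleast_2d(query).shape[0]
    out = []
    prev = 0.0
    for k in sorted(int(k) for k in ks):
        p = knn_pairing_recovery(query, reference, pairing, k)
        assert p >= prev - 1e-12, "recovery must be monotone in k"
        prev = p
        out.append((k / n, p))
    return out


def average_silhouette(embedding: np.ndarray, labels) -> float:
    """Mean silhouette width of the given labels on (usually 2-D) coordinates.

    Cells in singleton clusters get width 0 (sklearn's convention); a single
    label overall is an error.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("silhouette requires >= 2 distinct labels")
    return float(np.mean(silhouette_samples(embedding, labels, metric="euclidean")))


def cluster_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same cells."""
    return float(adjusted_rand_score(np.asarray(labels_a), np.asarray(labels_b)))


def paired_split(
    cell_ids, paired_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Benchmark split: assign a fraction of cells as paired-modality data
    and the rest as single-modality data.  Returns (paired_ids, single_ids)."""
    ids = np.asarray(cell_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_paired = int(round(paired_fraction * len(ids)))
    return ids[order[:n_paired]], ids[order[n_paired:]]


def louvain_cluster(latents: np.ndarray, n_neighbors: int = 30, seed: int = 0) -> np.ndarray:
    """Louvain community detection on a k-NN graph of the corrected latents."""
    import igraph as ig
    from sklearn.neighbors import kneighbors_graph

    A = kneighbors_graph(np.asarray(latents), n_neighbors=n_neighbors, mode="connectivity")
    A = A.maximum(A.T).tocoo()
    g = ig.Graph(n=A.shape[0], edges=list(zip(A.row.tolist(), A.col.tolist())))
    g.simplify()
    part = g.community_multilevel()
    return np.asarray(part.membership)


def embed_2d(latents: np.ndarray, n_neighbors: int = 30, seed: int = 0) -> np.ndarray:
    """2-D neighbor embedding (UMAP, 30 neighbors) of the corrected latents."""
    import umap

    return umap.UMAP(n_neighbors=n_neighbors, n_components=2, random_state=seed).fit_transform(
        np.asarray(latents)
    )
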