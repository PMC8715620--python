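"""Count-matrix I/O and multi-modality dataset assembly.

Cells are keyed by string IDs; a cell present (same ID) in several modality
matrices is a *paired* cell.  Matrices are held sparse (CSR) and densified
only inside minibatch assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread


@dataclass
class ModalityMatrix:
    """One modality's cells x features count matrix.

    counts : nonnegative integer matrix, cells on rows (stored CSR).
    cell_ids / feature_ids : unique string identifiers for rows / columns.
    batch_labels : one categorical label per cell.
    """

    modality_name: str
    counts: sp.csr_matrix
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    batch_labels: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        n, d = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix rows")
        if len(self.feature_ids) != d:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {d} columns")
        if len(self.batch_labels) != n:
            raise ValueError("one batch label per cell required")
        if len(set(self.cell_ids)) != n:
            raise ValueError(f"duplicate cell ids in modality {self.modality_name!r}")
        if len(set(self.feature_ids)) != d:
            raise ValueError(f"duplicate feature ids in modality {self.modality_name!r}")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be nonnegative integers")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def feature_means(self) -> np.ndarray:
        return np.asarray(self.counts.mean(axis=0)).ravel()


@dataclass
class MultiOmicDataset:
    """Modality matrices linked by shared cell IDs.

    ``cell_ids`` is the union over modalities (first-seen order) and
    ``presence`` the cells x modalities boolean mask derived from ID
    membership; cells with >= 2 modalities present are the paired cells.
    """

    modalities: list[ModalityMatrix]
    cell_ids: np.ndarray
    presence: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def modality_names(self) -> list[str]:
        return [m.modality_name for m in self.modalities]

    def subset_of(self, cell_id: str) -> tuple[int, ...]:
        i = int(np.flatnonzero(self.cell_ids == cell_id)[0])
        return tuple(int(j) for j in np.flatnonzero(self.presence[i]))

    def subset_counts(self) -> dict[tuple[int, ...], int]:
        """Number of cells per observed modality subset (e.g. n1, n2, n3)."""
        out: dict[tuple[int, ...], int] = {}
        for row in self.presence:
            key = tuple(int(j) for j in np.flatnonzero(row))
            out[key] = out.get(key, 0) + 1
        return out

    def batch_label_of(self, cell_id: str) -> str:
        for m in self.modalities:
            hit = np.flatnonzero(m.cell_ids == cell_id)
            if hit.size:
                return m.batch_labels[hit[0]]
        raise KeyError(cell_id)


def read_mtx_triplet(
    matrix_path,
    features_path,
    barcodes_path,
    modality_name: str,
    batch_label: str = "batch0",
) -> ModalityMatrix:
    """Read a 10x-style MatrixMarket triplet into a ModalityMatrix.

    The on-disk matrix may be cells x features or the (10x-conventional)
    features x cells; orientation is decided by matching a dimension to the
    barcode count.  A square matrix whose dimensions both match is ambiguous
    and rejected.
    """
    mat = mmread(str(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).to_numpy()
    nr, nc = mat.shape
    if nr == len(barcodes) and nc == len(features):
        if nr == nc and len(features) == len(barcodes):
            raise ValueError(
                "square matrix with equal feature/barcode counts: orientation ambiguous"
            )
        counts = mat
    elif nr == len(features) and nc == len(barcodes):
        counts = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"{len(barcodes)} barcodes x {len(features)} features nor its transpose"
        )
    counts = sp.csr_matrix(counts)
    if counts.nnz == 0:
        warnings.warn(f"modality {modality_name!r}: matrix has no nonzero entries")
    if counts.data.size and np.any(counts.data != np.round(counts.data)):
        raise ValueError("matrix contains non-integer entries")
    return ModalityMatrix(
        modality_name=modality_name,
        counts=counts,
        cell_ids=barcodes,
        feature_ids=features,
        batch_labels=np.full(len(barcodes), batch_label, dtype=object),
    )


def read_dense(path, modality_name: str, batch_label: str = "batch0", sep: str = ",") -> ModalityMatrix:
    """Read a small dense delimited matrix (header = feature ids, first column = cell ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ModalityMatrix(
        modality_name=modality_name,
        counts=sp.csr_matrix(df.to_numpy()),
        cell_ids=df.index.astype(str).to_numpy(),
        feature_ids=df.columns.astype(str).to_numpy(),
        batch_labels=np.full(df.shape[0], batch_label, dtype=object),
    )


def merge_batches(matrices: list[ModalityMatrix]) -> ModalityMatrix:
    """Concatenate several batches of one modality, outer-joining features.

    Features absent from one batch are filled with zeros (they are true
    zeros for the multinomial model).  Batch labels are preserved per cell.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    name = matrices[0].modality_name
    if any(m.modality_name != name for m in matrices):
        raise ValueError("merge_batches expects matrices of one modality")
    feats: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for f in m.feature_ids:
            if f not in seen:
                seen.add(f)
                feats.append(f)
    fidx = {f: j for j, f in enumerate(feats)}
    blocks = []
    for m in matrices:
        cols = np.array([fidx[f] for f in m.feature_ids])
        coo = m.counts.tocoo()
        blocks.append(
            sp.coo_matrix((coo.data, (coo.row, cols[coo.col])), shape=(m.n_cells, len(feats)))
        )
    return ModalityMatrix(
        modality_name=name,
        counts=sp.csr_matrix(sp.vstack(blocks)),
        cell_ids=np.concatenate([m.cell_ids for m in matrices]),
        feature_ids=np.array(feats, dtype=object),
        batch_labels=np.concatenate([m.batch_labels for m in matrices]),
    )


def assemble_dataset(matrices: list[ModalityMatrix]) -> MultiOmicDataset:
    """Link modality matrices into one dataset via shared cell IDs.

    Cells appearing in several modalities (same ID) become paired cells; the
    presence mask records each cell's observed modality subset.
    """
    if not matrices:
        raise ValueError("at least one modality matrix required")
    if sum(m.n_cells for m in matrices) == 0:
        raise ValueError("dataset contains zero cells")
    cell_ids: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for c in m.cell_ids:
            if c not in seen:
                seen.add(c)
                cell_ids.append(c)
    idx = {c: i for i, c in enumerate(cell_ids)}
    presence = np.zeros((len(cell_ids), len(matrices)), dtype=bool)
    for j, m in enumerate(matrices):
        for c in m.cell_ids:
            presence[idx[c], j] = True
    return MultiOmicDataset(
        modalities=list(matrices),
        cell_ids=np.array(cell_ids, dtype=object),
        presence=presence,
    )


def filter_features(
    m: ModalityMatrix,
    lower_quantile: float = 0.70,
    upper_quantile: float = 0.99,
) -> ModalityMatrix:
    """Keep features by average count: at or above the lower quantile of
    per-feature means (inclusive) and below the upper quantile (exclusive).

    With the defaults this retains the top 30% of features by mean count
    while dropping the top 1%.  Quantiles are linear-interpolated empirical
    quantiles of the per-feature means; boundary ties are kept at the lower
    bound and dropped at the upper.
    """
    if not (0 <= lower_quantile < upper_quantile <= 1):
        raise ValueError("require 0 <= lower < upper <= 1")
    means = m.feature_means()
    lo = np.quantile(means, lower_quantile)
    hi = np.quantile(means, upper_quantile)
    if upper_quantile == 1.0 or hi <= lo:
        # no upper cut at q=1; degenerate (tied) quantiles keep the lower rule only
        keep = means >= lo
    else:
        keep = (means >= lo) & (means < hi)
    if not np.any(keep):
        raise ValueError("feature filter removed all features")
    return ModalityMatrix(
        modality_name=m.modality_name,
        counts=sp.csr_matrix(m.counts[:, keep]),
        cell_ids=m.cell_ids,
        feature_ids=m.feature_ids[keep],
        batch_labels=m.batch_labels,
    )


def write_latents(latents: np.ndarray, cell_ids, path) -> None:
    """Write an (n, K) latent matrix as CSV with header cell_id,z1..zK."""
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or latents.shape[1] == 0:
        raise ValueError("latents must be a nonempty-width 2-D array")
    if latents.shape[0] != len(cell_ids):
        raise ValueError("one cell id per latent row required")
    cols = [f"z{k + 1}" for k in range(latents.shape[1])]
    df = pd.DataFrame(latents, columns=cols)
    df.insert(0, "cell_id", list(cell_ids))
    df.to_csv(path, index=False, float_format="%.10g")


def read_latents(path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_latents`; returns (latents, cell_ids)."""
    df = pd.read_csv(path)
    return df.drop(columns=["cell_id"]).to_numpy(dtype=np.float64), df["cell_id"].to_numpy()
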