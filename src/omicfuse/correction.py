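"""Missing-modality correction: align single-modality posterior means into
the joint latent space.

Posterior means conditioned on different modality subsets occupy subtly
different regions of the latent space, which distorts joint clustering of
paired and single-modality cells.  The correction exploits the paired cells,
for which every conditional posterior is available: a regression g_i is
trained to predict the joint-posterior mean from the modality-i-only mean,
then applied to the cells that carry only modality i.  Gradient-boosted
trees (squared loss, learning rate 0.8, max tree depth 3, one regressor per
latent coordinate) are the default backend; a k-nearest-neighbor regressor
performs equivalently and serves as a fallback when paired cells are scarce.

Because softmax is shift-invariant, latents are only identified up to an
additive constant; all estimates are centered to column mean zero (computed
over every cell's primary estimate) before the regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

JOINT = "joint"  #: view key for the all-observed-modalities posterior


@dataclass
class LatentEstimates:
    """Per-cell posterior-mean latents, grouped by conditioning view.

    ``blocks`` maps (group, view) -> (cell_ids, Z) where group is "paired"
    or "single" and view is :data:`JOINT` or a modality name.  Paired cells
    may carry the joint view plus one view per modality; single-modality
    cells carry exactly their own modality's view.
    """

    blocks: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    offset: np.ndarray | None = None

    def __getitem__(self, key: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
        return self.blocks[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.blocks

    @property
    def K(self) -> int:
        return next(iter(self.blocks.values()))[1].shape[1]

    def primary_stack(self) -> np.ndarray:
        """One row per cell: the joint view for paired cells, the modality
        view for single-modality cells."""
        rows = []
        for (group, view), (_, Z) in self.blocks.items():
            if (group == "paired") == (view == JOINT):
                rows.append(Z)
        return np.vstack(rows)


def center_latents(
    latents: np.ndarray | LatentEstimates, offset: np.ndarray | None = None
):
    """Shift latents to column mean zero.

    For a plain array, subtracts its own column mean (or the given offset)
    and returns ``(centered, offset)``.  For :class:`LatentEstimates`, the
    offset is computed globally over all cells' primary estimates and
    subtracted from every block, so all views land in one frame.
    """
    if isinstance(latents, LatentEstimates):
        off = latents.primary_stack().mean(axis=0) if offset is None else np.asarray(offset)
        blocks = {k: (ids, Z - off[None, :]) for k, (ids, Z) in latents.blocks.items()}
        return LatentEstimates(blocks=blocks, offset=off)
    Z = np.asarray(latents, dtype=np.float64)
    off = Z.mean(axis=0) if offset is None else np.asarray(offset)
    return Z - off[None, :], off


@dataclass
class CorrectionModel:
    """Per-modality regression maps from modality-specific to joint latents."""

    backend: str
    regressors: dict[str, list] = field(repr=False)
    train_r2: dict[str, np.ndarray] = field(default_factory=dict)

    def modalities(self) -> list[str]:
        return list(self.regressors)


def _make_regressor(backend: str, seed: int, n_rounds: int, n_neighbors: int):
    if backend == "xgboost":
        from xgboost import XGBRegressor

        return XGBRegressor(
            objective="reg:squarederror",
            learning_rate=0.8,
            max_depth=3,
            n_estimators=n_rounds,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if backend == "knn":
        from sklearn.neighbors import KNeighborsRegressor

        return KNeighborsRegressor(n_neighbors=n_neighbors)
    raise ValueError(f"unknown correction backend {backend!r}")


def fit_correction(
    Z_joint: np.ndarray,
    Z_by_modality: dict[str, np.ndarray],
    backend: str = "xgboost",
    min_paired: int = 50,
    n_rounds: int = 100,
    n_neighbors: int = 15,
    seed: int = 0,
) -> CorrectionModel:
    """Train per-modality maps g_i with g_i(Z_paired^(i)) ~= Z_joint.

    One regressor per latent coordinate (multi-output by stacking).
    Training R^2 per coordinate is recorded on ``train_r2``.
    """
    Z_joint = np.asarray(Z_joint, dtype=np.float64)
    n, K = Z_joint.shape
    if n < min_paired:
        raise ValueError(
            f"only {n} paired cells (< {min_paired}); too few for boosted-tree "
            f"correction — consider the 'knn' backend or lowering min_paired"
        )
    regressors: dict[str, list] = {}
    r2: dict[str, np.ndarray] = {}
    for name, Zm in Z_by_modality.items():
        Zm = np.asarray(Zm, dtype=np.float64)
        if Zm.shape != (n, K):
            raise ValueError(f"modality {name!r}: expected shape {(n, K)}, got {Zm.shape}")
        fitted, scores = [], []
        for k in range(K):
            reg = _make_regressor(backend, seed + k, n_rounds, n_neighbors)
            reg.fit(Zm, Z_joint[:, k])
            pred = reg.predict(Zm)
            resid = np.sum((Z_joint[:, k] - pred) ** 2)
            total = np.sum((Z_joint[:, k] - Z_joint[:, k].mean()) ** 2)
            scores.append(1.0 - resid / total if total > 0 else 1.0)
            fitted.append(reg)
        regressors[name] = fitted
        r2[name] = np.array(scores)
    return CorrectionModel(backend=backend, regressors=regressors, train_r2=r2)


def apply_correction(model: CorrectionModel, Z: np.ndarray, modality: str) -> np.ndarray:
    """Map modality-specific latents into the joint coordinate frame."""
    if modality not in model.regressors:
        raise KeyError(f"modality {modality!r} was not seen when fitting the correction")
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] == 0:
        return Z.copy()
    return np.column_stack([reg.predict(Z) for reg in model.regressors[modality]])


def integrate(
    latents: LatentEstimates,
    backend: str = "xgboost",
    min_paired: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, CorrectionModel]:
    """Full alignment: center, fit the correction on paired cells, correct
    all single-modality cells.

    Returns ``(cell_ids, Z_corrected, groups, model)`` covering every cell:
    paired cells keep their (centered) joint estimate; single-modality cells
    get their corrected estimate.  ``groups`` labels each row "paired" or
    the source modality name.
    """
    cl = center_latents(latents)
    joint_ids, Z1 = cl[("paired", JOINT)]
    Z_by_mod = {
        view: Z
        for (group, view), (_, Z) in cl.blocks.items()
        if group == "paired" and view != JOINT
    }
    model = fit_correction(Z1, Z_by_mod, backend=backend, min_paired=min_paired, seed=seed)
    ids_out, Z_out, grp_out = [joint_ids], [Z1], [np.full(len(joint_ids), "paired", object)]
    for (group, view), (ids, Z) in cl.blocks.items():
        if group != "single":
            continue
        ids_out.append(ids)
        Z_out.append(apply_correction(model, Z, view))
        grp_out.append(np.full(len(ids), view, object))
    return (
        np.concatenate(ids_out),
        np.vstack(Z_out),
        np.concatenate(grp_out),
        model,
    )
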