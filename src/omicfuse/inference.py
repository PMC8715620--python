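"""Variational inference for the multimodal latent model.

One encoder per modality maps log1p counts through a single hidden layer
(size 128, ReLU) to a diagonal-Gaussian posterior factor.  Posteriors for an
arbitrary observed modality subset A are formed by a product of experts
(PoE): precisions of the prior expert and of each modality expert add, so M
encoders serve every subset.  Training maximizes a subset-weighted ELBO: for
every cell each observed singleton contributes a term, and cells with >= 2
modalities additionally contribute a joint term; each term for subset A is
weighted by lambda_A = 1 / (number of cells contributing that term).  The KL
weight gamma is annealed linearly from 0 to 1 over the first 30 epochs, and
Adam (lr 0.005) runs minibatches of 128 cells for 100 epochs by default.

The whole engine is plain numpy with hand-derived gradients: the network is
one hidden layer plus linear heads, and the decoder is an explicit mixture
of per-category softmax distributions, so backpropagation is short enough to
write (and finite-difference check) directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp, softmax

from .correction import JOINT, LatentEstimates
from .data_io import MultiOmicDataset
from .generative import PROB_FLOOR, ModalityDecoder
from .prior import DirichletLaplacePrior, build_prior

logger = logging.getLogger("omicfuse")

#: encoder log-variances are clamped to this symmetric range for stability
LOG_VAR_CLIP = 10.0


# ---------------------------------------------------------------------------
# configuration and small value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianParams:
    """Diagonal Gaussian over the K-dim latent space (possibly batched)."""

    mean: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=np.float64)
        lv = np.asarray(self.log_var, dtype=np.float64)
        if m.shape != lv.shape:
            raise ValueError("mean and log_var must share a shape")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(lv))):
            raise ValueError("GaussianParams must be finite")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "log_var", lv)

    @property
    def var(self) -> np.ndarray:
        return np.exp(self.log_var)


@dataclass(frozen=True)
class TrainingConfig:
    K: int
    hidden_size: int = 128
    learning_rate: float = 0.005
    batch_size: int = 128
    epochs: int = 100
    annealing_epochs: int = 30
    eta: float = 1.0
    total_concentration: float = 50.0
    seed: int = 0
    use_batch_offsets: bool = True

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        for name in ("hidden_size", "learning_rate", "batch_size", "annealing_epochs",
                     "eta", "total_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.annealing_epochs > max(self.epochs, 1):
            raise ValueError("annealing_epochs must not exceed epochs")


@dataclass(frozen=True)
class SubsetWeights:
    """lambda_A per observed modality subset (tuple of modality indices)."""

    lambda_A: dict[tuple[int, ...], float]

    def __getitem__(self, A: tuple[int, ...]) -> float:
        return self.lambda_A[A]


def compute_subset_weights(dataset: MultiOmicDataset) -> SubsetWeights:
    """lambda_A = 1 / n_A for every training term.

    Singleton terms draw from every cell observing that modality (paired and
    single-modality alike); a joint term for subset A draws from the cells
    whose observed set is exactly A.
    """
    lam: dict[tuple[int, ...], float] = {}
    for i in range(dataset.n_modalities):
        n_i = int(dataset.presence[:, i].sum())
        if n_i > 0:
            lam[(i,)] = 1.0 / n_i
    for A, n_A in dataset.subset_counts().items():
        if len(A) >= 2:
            lam[A] = 1.0 / n_A
    return SubsetWeights(lambda_A=lam)


def kl_annealing(epoch: int, annealing_epochs: int = 30) -> float:
    """Linear KL-weight ramp: 0 at epoch 0, 1 from ``annealing_epochs`` on."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return min(1.0, epoch / annealing_epochs)


def product_of_experts(
    experts: list[GaussianParams], prior: DirichletLaplacePrior
) -> GaussianParams:
    """Precision-weighted combination of expert posteriors and the prior.

    With zero experts this returns the prior itself; each added expert can
    only increase precision (shrink variances).
    """
    T = 1.0 / prior.var_prior
    if np.any(prior.var_prior <= 0):
        raise ValueError("prior variances must be positive")
    num = T * prior.mu_prior
    for e in experts:
        v = e.var
        if np.any(v <= 0):
            raise ValueError("expert variances must be positive")
        if e.mean.shape[-1] != prior.K:
            raise ValueError("expert dimension does not match the prior")
        T = T + 1.0 / v
        num = num + e.mean / v
    var = 1.0 / T
    return GaussianParams(mean=num * var, log_var=np.log(var))


# ---------------------------------------------------------------------------
# parameters, initialization, fitted model
# ---------------------------------------------------------------------------


def _init_params(
    dims: list[int], K: int, hidden: int, n_batches: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fan-in uniform init for encoder nets; N(0, 0.1^2) for decoder logits
    and batch offsets (reference batch row pinned at zero)."""
    params: dict[str, np.ndarray] = {}
    for i, d in enumerate(dims):
        s1, s2 = 1.0 / np.sqrt(d), 1.0 / np.sqrt(hidden)
        params[f"enc{i}.W1"] = rng.uniform(-s1, s1, size=(d, hidden))
        params[f"enc{i}.b1"] = rng.uniform(-s1, s1, size=hidden)
        params[f"enc{i}.Wm"] = rng.uniform(-s2, s2, size=(hidden, K))
        params[f"enc{i}.bm"] = rng.uniform(-s2, s2, size=K)
        params[f"enc{i}.Wv"] = rng.uniform(-s2, s2, size=(hidden, K))
        params[f"enc{i}.bv"] = rng.uniform(-s2, s2, size=K)
        params[f"dec{i}.B"] = rng.normal(0.0, 0.1, size=(K, d))
        off = rng.normal(0.0, 0.1, size=(n_batches, d))
        off[0] = 0.0
        params[f"dec{i}.off"] = off
    return params


@dataclass
class FittedModel:
    """Encoder/decoder parameters plus everything needed to re-embed cells."""

    config: TrainingConfig
    prior: DirichletLaplacePrior
    modality_names: list[str]
    feature_ids: list[np.ndarray]
    batch_levels: tuple[str, ...]
    params: dict[str, np.ndarray] = field(repr=False)
    epoch_elbo: list[float] = field(default_factory=list, repr=False)

    @property
    def n_modalities(self) -> int:
        return len(self.modality_names)

    def encode_modality(self, x, i: int) -> GaussianParams:
        """Deterministic encoder pass for modality i on raw counts x
        ((n, d_i) array/sparse or a single d_i vector)."""
        X = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=np.float64)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != len(self.feature_ids[i]):
            raise ValueError(
                f"modality {self.modality_names[i]!r} expects "
                f"{len(self.feature_ids[i])} features, got {X.shape[1]}"
            )
        mu, lv, _ = _encoder_forward(self.params, i, np.log1p(X))
        if single:
            return GaussianParams(mean=mu[0], log_var=lv[0])
        return GaussianParams(mean=mu, log_var=lv)

    def decoder(self, i: int) -> ModalityDecoder:
        return ModalityDecoder(
            B=self.params[f"dec{i}.B"],
            batch_offsets=self.params[f"dec{i}.off"]
            if self.config.use_batch_offsets
            else np.zeros_like(self.params[f"dec{i}.off"]),
            batch_levels=self.batch_levels,
        )

    def save(self, path) -> None:
        import json

        meta = {
            "config": {k: (v if not isinstance(v, np.generic) else v.item())
                       for k, v in self.config.__dict__.items()},
            "modality_names": self.modality_names,
            "batch_levels": list(self.batch_levels),
            "epoch_elbo": self.epoch_elbo,
        }
        np.savez(
            path,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"feat{i}": fid.astype(str) for i, fid in enumerate(self.feature_ids)},
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            config = TrainingConfig(**meta["config"])
            feats = []
            i = 0
            while f"feat{i}" in z:
                feats.append(z[f"feat{i}"].astype(object))
                i += 1
            params = {k: z[k] for k in z.files if not k.startswith("feat") and k != "_meta"}
        return cls(
            config=config,
            prior=build_prior(config.K, config.total_concentration),
            modality_names=meta["modality_names"],
            feature_ids=feats,
            batch_levels=tuple(meta["batch_levels"]),
            params=params,
            epoch_elbo=list(meta["epoch_elbo"]),
        )


# ---------------------------------------------------------------------------
# forward / backward passes
# ---------------------------------------------------------------------------


def _encoder_forward(params, i, U):
    """U = log1p counts, (n, d).  Returns (mu, lv, cache)."""
    a = U @ params[f"enc{i}.W1"] + params[f"enc{i}.b1"]
    H = np.maximum(a, 0.0)
    mu = H @ params[f"enc{i}.Wm"] + params[f"enc{i}.bm"]
    lv_raw = H @ params[f"enc{i}.Wv"] + params[f"enc{i}.bv"]
    lv = np.clip(lv_raw, -LOG_VAR_CLIP, LOG_VAR_CLIP)
    return mu, lv, (U, a, H, lv_raw)


def _encoder_backward(params, grads, i, cache, gmu, glv):
    U, a, H, lv_raw = cache
    glv = glv * ((lv_raw > -LOG_VAR_CLIP) & (lv_raw < LOG_VAR_CLIP))
    grads[f"enc{i}.Wm"] += H.T @ gmu
    grads[f"enc{i}.bm"] += gmu.sum(axis=0)
    grads[f"enc{i}.Wv"] += H.T @ glv
    grads[f"enc{i}.bv"] += glv.sum(axis=0)
    gH = gmu @ params[f"enc{i}.Wm"].T + glv @ params[f"enc{i}.Wv"].T
    ga = gH * (a > 0)
    grads[f"enc{i}.W1"] += U.T @ ga
    grads[f"enc{i}.b1"] += ga.sum(axis=0)


class _Prepared:
    """Dataset views indexed for minibatch training."""

    def __init__(self, dataset: MultiOmicDataset, use_batch_offsets: bool):
        self.dataset = dataset
        M = dataset.n_modalities
        n = dataset.n_cells
        levels: list[str] = []
        for m in dataset.modalities:
            for b in m.batch_labels:
                if b not in levels:
                    levels.append(b)
        self.batch_levels = tuple(levels)
        self.X = [m.counts.tocsr() for m in dataset.modalities]
        id_index = {c: j for j, c in enumerate(dataset.cell_ids)}
        self.row_of_cell = np.full((M, n), -1, dtype=int)
        self.batch_idx = np.zeros(n, dtype=int)
        for i, m in enumerate(dataset.modalities):
            for r, cid in enumerate(m.cell_ids):
                j = id_index[cid]
                self.row_of_cell[i, j] = r
                self.batch_idx[j] = levels.index(m.batch_labels[r])
        if not use_batch_offsets:
            self.batch_idx = np.zeros(n, dtype=int)
        # exact observed subset per cell, and cells grouped by it
        self.subsets = [
            tuple(int(j) for j in np.flatnonzero(row)) for row in dataset.presence
        ]
        self.joint_groups: dict[tuple[int, ...], np.ndarray] = {}
        for A in set(self.subsets):
            if len(A) >= 2:
                self.joint_groups[A] = np.array(
                    [j for j, S in enumerate(self.subsets) if S == A]
                )

    def counts_for(self, i: int, cells: np.ndarray) -> np.ndarray:
        return self.X[i][self.row_of_cell[i, cells]].toarray().astype(np.float64)


def _term_cells(prep: _Prepared, mb: np.ndarray):
    """Yield (A, cells) training terms for a minibatch of dataset cells."""
    M = prep.dataset.n_modalities
    for i in range(M):
        cells = mb[prep.row_of_cell[i, mb] >= 0]
        if cells.size:
            yield (i,), cells
    for A in sorted(prep.joint_groups):
        cells = mb[[prep.subsets[j] == A for j in mb]]
        if cells.size:
            yield A, cells


def _term_forward_backward(
    params,
    grads,
    prep: _Prepared,
    A: tuple[int, ...],
    cells: np.ndarray,
    prior: DirichletLaplacePrior,
    eps: np.ndarray,
    lam: float,
    gamma: float,
    eta: float,
    inv_n_mb: float,
    use_batch_offsets: bool,
):
    """One ELBO term (subset A over `cells`): forward pass, ELBO value, and —
    if grads is not None — analytic gradients of the minibatch loss
    loss = -(1/n_mb) * sum(term values)."""
    nc = cells.size
    Xs, caches, mus, lvs = {}, {}, {}, {}
    for i in A:
        X = prep.counts_for(i, cells)
        mu, lv, cache = _encoder_forward(params, i, np.log1p(X))
        Xs[i], caches[i], mus[i], lvs[i] = X, cache, mu, lv

    # product of experts with the prior
    T0 = 1.0 / prior.var_prior
    T = np.broadcast_to(T0, (nc, prior.K)).copy()
    num = np.broadcast_to(T0 * prior.mu_prior, (nc, prior.K)).copy()
    Ti = {}
    for i in A:
        Ti[i] = np.exp(-lvs[i])
        T += Ti[i]
        num += Ti[i] * mus[i]
    var_q = 1.0 / T
    mu_q = num * var_q

    z = mu_q + np.sqrt(var_q) * eps
    zs = z - z.max(axis=1, keepdims=True)
    theta = np.exp(zs)
    theta /= theta.sum(axis=1, keepdims=True)

    # reconstruction per modality, grouped by batch level
    recon = np.zeros(nc)
    batch_of = prep.batch_idx[cells]
    g_theta = np.zeros_like(theta) if grads is not None else None
    for i in A:
        offs = params[f"dec{i}.off"]
        B = params[f"dec{i}.B"]
        for b in np.unique(batch_of):
            sel = batch_of == b
            logits = B + (offs[b][None, :] if use_batch_offsets else 0.0)
            ls = logits - logits.max(axis=1, keepdims=True)
            P = np.exp(ls)
            P /= P.sum(axis=1, keepdims=True)  # (K, d) rows on simplex
            th = theta[sel]
            pi = th @ P
            pi_safe = np.maximum(pi, PROB_FLOOR)
            Xb = Xs[i][sel]
            recon[sel] += np.sum(Xb * np.log(pi_safe), axis=1)
            if grads is not None:
                c_rec = -lam * eta * inv_n_mb
                Gpi = c_rec * (Xb / pi_safe) * (pi > PROB_FLOOR)
                g_theta[sel] += Gpi @ P.T
                dP = th.T @ Gpi
                dA = P * (dP - np.sum(P * dP, axis=1, keepdims=True))
                grads[f"dec{i}.B"] += dA
                if use_batch_offsets and b != 0:
                    grads[f"dec{i}.off"][b] += dA.sum(axis=0)

    # KL(q || prior), closed form, per cell
    dmu = mu_q - prior.mu_prior
    kl = 0.5 * np.sum(
        np.log(prior.var_prior) - np.log(var_q)
        + (var_q + dmu**2) / prior.var_prior
        - 1.0,
        axis=1,
    )
    term_values = lam * (eta * recon - gamma * kl)

    if grads is not None:
        # theta = softmax(z)
        gz = theta * (g_theta - np.sum(theta * g_theta, axis=1, keepdims=True))
        c_kl = lam * gamma * inv_n_mb
        gmu_q = gz + c_kl * dmu / prior.var_prior
        gvar_q = gz * eps / (2.0 * np.sqrt(var_q)) + c_kl * 0.5 * (
            1.0 / prior.var_prior - 1.0 / var_q
        )
        for i in A:
            gmu_i = gmu_q * Ti[i] * var_q
            gTi = gmu_q * (mus[i] - mu_q) * var_q - gvar_q * var_q**2
            glv_i = -Ti[i] * gTi
            _encoder_backward(params, grads, i, caches[i], gmu_i, glv_i)

    return term_values, recon, kl


def _minibatch_pass(
    params,
    prep: _Prepared,
    mb: np.ndarray,
    prior: DirichletLaplacePrior,
    weights: SubsetWeights,
    gamma: float,
    eta: float,
    eps_by_term: dict,
    compute_grads: bool,
    use_batch_offsets: bool,
):
    """Returns (loss, grads, elbo_sum, breakdown).  loss = -elbo_sum/n_mb."""
    grads = {k: np.zeros_like(v) for k, v in params.items()} if compute_grads else None
    inv_n_mb = 1.0 / mb.size
    elbo_sum = 0.0
    breakdown: dict[tuple[int, ...], dict[str, float]] = {}
    for A, cells in _term_cells(prep, mb):
        tv, recon, kl = _term_forward_backward(
            params, grads, prep, A, cells, prior, eps_by_term[A],
            weights[A], gamma, eta, inv_n_mb, use_batch_offsets,
        )
        elbo_sum += float(tv.sum())
        breakdown[A] = {
            "n_cells": int(cells.size),
            "lambda": weights[A],
            "recon": float(recon.sum()),
            "kl": float(kl.sum()),
            "weighted": float(tv.sum()),
        }
    return -elbo_sum * inv_n_mb, grads, elbo_sum, breakdown


def _draw_eps(prep: _Prepared, mb: np.ndarray, K: int, rng: np.random.Generator):
    return {A: rng.standard_normal((cells.size, K)) for A, cells in _term_cells(prep, mb)}


def elbo(
    minibatch,
    model: FittedModel,
    weights: SubsetWeights,
    gamma: float,
    eta: float = 1.0,
    rng: np.random.Generator | None = None,
):
    """Single-sample ELBO estimate over a minibatch of dataset cell indices.

    Returns ``(value, breakdown)`` where value is the mean over the
    minibatch of the lambda-weighted per-cell term sums (to be maximized)
    and breakdown reports recon/KL totals per subset term.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    dataset, mb = minibatch
    prep = dataset if isinstance(dataset, _Prepared) else _Prepared(
        dataset, model.config.use_batch_offsets
    )
    mb = np.asarray(mb, dtype=int)
    rng = rng or np.random.default_rng(model.config.seed)
    eps = _draw_eps(prep, mb, model.config.K, rng)
    loss, _, elbo_sum, breakdown = _minibatch_pass(
        model.params, prep, mb, model.prior, weights, gamma, eta, eps,
        compute_grads=False, use_batch_offsets=model.config.use_batch_offsets,
    )
    return elbo_sum / mb.size, breakdown


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def fit(dataset: MultiOmicDataset, config: TrainingConfig) -> FittedModel:
    """Train the model by minibatch Adam on the annealed subset-weighted ELBO.

    Deterministic for a fixed seed and thread count; per-epoch mean ELBO is
    logged and stored on the returned model.
    """
    if dataset.n_cells == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    prep = _Prepared(dataset, config.use_batch_offsets)
    dims = [m.n_features for m in dataset.modalities]
    params = _init_params(dims, config.K, config.hidden_size, len(prep.batch_levels), rng)
    prior = build_prior(config.K, config.total_concentration)
    weights = compute_subset_weights(dataset)
    model = FittedModel(
        config=config,
        prior=prior,
        modality_names=dataset.modality_names,
        feature_ids=[m.feature_ids for m in dataset.modalities],
        batch_levels=prep.batch_levels,
        params=params,
    )
    opt = _Adam(params, config.learning_rate)
    n = dataset.n_cells
    for epoch in range(config.epochs):
        gamma = kl_annealing(epoch, config.annealing_epochs)
        order = rng.permutation(n)
        epoch_elbo = 0.0
        for start in range(0, n, config.batch_size):
            mb = order[start : start + config.batch_size]
            eps = _draw_eps(prep, mb, config.K, rng)
            loss, grads, elbo_sum, breakdown = _minibatch_pass(
                params, prep, mb, prior, weights, gamma, config.eta, eps,
                compute_grads=True, use_batch_offsets=config.use_batch_offsets,
            )
            if not np.isfinite(loss):
                bad = {A: b for A, b in breakdown.items()
                       if not np.isfinite(b["weighted"])}
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, minibatch starting {start}: "
                    f"offending terms {bad or breakdown}"
                )
            opt.step(params, grads)
            epoch_elbo += elbo_sum
        model.epoch_elbo.append(epoch_elbo / n)
        logger.info("epoch %3d  gamma=%.3f  elbo=%.4f", epoch, gamma, model.epoch_elbo[-1])
    return model


# ---------------------------------------------------------------------------
# posterior means
# ---------------------------------------------------------------------------


def _poe_mean(model: FittedModel, prep: _Prepared, A: tuple[int, ...], cells: np.ndarray):
    experts = []
    for i in A:
        X = prep.counts_for(i, cells)
        mu, lv, _ = _encoder_forward(model.params, i, np.log1p(X))
        experts.append(GaussianParams(mean=mu, log_var=lv))
    T = 1.0 / model.prior.var_prior
    num = T * model.prior.mu_prior
    for e in experts:
        T = T + 1.0 / e.var
        num = num + e.mean / e.var
    return num / T


def posterior_means(
    model: FittedModel,
    dataset: MultiOmicDataset,
    subset_policy: str = "with_singles",
    subset: tuple[int, ...] | None = None,
) -> LatentEstimates:
    """Posterior-mean latents for every cell.

    subset_policy "full": each cell conditioned on its full observed subset.
    "with_singles" additionally computes each single-modality view for
    paired cells (needed to train the missing-modality correction).  Passing
    ``subset`` instead requests one specific conditioning subset for all
    cells and errors if any cell lacks one of its modalities.
    """
    prep = _Prepared(dataset, model.config.use_batch_offsets)
    names = model.modality_names
    if subset is not None:
        missing = [
            str(dataset.cell_ids[j])
            for j in range(dataset.n_cells)
            if not set(subset) <= set(prep.subsets[j])
        ]
        if missing:
            raise ValueError(
                f"subset {subset} requested but {len(missing)} cells lack one of "
                f"these modalities (e.g. {missing[0]!r})"
            )
        cells = np.arange(dataset.n_cells)
        Z = _poe_mean(model, prep, subset, cells)
        view = JOINT if len(subset) > 1 else names[subset[0]]
        return LatentEstimates(blocks={("paired", view): (dataset.cell_ids.copy(), Z)})

    if subset_policy not in ("full", "with_singles"):
        raise ValueError(f"unknown subset_policy {subset_policy!r}")
    blocks: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for A, cells in prep.joint_groups.items():
        blocks[("paired", JOINT)] = (
            dataset.cell_ids[cells].copy(),
            _poe_mean(model, prep, A, cells),
        )
        if subset_policy == "with_singles":
            for i in A:
                blocks[("paired", names[i])] = (
                    dataset.cell_ids[cells].copy(),
                    _poe_mean(model, prep, (i,), cells),
                )
    for i in range(dataset.n_modalities):
        cells = np.array([j for j, S in enumerate(prep.subsets) if S == (i,)])
        if cells.size:
            blocks[("single", names[i])] = (
                dataset.cell_ids[cells].copy(),
                _poe_mean(model, prep, (i,), cells),
            )
    return LatentEstimates(blocks=blocks)


# ---------------------------------------------------------------------------
# importance-sampling evidence estimate (used as an oracle for the ELBO bound)
# ---------------------------------------------------------------------------


def importance_weighted_evidence(
    model: FittedModel,
    dataset: MultiOmicDataset,
    weights: SubsetWeights,
    n_samples: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Importance-sampling estimate of the lambda-weighted log evidence,
    mean over cells: for each training term A, log p(x_A) is estimated with
    q_A as proposal; by Jensen it upper-bounds the gamma=1 ELBO in
    expectation."""
    rng = rng or np.random.default_rng(0)
    prep = _Prepared(dataset, model.config.use_batch_offsets)
    mb = np.arange(dataset.n_cells)
    prior = model.prior
    total = 0.0
    for A, cells in _term_cells(prep, mb):
        Xs = {i: prep.counts_for(i, cells) for i in A}
        experts = {}
        for i in A:
            mu, lv, _ = _encoder_forward(model.params, i, np.log1p(Xs[i]))
            experts[i] = (mu, np.exp(lv))
        T = 1.0 / prior.var_prior + sum(1.0 / v for _, v in experts.values())
        mu_q = (prior.mu_prior / prior.var_prior
                + sum(m / v for m, v in experts.values())) / T
        var_q = 1.0 / T
        nc = cells.size
        logw = np.zeros((n_samples, nc))
        batch_of = prep.batch_idx[cells]
        Ps = {
            i: {
                b: softmax(
                    model.params[f"dec{i}.B"]
                    + (model.params[f"dec{i}.off"][b][None, :]
                       if model.config.use_batch_offsets else 0.0),
                    axis=1,
                )
                for b in np.unique(batch_of)
            }
            for i in A
        }
        for s in range(n_samples):
            z = mu_q + np.sqrt(var_q) * rng.standard_normal((nc, prior.K))
            theta = softmax(z, axis=1)
            lp = -0.5 * np.sum(
                np.log(2 * np.pi * prior.var_prior)
                + (z - prior.mu_prior) ** 2 / prior.var_prior,
                axis=1,
            )
            lq = -0.5 * np.sum(
                np.log(2 * np.pi * var_q) + (z - mu_q) ** 2 / var_q, axis=1
            )
            rec = np.zeros(nc)
            for i in A:
                for b in np.unique(batch_of):
                    sel = batch_of == b
                    pi = np.maximum(theta[sel] @ Ps[i][b], PROB_FLOOR)
                    rec[sel] += np.sum(Xs[i][sel] * np.log(pi), axis=1)
            logw[s] = rec + lp - lq
        log_phat = logsumexp(logw, axis=0) - np.log(n_samples)
        total += weights[A] * log_phat.sum()
    return total / dataset.n_cells
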