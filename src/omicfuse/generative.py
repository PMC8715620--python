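"""Decoder: latent mixing proportions -> multinomial counts per modality.

Each latent category k carries a feature-logit vector beta_k per modality;
a cell with proportions theta = softmax(z) samples counts from a multinomial
whose probabilities are the theta-mixture of the per-category feature
distributions,

    pi = sum_k theta_k * softmax_features(beta_k + offset_batch),

where offset_batch is an additive per-batch logit shift (reference batch
fixed at zero) absorbing technical differences in capture efficiency while
keeping pi on the simplex.  The decoder has no neural network: B and the
offsets are free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

#: floor applied to probabilities before log, so early-training zeros in pi
#: never produce -inf likelihoods.
PROB_FLOOR = 1e-10


@dataclass
class ModalityDecoder:
    """Decoder parameters for one modality.

    B : (K, d) category-by-feature logits (rows beta_k).
    batch_offsets : (n_batches, d); row 0 is the reference batch, fixed at 0.
    batch_levels : ordered batch-label vocabulary; index 0 is the reference.
    """

    B: np.ndarray
    batch_offsets: np.ndarray
    batch_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.float64)
        self.batch_offsets = np.asarray(self.batch_offsets, dtype=np.float64)
        if not np.all(np.isfinite(self.B)) or not np.all(np.isfinite(self.batch_offsets)):
            raise ValueError("decoder parameters must be finite")
        if self.batch_offsets.shape != (len(self.batch_levels), self.B.shape[1]):
            raise ValueError("one offset vector of length d per batch level required")
        if np.any(self.batch_offsets[0] != 0):
            raise ValueError("reference batch offset must be identically zero")

    @property
    def K(self) -> int:
        return self.B.shape[0]

    @property
    def n_features(self) -> int:
        return self.B.shape[1]

    def batch_index(self, batch: str) -> int:
        try:
            return self.batch_levels.index(batch)
        except ValueError:
            raise KeyError(f"unknown batch label {batch!r}; known: {self.batch_levels}")

    def category_distributions(self, batch_idx: int) -> np.ndarray:
        """(K, d) matrix of softmax(beta_k + offset_b), rows on the simplex."""
        return softmax(self.B + self.batch_offsets[batch_idx][None, :], axis=1)


@dataclass(frozen=True)
class CellState:
    """A cell's latent position z and its mixing proportions theta = softmax(z)."""

    z: np.ndarray
    theta: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.float64)
        object.__setattr__(self, "z", z)
        theta = softmax(z) if self.theta is None else np.asarray(self.theta, float)
        if np.any(theta < 0) or abs(theta.sum() - 1.0) > 1e-8:
            raise ValueError("theta must lie on the simplex")
        object.__setattr__(self, "theta", theta)


def decode(z: np.ndarray, decoder: ModalityDecoder, batch: str) -> np.ndarray:
    """Multinomial probabilities pi for latent position z in a given batch.

    Supports a single K-vector z or an (n, K) array; returns (d,) or (n, d)
    rows on the simplex.
    """
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    b = decoder.batch_index(batch)
    theta = softmax(z, axis=-1)
    return theta @ decoder.category_distributions(b)


def log_multinomial(x: np.ndarray, pi: np.ndarray) -> float:
    """Count log-likelihood sum_j x_j log pi_j.

    The multinomial coefficient is omitted (constant in all model
    parameters); probabilities are floored at PROB_FLOOR so observed counts
    on zero-probability features yield a large but finite penalty.
    """
    x = np.asarray(x, dtype=np.float64)
    pi = np.asarray(pi, dtype=np.float64)
    if x.shape != pi.shape:
        raise ValueError("count and probability vectors must have equal length")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    return float(np.sum(x * np.log(np.maximum(pi, PROB_FLOOR))))


def sample_counts(
    z: np.ndarray,
    decoder: ModalityDecoder,
    batch: str,
    library_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multinomial draw of ``library_size`` total counts at latent z."""
    if library_size < 0:
        raise ValueError("library_size must be >= 0")
    pi = decode(z, decoder, batch)
    if pi.ndim != 1:
        raise ValueError("sample_counts expects a single cell's z")
    return rng.multinomial(int(library_size), pi)
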