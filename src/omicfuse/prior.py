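"""Gaussian prior on the softmax-basis latent variable.

The generative model places a Dirichlet prior on the per-cell category
proportions theta.  To embed that prior in a VAE with a Gaussian latent z
(theta = softmax(z)), the Dirichlet is replaced by its Laplace approximation
in the softmax basis, yielding a diagonal Gaussian over z.  The diagonal
moment formulas follow the ProdLDA construction (the exact full-covariance
Laplace approximation is deliberately reduced to its diagonal, matching the
diagonal-Gaussian encoders):

    mu_k  = log(alpha_k) - (1/K) * sum_i log(alpha_i)
    var_k = (1/alpha_k) * (1 - 2/K) + (1/K^2) * sum_i (1/alpha_i)

For a symmetric Dirichlet the mean is exactly zero.  The default total
concentration is 50, split evenly over the K categories (alpha_k = 50/K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DirichletLaplacePrior:
    """Diagonal-Gaussian Laplace approximation to a Dirichlet prior.

    Attributes
    ----------
    alpha : concentration vector of the approximated Dirichlet (all > 0).
    mu_prior : K-vector, mean of the Gaussian approximation.
    var_prior : K-vector, diagonal variances (all > 0).
    """

    alpha: np.ndarray
    mu_prior: np.ndarray = field(repr=False)
    var_prior: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        for name in ("alpha", "var_prior"):
            v = getattr(self, name)
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise ValueError(f"{name} must be finite and positive")
        if not (self.alpha.shape == self.mu_prior.shape == self.var_prior.shape):
            raise ValueError("alpha, mu_prior, var_prior must share one shape")

    @property
    def K(self) -> int:
        return self.alpha.shape[0]


def laplace_moments(alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal Laplace moments of a Dirichlet(alpha) in the softmax basis."""
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.ndim != 1 or alpha.shape[0] < 2:
        raise ValueError("alpha must be a vector of length >= 2")
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet concentrations must be positive")
    K = alpha.shape[0]
    log_a = np.log(alpha)
    mu = log_a - log_a.mean()
    inv_a = 1.0 / alpha
    var = inv_a * (1.0 - 2.0 / K) + inv_a.sum() / K**2
    return mu, var


def build_prior(K: int, total_concentration: float = 50.0) -> DirichletLaplacePrior:
    """Symmetric Dirichlet prior with alpha_k = total_concentration / K.

    Parameters
    ----------
    K : number of latent categories, >= 2.
    total_concentration : summed Dirichlet concentration (default 50, so
        e.g. K=10 gives alpha_k = 5).

    Returns
    -------
    DirichletLaplacePrior with zero mean (forced by symmetry) and the
    closed-form diagonal variances.
    """
    if K < 2:
        raise ValueError("K must be >= 2: the softmax basis is degenerate for K < 2")
    if total_concentration <= 0:
        raise ValueError("total_concentration must be positive")
    alpha = np.full(K, total_concentration / K, dtype=np.float64)
    mu, var = laplace_moments(alpha)
    mu = np.zeros_like(mu)  # exact for symmetric alpha; avoids rounding dust
    return DirichletLaplacePrior(alpha=alpha, mu_prior=mu, var_prior=var)


def build_prior_from_alpha(alpha: np.ndarray) -> DirichletLaplacePrior:
    """Laplace-approximated prior for a general (possibly asymmetric) alpha."""
    mu, var = laplace_moments(alpha)
    return DirichletLaplacePrior(alpha=np.asarray(alpha, float), mu_prior=mu, var_prior=var)


def kl_diag_gaussians(
    mean_q,
    var_q,
    mean_p=None,
    var_p=None,
) -> float:
    """KL( N(mean_q, diag var_q) || N(mean_p, diag var_p) ), closed form.

    Accepts either four K-vectors, or two distribution objects — anything
    with ``mean``/``var`` attributes (e.g. an encoder output) as q and a
    :class:`DirichletLaplacePrior` as p.  Returns a nonnegative scalar;
    raises on nonpositive variances or shape mismatch.
    """
    if mean_p is None and var_p is None:
        q, p = mean_q, var_q
        mean_q, var_q = q.mean, q.var
        mean_p, var_p = p.mu_prior, p.var_prior
    mean_q, var_q, mean_p, var_p = map(np.asarray, (mean_q, var_q, mean_p, var_p))
    if mean_q.shape != mean_p.shape:
        raise ValueError("dimension mismatch between q and p")
    if np.any(var_q <= 0) or np.any(var_p <= 0):
        raise ValueError("variances must be positive")
    terms = np.log(var_p / var_q) + (var_q + (mean_q - mean_p) ** 2) / var_p - 1.0
    return float(0.5 * np.sum(terms))
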