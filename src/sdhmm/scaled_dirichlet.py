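"""Scaled Dirichlet (SD) distribution on the probability simplex.

The SD density generalizes the Dirichlet with a second, scale parameter:

    SD(x | alpha, beta) = Gamma(sum_d alpha_d) / prod_d Gamma(alpha_d)
                          * prod_d beta_d^alpha_d x_d^(alpha_d - 1)
                          / (sum_d beta_d x_d)^(sum_d alpha_d)

for x on the (D-1)-simplex and strictly positive shape ``alpha`` and scale
``beta``.  When all entries of ``beta`` are equal the beta terms cancel and
the density reduces to Dirichlet(alpha).  The density is invariant to
rescaling ``beta`` by any positive constant, so ``beta`` is stored in the
canonical sum-to-one form.

All density work is done in log space via ``gammaln``; observations are
clamped away from the simplex boundary before evaluation because the
density is singular at x_d = 0 whenever alpha_d < 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SDParams",
    "clamp_simplex",
    "sd_logpdf",
    "sd_logpdf_grid",
    "sd_sample",
    "sd_moment_init",
]

#: Boundary clamp applied to simplex vectors before density evaluation.
SIMPLEX_EPS = 1e-10


@dataclass(frozen=True)
class SDParams:
    """Shape and scale of one scaled-Dirichlet component.

    ``beta`` is normalized to sum to one on construction (the density does
    not identify the scale of ``beta``).
    """

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if alpha.ndim != 1 or beta.ndim != 1 or alpha.shape != beta.shape:
            raise ValueError("alpha and beta must be 1-D vectors of equal length")
        if alpha.size < 2:
            raise ValueError("SD distribution needs dimension D >= 2")
        if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
            raise ValueError("alpha entries must be finite and > 0")
        if not np.all(np.isfinite(beta)) or np.any(beta <= 0):
            raise ValueError("beta entries must be finite and > 0")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta / beta.sum())

    @property
    def dim(self) -> int:
        return self.alpha.size

    def to_dict(self) -> dict:
        return {"alpha": self.alpha.tolist(), "beta": self.beta.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "SDParams":
        return cls(np.asarray(d["alpha"], float), np.asarray(d["beta"], float))


def clamp_simplex(x: np.ndarray, eps: float = SIMPLEX_EPS) -> np.ndarray:
    """Clamp entries of simplex vector(s) to [eps, 1-eps] and renormalize.

    Accepts a single vector or an (n, D) array of rows; always returns rows
    that sum to one with entries strictly inside (0, 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        # tolerate tiny negative noise only
        if np.any(x < -1e-8):
            raise ValueError("simplex vector has negative entries")
    y = np.clip(x, eps, 1.0 - eps)
    s = y.sum(axis=-1, keepdims=True)
    return y / s


def _check_simplex(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("observation contains non-finite entries")
    sums = x.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("observation rows must sum to 1 (apply to_simplex first)")
    return clamp_simplex(x)


def sd_logpdf(x: np.ndarray, params: SDParams) -> np.ndarray | float:
    """Natural-log SD density at ``x`` (one vector or rows of vectors)."""
    x = _check_simplex(x)
    a, b = params.alpha, params.beta
    if x.shape[-1] != a.size:
        raise ValueError(f"dimension mismatch: x has D={x.shape[-1]}, params D={a.size}")
    a0 = a.sum()
    const = gammaln(a0) - gammaln(a).sum() + float(np.dot(a, np.log(b)))
    val = const + (a - 1.0) @ np.log(x).T - a0 * np.log(x @ b)
    return float(val) if np.ndim(val) == 0 else np.asarray(val)


def sd_logpdf_grid(x: np.ndarray, alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Log density of every row of ``x`` under every (k, m) component.

    Parameters
    ----------
    x : (T, D) rows on the simplex (already clamped / validated upstream)
    alpha, beta : (K, M, D) positive arrays; beta rows need not be normalized
        (the density is scale-invariant in beta).

    Returns
    -------
    (T, K, M) array of log densities.
    """
    x = np.asarray(x, float)
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    a0 = alpha.sum(axis=-1)  # (K, M)
    const = gammaln(a0) - gammaln(alpha).sum(axis=-1) + (alpha * np.log(beta)).sum(axis=-1)
    logx = np.log(x)  # (T, D)
    shape_term = np.einsum("td,kmd->tkm", logx, alpha - 1.0)
    sbx = np.einsum("td,kmd->tkm", x, beta)
    return const[None, :, :] + shape_term - a0[None, :, :] * np.log(sbx)


def sd_sample(params: SDParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` simplex vectors from the SD distribution.

    Uses the change of variables x_d = (y_d / beta_d) / sum_k (y_k / beta_k)
    with y ~ Dirichlet(alpha); for equal beta this is the identity and the
    draws are plain Dirichlet(alpha).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    y = rng.dirichlet(params.alpha, size=n)
    z = y / params.beta
    return z / z.sum(axis=1, keepdims=True)


def sd_moment_init(data: np.ndarray) -> SDParams:
    """Moment-based initial SD parameters from simplex observations.

    ``beta`` starts uniform (1/D).  ``alpha`` is set by the Dirichlet method
    of moments: the common concentration s is estimated from the mean and
    variance of the first coordinate via s = m1 (1 - m1) / var - 1, then
    alpha_d = s * mean_d, clamped to [0.1, 100].  Degenerate (zero-variance)
    input falls back to alpha = 1.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be an (n, D) array")
    n, D = data.shape
    if n < 2:
        raise ValueError("moment initialization needs at least 2 observations")
    mean = data.mean(axis=0)
    var1 = data[:, 0].var()
    beta = np.full(D, 1.0 / D)
    if var1 <= 1e-12:
        return SDParams(np.ones(D), beta)
    m1 = mean[0]
    s = m1 * (1.0 - m1) / var1 - 1.0
    alpha = np.clip(s * mean, 0.1, 100.0)
    return SDParams(alpha, beta)
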