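"""Exact inference for hidden Markov models with mixture-of-SD emissions.

The generative model: an initial state h_1 ~ pi, a first-order chain
h_t ~ B[h_{t-1}, :], a per-state mixture component m_t ~ C[h_t, :], and an
emission x_t ~ SD(alpha[h_t, m_t], beta[h_t, m_t]) on the simplex.

Inference uses the classical scaled forward-backward recursion: per-step
normalization constants keep the recursion in a stable numeric range and
their logs accumulate into the sequence log-likelihood.  Mixture components
are collapsed with log-sum-exp when forming per-state emission likelihoods.
States and components are 0-based throughout this module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .scaled_dirichlet import SDParams, _check_simplex, sd_logpdf_grid

__all__ = [
    "HMMParams",
    "Responsibilities",
    "emission_log_matrix",
    "forward_backward",
    "brute_force_loglik",
    "decode",
]


def _check_stochastic(v: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < -1e-12):
        raise ValueError(f"{name} has negative entries")
    sums = v.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ValueError(f"{name} rows must sum to 1 (max dev {np.max(np.abs(sums - 1)):.2e})")
    return v


@dataclass(frozen=True)
class HMMParams:
    """Full parameter set of a K-state, M-component SD-HMM.

    pi : (K,) initial state probabilities
    B : (K, K) transition matrix, rows sum to 1
    C : (K, M) per-state mixture weights, rows sum to 1
    alpha, beta : (K, M, D) positive SD shape and scale parameters
    """

    pi: np.ndarray
    B: np.ndarray
    C: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        pi = _check_stochastic(np.asarray(self.pi, float), "pi", 1e-9)
        B = _check_stochastic(np.asarray(self.B, float), "B", 1e-9)
        C = _check_stochastic(np.asarray(self.C, float), "C", 1e-9)
        alpha = np.asarray(self.alpha, float)
        beta = np.asarray(self.beta, float)
        K = pi.size
        if B.shape != (K, K):
            raise ValueError("B must be K x K")
        if C.ndim != 2 or C.shape[0] != K:
            raise ValueError("C must be K x M")
        M = C.shape[1]
        if alpha.shape[:2] != (K, M) or alpha.shape != beta.shape or alpha.ndim != 3:
            raise ValueError("alpha/beta must be (K, M, D) arrays")
        if np.any(alpha <= 0) or np.any(beta <= 0):
            raise ValueError("alpha and beta must be strictly positive")
        for attr, val in (("pi", pi), ("B", B), ("C", C), ("alpha", alpha), ("beta", beta)):
            object.__setattr__(self, attr, val)

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_components(self) -> int:
        return self.C.shape[1]

    @property
    def dim(self) -> int:
        return self.alpha.shape[2]

    def sd(self, i: int, j: int) -> SDParams:
        """The SD emission component of state i, mixture component j."""
        return SDParams(self.alpha[i, j], self.beta[i, j])

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(*(np.asarray(d[k], float) for k in ("pi", "B", "C", "alpha", "beta")))


@dataclass
class Responsibilities:
    """Posterior assignment probabilities from forward-backward.

    gamma_sc : (T, K, M) state-component posteriors p(h_t=i, m_t=j | X)
    xi : (T-1, K, K) pairwise posteriors p(h_t=i, h_{t+1}=i' | X)
    gamma_init : (K,) posterior over the initial state
    loglik : log p(X | parameters)
    """

    gamma_sc: np.ndarray
    xi: np.ndarray
    gamma_init: np.ndarray
    loglik: float

    @property
    def gamma_state(self) -> np.ndarray:
        """(T, K) marginal state posteriors."""
        return self.gamma_sc.sum(axis=2)


def emission_log_matrix(seq: np.ndarray, params: HMMParams) -> np.ndarray:
    """(T, K, M) array with entry [t,i,j] = log C[i,j] + log SD(x_t | phi_ij)."""
    x = _check_simplex(np.atleast_2d(seq))
    if x.shape[1] != params.dim:
        raise ValueError(f"dimension mismatch: sequence D={x.shape[1]}, model D={params.dim}")
    with np.errstate(divide="ignore"):
        logC = np.log(params.C)
    return logC[None, :, :] + sd_logpdf_grid(x, params.alpha, params.beta)


def forward_backward(emissions: np.ndarray, pi: np.ndarray, B: np.ndarray) -> Responsibilities:
    """Exact posteriors for an HMM given a (T, K, M) emission log matrix.

    Runs the scaled forward-backward recursion over states after collapsing
    the mixture axis by log-sum-exp; the mixture posterior within each state
    is restored afterwards from the emission matrix.
    """
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 3:
        raise ValueError("emissions must be a (T, K, M) array")
    T, K, M = emissions.shape
    pi = _check_stochastic(pi, "pi")
    B = _check_stochastic(B, "B")
    pi = pi / pi.sum()
    B = B / B.sum(axis=1, keepdims=True)

    # collapse mixture: log p(x_t | h_t = i)
    log_state = logsumexp(emissions, axis=2)  # (T, K)
    bad = np.where(~np.isfinite(log_state.max(axis=1)))[0]
    if bad.size:
        raise ValueError(f"impossible observation: all emission likelihoods vanish at t={bad[0]}")

    # per-step shift keeps exp() in range; shifts rejoin the loglik at the end
    shift = log_state.max(axis=1)  # (T,)
    p = np.exp(log_state - shift[:, None])  # (T, K)

    alpha_hat = np.empty((T, K))
    scale = np.empty(T)
    a = pi * p[0]
    scale[0] = a.sum()
    alpha_hat[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha_hat[t - 1] @ B) * p[t]
        scale[t] = a.sum()
        if scale[t] <= 0 or not np.isfinite(scale[t]):
            raise ValueError(f"impossible observation: forward mass vanishes at t={t}")
        alpha_hat[t] = a / scale[t]

    beta_hat = np.empty((T, K))
    beta_hat[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta_hat[t] = (B @ (p[t + 1] * beta_hat[t + 1])) / scale[t + 1]

    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.empty((max(T - 1, 0), K, K))
    for t in range(T - 1):
        m = (alpha_hat[t][:, None] * B) * (p[t + 1] * beta_hat[t + 1])[None, :] / scale[t + 1]
        xi[t] = m / m.sum()

    # mixture posterior within each state
    with np.errstate(invalid="ignore"):
        comp = np.exp(emissions - log_state[:, :, None])
    comp = np.where(np.isfinite(comp), comp, 0.0)
    gamma_sc = gamma[:, :, None] * comp

    loglik = float(np.log(scale).sum() + shift.sum())
    return Responsibilities(gamma_sc=gamma_sc, xi=xi, gamma_init=gamma[0].copy(), loglik=loglik)


def brute_force_loglik(seq: np.ndarray, params: HMMParams) -> float:
    """Log-likelihood by exhaustive summation over every (state, component) path.

    Test oracle only: enumerates all K^T * M^T joint paths in log space.
    """
    x = np.atleast_2d(np.asarray(seq, float))
    T = x.shape[0]
    K, M = params.n_states, params.n_components
    if (K * M) ** T > 10**6:
        raise ValueError("instance too large for brute-force enumeration")
    em = emission_log_matrix(x, params)  # includes log C
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_B = np.log(params.B)
    terms = []
    for states in itertools.product(range(K), repeat=T):
        lp_chain = log_pi[states[0]]
        for t in range(1, T):
            lp_chain += log_B[states[t - 1], states[t]]
        if not np.isfinite(lp_chain):
            continue
        for comps in itertools.product(range(M), repeat=T):
            lp = lp_chain
            for t in range(T):
                lp += em[t, states[t], comps[t]]
            terms.append(lp)
    return float(logsumexp(terms))


def decode(seq: np.ndarray, params: HMMParams, method: str = "marginal") -> np.ndarray:
    """Most probable state per step.

    ``marginal`` (default) takes the per-step argmax of the marginal state
    posterior, which maximizes expected per-step agreement; ``viterbi``
    returns the jointly most probable path.  Ties break toward the lower
    state index.
    """
    x = np.atleast_2d(np.asarray(seq, float))
    em = emission_log_matrix(x, params)
    if method == "marginal":
        resp = forward_backward(em, params.pi, params.B)
        return resp.gamma_state.argmax(axis=1)
    if method == "viterbi":
        log_state = logsumexp(em, axis=2)
        with np.errstate(divide="ignore"):
            log_pi = np.log(params.pi)
            log_B = np.log(params.B)
        T, K = log_state.shape
        delta = np.empty((T, K))
        back = np.zeros((T, K), dtype=int)
        delta[0] = log_pi + log_state[0]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + log_B
            back[t] = cand.argmax(axis=0)
            delta[t] = cand[back[t], np.arange(K)] + log_state[t]
        path = np.empty(T, dtype=int)
        path[T - 1] = int(delta[T - 1].argmax())
        for t in range(T - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        return path
    raise ValueError(f"unknown decoding method: {method!r}")
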