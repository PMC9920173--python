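"""Mean-field variational Bayes for the scaled-Dirichlet HMM.

Conjugate-style priors: Dirichlet on the initial distribution pi, on each
transition row of B and each mixing row of C; independent Gamma(u, v) priors
on every SD shape entry alpha and a Dirichlet(h) prior on every SD scale
vector beta.  The mean-field posterior factorizes over
q(pi) q(B) q(C) q(alpha) q(beta) q(S, L) and is optimized by coordinate
updates:

* structural updates add expected assignment counts to the Dirichlet
  weights (w = responsibilities + prior);
* emission updates linearize the non-conjugate SD log-likelihood around the
  current posterior means alpha_bar = u*/v* and beta_bar = h*/sum(h*),
  giving additive corrections eta (to u), theta (to v, subtracted) and tau
  (to h);
* the E-step substitutes "tilde" quasi-parameters exp<ln pi>, exp<ln B>,
  exp<ln C> (sub-normalized by Jensen's inequality; renormalized before the
  forward-backward recursion) and the expected emission parameters into the
  exact forward-backward algorithm.

The convergence monitor is the data log-likelihood under the substituted
expected parameters; training stops when its relative change drops below
``tol`` or after ``max_iter`` sweeps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import digamma, polygamma

from .hmm import HMMParams, Responsibilities, forward_backward
from .scaled_dirichlet import clamp_simplex, sd_logpdf_grid, sd_moment_init

__all__ = [
    "PriorConfig",
    "VariationalPosterior",
    "ExpectedParams",
    "UpdateIntermediates",
    "FitConfig",
    "FitResult",
    "expected_params",
    "e_step",
    "m_step_structural",
    "m_step_emissions",
    "fit",
    "prune_components",
    "to_hmm_params",
    "save_checkpoint",
    "load_checkpoint",
]

#: Positivity floor for posterior hyperparameters (the subtraction in the
#: v update and extreme eta values can otherwise drive them non-positive).
HYPER_FLOOR = 1e-6


def _positive(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of all priors.

    phi_pi: (K,), phi_B: (K, K), phi_C: (K, M) Dirichlet pseudo-counts;
    u, v: (K, M, D) Gamma shape/rate for alpha; h: (K, M, D) Dirichlet for beta.
    """

    phi_pi: np.ndarray
    phi_B: np.ndarray
    phi_C: np.ndarray
    u: np.ndarray
    v: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        for name in ("phi_pi", "phi_B", "phi_C", "u", "v", "h"):
            object.__setattr__(self, name, _positive(name, getattr(self, name)))

    @classmethod
    def default(cls, K: int, M: int, D: int) -> "PriorConfig":
        """Weakly informative symmetric priors: phi = 1, u = 1, v = 0.1, h = 1."""
        return cls(
            phi_pi=np.ones(K),
            phi_B=np.ones((K, K)),
            phi_C=np.ones((K, M)),
            u=np.ones((K, M, D)),
            v=np.full((K, M, D), 0.1),
            h=np.ones((K, M, D)),
        )


@dataclass
class VariationalPosterior:
    """Factorized posterior: Dirichlet weights and Gamma/Dirichlet emission
    hyperparameters, shapes mirroring :class:`PriorConfig`."""

    w_pi: np.ndarray
    w_B: np.ndarray
    w_C: np.ndarray
    u_star: np.ndarray
    v_star: np.ndarray
    h_star: np.ndarray

    def validate(self) -> "VariationalPosterior":
        for name in ("w_pi", "w_B", "w_C", "u_star", "v_star", "h_star"):
            _positive(name, getattr(self, name))
        return self


@dataclass
class ExpectedParams:
    """Point quantities entering the E-step.

    pi_tilde, B_tilde, C_tilde are exp of expected logs under the Dirichlet
    posteriors; each row sums to at most 1 (sub-normalized).  alpha_bar is
    the Gamma posterior mean u*/v*, ln_alpha the expected log shape, and
    beta_bar the Dirichlet posterior mean of the scale (rows on the simplex).
    """

    pi_tilde: np.ndarray
    B_tilde: np.ndarray
    C_tilde: np.ndarray
    alpha_bar: np.ndarray
    ln_alpha: np.ndarray
    beta_bar: np.ndarray


class UpdateIntermediates(NamedTuple):
    """Additive corrections of one emission M-step (all (K, M, D))."""

    eta: np.ndarray
    theta: np.ndarray
    tau: np.ndarray


@dataclass(frozen=True)
class FitConfig:
    """Training configuration for :func:`fit`."""

    K: int
    M: int = 1
    tol: float = 1e-6
    max_iter: int = 200
    seed: int = 0
    prune_threshold: float = 0.0
    n_restarts: int = 1
    fix_beta_uniform: bool = False  # restricts to a Dirichlet-emission HMM

    def __post_init__(self) -> None:
        if self.K < 1 or self.M < 1 or self.max_iter < 1:
            raise ValueError("K, M and max_iter must be >= 1")
        if not (0 <= self.prune_threshold < 1):
            raise ValueError("prune_threshold must be in [0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "K": self.K, "M": self.M, "tol": self.tol, "max_iter": self.max_iter,
            "seed": self.seed, "prune_threshold": self.prune_threshold,
            "n_restarts": self.n_restarts, "fix_beta_uniform": self.fix_beta_uniform,
        }


@dataclass
class FitResult:
    """Outcome of variational training."""

    posterior: VariationalPosterior
    expected: ExpectedParams
    trace: list[float]
    config: FitConfig
    prior: PriorConfig

    @property
    def final_loglik(self) -> float:
        return self.trace[-1]

    def to_hmm_params(self) -> HMMParams:
        return to_hmm_params(self.expected)

    def decode(self, seq: np.ndarray, method: str = "marginal") -> np.ndarray:
        from .hmm import decode as _decode

        return _decode(clamp_simplex(np.atleast_2d(seq)), self.to_hmm_params(), method=method)


def expected_params(post: VariationalPosterior) -> ExpectedParams:
    """Expected (tilde and mean) parameters under the current posterior."""
    post.validate()
    pi_tilde = np.exp(digamma(post.w_pi) - digamma(post.w_pi.sum()))
    B_tilde = np.exp(digamma(post.w_B) - digamma(post.w_B.sum(axis=1, keepdims=True)))
    C_tilde = np.exp(digamma(post.w_C) - digamma(post.w_C.sum(axis=1, keepdims=True)))
    alpha_bar = post.u_star / post.v_star
    ln_alpha = digamma(post.u_star) - np.log(post.v_star)
    beta_bar = post.h_star / post.h_star.sum(axis=2, keepdims=True)
    return ExpectedParams(pi_tilde, B_tilde, C_tilde, alpha_bar, ln_alpha, beta_bar)


def e_step(seq: np.ndarray, exp: ExpectedParams) -> Responsibilities:
    """Responsibilities and monitor log-likelihood for one sequence.

    The emission log matrix combines the sub-normalized C_tilde weights with
    SD densities at (alpha_bar, beta_bar); pi_tilde and B_tilde rows are
    renormalized before the forward-backward recursion.
    """
    x = clamp_simplex(np.atleast_2d(np.asarray(seq, float)))
    em = np.log(exp.C_tilde)[None, :, :] + sd_logpdf_grid(x, exp.alpha_bar, exp.beta_bar)
    pi = exp.pi_tilde / exp.pi_tilde.sum()
    B = exp.B_tilde / exp.B_tilde.sum(axis=1, keepdims=True)
    return forward_backward(em, pi, B)


def m_step_structural(
    resp: Responsibilities | Sequence[Responsibilities], prior: PriorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dirichlet weight updates: expected counts plus prior pseudo-counts.

    With several sequences, transition and mixing counts accumulate across
    sequences while the initial-state responsibility averages over sequence
    starts.
    """
    resps = [resp] if isinstance(resp, Responsibilities) else list(resp)
    if not resps:
        raise ValueError("no responsibilities given")
    gamma_init = np.mean([r.gamma_init for r in resps], axis=0)
    w_pi = gamma_init + prior.phi_pi
    w_B = sum(r.xi.sum(axis=0) for r in resps) + prior.phi_B
    w_C = sum(r.gamma_sc.sum(axis=0) for r in resps) + prior.phi_C
    return w_pi, w_B, w_C


def _solve_scale_direction(
    X: np.ndarray, Z: np.ndarray, abar: np.ndarray, b0: np.ndarray, n_inner: int = 30
) -> np.ndarray:
    """Weighted stationary scale direction for one emission component.

    Solves E_Z[ b_d x_d / (b . x) ] = abar_d / sum(abar) for b on the
    simplex by a multiplicative fixed point (each sweep rescales b by the
    ratio of target to realized Dirichlet-transformed means).  This is the
    zero of the expected log-likelihood gradient with respect to the scale
    mean, the condition the additive scale correction linearizes.
    """
    target = abar / abar.sum()
    b = b0.copy()
    zsum = Z.sum()
    for _ in range(n_inner):
        y = b * X / (X @ b)[:, None]
        realized = (Z[:, None] * y).sum(axis=0) / zsum
        b = b * target / np.maximum(realized, 1e-300)
        b /= b.sum()
    return b


def m_step_emissions(
    data: np.ndarray | Sequence[np.ndarray],
    resp: Responsibilities | Sequence[Responsibilities],
    exp: ExpectedParams,
    prior: PriorConfig,
    fix_beta_uniform: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, UpdateIntermediates]:
    """Emission hyperparameter updates u* = u + eta, v* = v - theta, h* = h + tau.

    Per observation x with responsibility weight Z = gamma_sc[t, i, j]:

        eta_d   = Z * abar_d * [ psi(A) - psi(abar_d)
                                 + psi'(A) * sum_{s != d} abar_s (<ln a_s> - ln abar_s) ]
        theta_d = Z * [ ln bbar_d + ln x_d - ln(sum_k bbar_k x_k) ]

    with A = sum_d abar_d, summed over observations (and sequences); theta
    is never positive, so v* = v - theta stays positive.  The scale
    pseudo-counts tau distribute each component's total responsibility mass
    over dimensions along the stationary scale direction of the expected
    log-likelihood (see :func:`_solve_scale_direction`), so h* = h + tau is
    a proper Dirichlet posterior whose mean solves the scale stationarity
    condition and which collapses to the prior for an empty component.
    Hyperparameters are floored at a small positive constant as a last
    guard against degenerate responsibilities.
    """
    if isinstance(data, np.ndarray) and data.ndim <= 2:
        seqs = [np.atleast_2d(np.asarray(data, float))]
    else:
        seqs = [np.atleast_2d(np.asarray(s, float)) for s in data]
    resps = [resp] if isinstance(resp, Responsibilities) else list(resp)
    if len(seqs) != len(resps):
        raise ValueError("data/responsibility sequence counts differ")

    K, M, D = exp.alpha_bar.shape
    abar = exp.alpha_bar  # (K, M, D)
    bbar = exp.beta_bar
    A = abar.sum(axis=2, keepdims=True)  # (K, M, 1)
    # observation-independent bracket of eta
    g = abar * (exp.ln_alpha - np.log(abar))  # (K, M, D), each entry <= 0
    cross = polygamma(1, A) * (g.sum(axis=2, keepdims=True) - g)
    bracket = abar * (digamma(A) - digamma(abar) + cross)  # (K, M, D)

    eta = np.zeros((K, M, D))
    theta = np.zeros((K, M, D))
    tau = np.zeros((K, M, D))
    Xall = np.vstack([clamp_simplex(x) for x in seqs])
    Zall = np.concatenate([r.gamma_sc for r in resps], axis=0)  # (N, K, M)
    nz = Zall.sum(axis=0)  # (K, M)
    eta += nz[:, :, None] * bracket
    logx = np.log(Xall)  # (N, D)
    sbx = np.einsum("td,kmd->tkm", Xall, bbar)  # (N, K, M)
    theta += nz[:, :, None] * np.log(bbar)
    theta += np.einsum("tkm,td->kmd", Zall, logx)
    theta -= np.einsum("tkm,tkm->km", Zall, np.log(sbx))[:, :, None]
    if not fix_beta_uniform:
        # Gauss-Seidel ordering: the scale solve targets the freshly updated
        # shape mean, which keeps the coupled shape/scale iteration stable.
        abar_new = np.maximum(prior.u + eta, HYPER_FLOOR) / np.maximum(prior.v - theta, HYPER_FLOOR)
        for i in range(K):
            for j in range(M):
                if nz[i, j] <= 1e-12:
                    continue  # empty component: posterior stays at the prior
                b = _solve_scale_direction(Xall, Zall[:, i, j], abar_new[i, j], bbar[i, j])
                tau[i, j] = nz[i, j] * b

    inter = UpdateIntermediates(eta=eta, theta=theta, tau=tau)
    for name, arr in inter._asdict().items():
        if not np.all(np.isfinite(arr)):
            i, j, d = np.unravel_index(int(np.argmin(np.isfinite(arr))), arr.shape)
            raise ValueError(
                f"non-finite {name} at state {i}, component {j}, dimension {d}"
            )

    u_star = prior.u + eta
    v_star = prior.v - theta
    h_star = prior.h if fix_beta_uniform else prior.h + tau
    floored = (u_star < HYPER_FLOOR).any() or (v_star < HYPER_FLOOR).any() or (
        np.asarray(h_star) < HYPER_FLOOR
    ).any()
    if floored:
        warnings.warn("emission hyperparameters floored to keep posteriors proper")
    u_star = np.maximum(u_star, HYPER_FLOOR)
    v_star = np.maximum(v_star, HYPER_FLOOR)
    h_star = np.maximum(h_star, HYPER_FLOOR)
    return u_star, v_star, h_star, inter


def _kmeans_cells(X: np.ndarray, n_cells: int, rng: np.random.Generator, n_iter: int = 15) -> np.ndarray:
    """Seeded Lloyd-style partition of rows into ``n_cells`` cells."""
    n = X.shape[0]
    centers = X[rng.choice(n, size=n_cells, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        for c in range(n_cells):
            mask = labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:
                centers[c] = X[rng.integers(n)]
    return labels


def _initial_responsibilities(
    seqs: list[np.ndarray], cfg: FitConfig, rng: np.random.Generator
) -> list[Responsibilities]:
    """Smoothed one-hot responsibilities from a k-means-style partition."""
    K, M = cfg.K, cfg.M
    Xall = np.vstack(seqs)
    cells = _kmeans_cells(Xall, K * M, rng)
    out = []
    offset = 0
    for x in seqs:
        T = x.shape[0]
        lab = cells[offset : offset + T]
        offset += T
        gamma_sc = np.full((T, K, M), 0.1 / (K * M))
        flat = gamma_sc.reshape(T, K * M)
        flat[np.arange(T), lab] += 0.9
        gamma_sc = flat.reshape(T, K, M)
        gs = gamma_sc.sum(axis=2)  # (T, K)
        xi = gs[:-1, :, None] * gs[1:, None, :] if T > 1 else np.zeros((0, K, K))
        out.append(
            Responsibilities(gamma_sc=gamma_sc, xi=xi, gamma_init=gs[0].copy(), loglik=-np.inf)
        )
    return out


def _fit_once(
    seqs: list[np.ndarray], cfg: FitConfig, prior: PriorConfig, seed: int
) -> FitResult:
    rng = np.random.default_rng(seed)
    K, M, D = cfg.K, cfg.M, seqs[0].shape[1]

    resps = _initial_responsibilities(seqs, cfg, rng)

    # moment-init shape, perturbed per (state, component)
    base = sd_moment_init(np.vstack(seqs))
    alpha0 = np.clip(
        base.alpha[None, None, :] * np.exp(rng.normal(0.0, 0.25, size=(K, M, D))),
        0.1, 100.0,
    )
    scale0 = 10.0
    post = VariationalPosterior(
        w_pi=prior.phi_pi.copy(), w_B=prior.phi_B.copy(), w_C=prior.phi_C.copy(),
        u_star=scale0 * alpha0, v_star=np.full((K, M, D), scale0), h_star=prior.h.copy(),
    )
    # fold the initial partition into the posterior before the first E-step
    exp = expected_params(post)
    u, v, h, _ = m_step_emissions(seqs, resps, exp, prior, cfg.fix_beta_uniform)
    w_pi, w_B, w_C = m_step_structural(resps, prior)
    post = VariationalPosterior(w_pi, w_B, w_C, u, v, h)

    trace: list[float] = []
    prev = None
    for _ in range(cfg.max_iter):
        exp = expected_params(post)
        resps = [e_step(x, exp) for x in seqs]
        monitor = float(sum(r.loglik for r in resps))
        if not np.isfinite(monitor):
            if not trace:
                raise RuntimeError("initialization failed: no finite monitor after first iteration")
            break
        trace.append(monitor)
        if prev is not None and abs(monitor - prev) < cfg.tol * (abs(prev) + 1e-12):
            break
        prev = monitor
        u, v, h, _ = m_step_emissions(seqs, resps, exp, prior, cfg.fix_beta_uniform)
        w_pi, w_B, w_C = m_step_structural(resps, prior)
        post = VariationalPosterior(w_pi, w_B, w_C, u, v, h)

    return FitResult(posterior=post, expected=expected_params(post), trace=trace,
                     config=cfg, prior=prior)


def fit(
    data: np.ndarray | Sequence[np.ndarray],
    cfg: FitConfig,
    prior: PriorConfig | None = None,
) -> FitResult:
    """Variational training of the SD-HMM on one or more simplex sequences.

    Initializes from a seeded k-means-style partition plus a perturbed
    moment-based shape estimate, then alternates E-steps (responsibilities
    under expected parameters) with structural and emission posterior
    updates until the monitor converges.  With ``n_restarts > 1`` the
    restart with the best final monitor wins.  Fully deterministic for a
    fixed seed.
    """
    if isinstance(data, np.ndarray) and data.ndim == 2:
        seqs = [data]
    else:
        seqs = [np.atleast_2d(np.asarray(s, float)) for s in data]
    seqs = [clamp_simplex(s) for s in seqs]
    D = seqs[0].shape[1]
    if any(s.shape[1] != D for s in seqs):
        raise ValueError("all sequences must share the same dimension D")
    n_obs = sum(s.shape[0] for s in seqs)
    if cfg.K * cfg.M > n_obs:
        raise ValueError("K*M exceeds the number of observations")
    if prior is None:
        prior = PriorConfig.default(cfg.K, cfg.M, D)

    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_restarts) % (2**31)
    best: FitResult | None = None
    for s in seeds:
        res = _fit_once(seqs, cfg, prior, int(s))
        if best is None or res.final_loglik > best.final_loglik:
            best = res
    assert best is not None
    return best


def prune_components(
    exp: ExpectedParams, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Flag mixture components whose expected mixing weight falls below
    ``threshold`` and renormalize each state's weights over the survivors.

    Returns (mask, C) where mask is a (K, M) boolean array of active
    components and C the renormalized mixing matrix (zeros at pruned cells).
    """
    weights = exp.C_tilde / exp.C_tilde.sum(axis=1, keepdims=True)
    mask = weights >= threshold
    dead_states = ~mask.any(axis=1)
    if dead_states.any():
        raise ValueError(f"all components pruned in state {int(np.where(dead_states)[0][0])}")
    C = np.where(mask, weights, 0.0)
    C /= C.sum(axis=1, keepdims=True)
    return mask, C


def to_hmm_params(exp: ExpectedParams) -> HMMParams:
    """Point-estimate HMM parameters from expected quantities (tilde rows
    renormalized, emissions at posterior means)."""
    return HMMParams(
        pi=exp.pi_tilde / exp.pi_tilde.sum(),
        B=exp.B_tilde / exp.B_tilde.sum(axis=1, keepdims=True),
        C=exp.C_tilde / exp.C_tilde.sum(axis=1, keepdims=True),
        alpha=exp.alpha_bar,
        beta=exp.beta_bar / exp.beta_bar.sum(axis=2, keepdims=True),
    )


def save_checkpoint(path, result: FitResult) -> None:
    """Write a fitted model as a JSON checkpoint."""
    payload = {
        "w_pi": result.posterior.w_pi.tolist(),
        "w_B": result.posterior.w_B.tolist(),
        "w_C": result.posterior.w_C.tolist(),
        "u_star": result.posterior.u_star.tolist(),
        "v_star": result.posterior.v_star.tolist(),
        "h_star": result.posterior.h_star.tolist(),
        "config": result.config.to_dict(),
        "monitor_trace": result.trace,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_checkpoint(path) -> FitResult:
    """Load a JSON checkpoint written by :func:`save_checkpoint`."""
    with open(path) as fh:
        payload = json.load(fh)
    post = VariationalPosterior(
        *(np.asarray(payload[k], float) for k in ("w_pi", "w_B", "w_C", "u_star", "v_star", "h_star"))
    )
    cfg = FitConfig(**payload["config"])
    K, M, D = post.u_star.shape
    return FitResult(
        posterior=post,
        expected=expected_params(post),
        trace=list(payload["monitor_trace"]),
        config=cfg,
        prior=PriorConfig.default(K, M, D),
    )
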