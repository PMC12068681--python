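"""Single-subject Gaussian HMM machinery.

States are labelled 1..m in user-facing :class:`StateSequence` objects
(0 marks an undefined day); internal arrays are 0-based.  Emissions are
multivariate Gaussian with conditional independence of items given the
state (diagonal covariance), and missing items simply drop out of the
per-day emission density.  Transition rows are parameterised as
multinomial logits against the self-transition (the i -> i logit is fixed
at 0), so covariate and random effects read as switching propensities.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SubjectParams",
    "StateSequence",
    "logits_to_probs",
    "probs_to_logits",
    "emission_logdensity",
    "forward_loglik",
    "ffbs_sample",
    "viterbi",
    "em_fit_single_level",
    "aic",
    "stationary_dist",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# logit parameterisation

def _offdiag_to_full(logits: np.ndarray) -> np.ndarray:
    """Insert the fixed 0 self-logit: (..., m, m-1) -> (..., m, m)."""
    logits = np.asarray(logits, dtype=float)
    m = logits.shape[-2]
    if logits.shape[-1] != m - 1:
        raise ValueError("expected shape (..., m, m-1)")
    full = np.zeros(logits.shape[:-1] + (m,))
    for i in range(m):
        cols = [j for j in range(m) if j != i]
        full[..., i, cols] = logits[..., i, :]
    return full


def logits_to_probs(logits: np.ndarray) -> np.ndarray:
    """Map row logits (m, m-1), self category fixed at 0, to a stochastic matrix.

    Accepts any leading batch dimensions.  Overflow-guarded softmax.
    """
    full = _offdiag_to_full(logits)
    full = full - full.max(axis=-1, keepdims=True)
    ex = np.exp(full)
    return ex / ex.sum(axis=-1, keepdims=True)


def probs_to_logits(transition: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Inverse of :func:`logits_to_probs`: log(p_ij / p_ii) off the diagonal."""
    p = np.clip(np.asarray(transition, dtype=float), floor, None)
    m = p.shape[-1]
    out = np.empty(p.shape[:-2] + (m, m - 1))
    for i in range(m):
        cols = [j for j in range(m) if j != i]
        out[..., i, :] = np.log(p[..., i, cols]) - np.log(p[..., i, i:i + 1])
    return out


# ---------------------------------------------------------------------------
# parameter containers

@dataclasses.dataclass
class SubjectParams:
    """One subject's (or one pooled) m-state Gaussian HMM parameters."""

    emission_mean: np.ndarray            # (m, q)
    emission_sd: np.ndarray              # (m, q), > 0
    transition: np.ndarray               # (m, m) row-stochastic
    initial_dist: np.ndarray | None = None  # (m,); default = stationary dist

    def __post_init__(self) -> None:
        self.emission_mean = np.atleast_2d(np.asarray(self.emission_mean, float))
        self.emission_sd = np.atleast_2d(np.asarray(self.emission_sd, float))
        self.transition = np.atleast_2d(np.asarray(self.transition, float))
        m = self.transition.shape[0]
        if self.transition.shape != (m, m):
            raise ValueError("transition must be square")
        if self.emission_mean.shape[0] != m or self.emission_sd.shape != self.emission_mean.shape:
            raise ValueError("emission parameter shapes inconsistent with m")
        if np.any(self.emission_sd <= 0):
            raise ValueError("emission_sd must be positive")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition rows must sum to 1")
        if self.initial_dist is None:
            self.initial_dist, _ = stationary_dist(self.transition)
        else:
            self.initial_dist = np.asarray(self.initial_dist, float)
            if abs(self.initial_dist.sum() - 1.0) > 1e-8:
                raise ValueError("initial_dist must sum to 1")

    @property
    def m(self) -> int:
        return self.transition.shape[0]

    @property
    def q(self) -> int:
        return self.emission_mean.shape[1]

    @property
    def transition_logits(self) -> np.ndarray:
        return probs_to_logits(self.transition)


@dataclasses.dataclass
class StateSequence:
    """A decoded or sampled state path; states 1..m, 0 = undefined."""

    subject_id: str
    states: np.ndarray
    log_posterior_score: float = np.nan

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    @property
    def defined(self) -> np.ndarray:
        return self.states > 0


# ---------------------------------------------------------------------------
# emission densities

def emission_logdensity(params: SubjectParams, obs: np.ndarray, state: int) -> float:
    """Log density of one day's observation vector in 1-based ``state``.

    Missing items (NaN) are marginalised out; an all-missing day carries no
    evidence and returns 0.0.
    """
    if not 1 <= state <= params.m:
        raise ValueError("state out of range")
    obs = np.asarray(obs, dtype=float)
    seen = ~np.isnan(obs)
    if not np.all(np.isfinite(obs[seen])):
        raise ValueError("observed values must be finite")
    mu = params.emission_mean[state - 1, seen]
    sd = params.emission_sd[state - 1, seen]
    z = (obs[seen] - mu) / sd
    return float(np.sum(-0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI))


def _log_emission_matrix(params: SubjectParams, obs_seq: np.ndarray) -> np.ndarray:
    """(T, m) log emission densities with missing items marginalised."""
    obs_seq = np.atleast_2d(np.asarray(obs_seq, dtype=float))
    seen = ~np.isnan(obs_seq)
    if not np.all(np.isfinite(obs_seq[seen])):
        raise ValueError("observed values must be finite")
    y = np.where(seen, obs_seq, 0.0)[:, None, :]           # (T, 1, q)
    mu = params.emission_mean[None, :, :]                   # (1, m, q)
    sd = params.emission_sd[None, :, :]
    z = (y - mu) / sd
    per_item = -0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI
    return np.where(seen[:, None, :], per_item, 0.0).sum(axis=2)


# ---------------------------------------------------------------------------
# recursions

def _forward_scaled(log_b: np.ndarray, transition: np.ndarray,
                    initial: np.ndarray):
    """Scaled forward pass.

    Returns (loglik, alpha) where alpha[t] is the filtered state
    distribution p(S_t | y_1..t).  Per-day emission weights are rescaled by
    their maximum before exponentiation, which is the streaming equivalent
    of a log-sum-exp and keeps the recursion finite for any finite inputs.
    """
    t_len, m = log_b.shape
    alpha = np.empty((t_len, m))
    loglik = 0.0
    shift = log_b.max(axis=1)
    b = np.exp(log_b - shift[:, None])
    a = initial * b[0]
    norm = a.sum()
    alpha[0] = a / norm
    loglik += np.log(norm) + shift[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ transition) * b[t]
        norm = a.sum()
        alpha[t] = a / norm
        loglik += np.log(norm) + shift[t]
    return float(loglik), alpha


def forward_loglik(params: SubjectParams, obs_seq: np.ndarray):
    """Total marginal log-likelihood and log forward (filtered) probabilities.

    Returns ``(loglik, log_alpha)`` with ``log_alpha`` of shape (T, m)
    holding log p(S_t = i | y_1..t).
    """
    log_b = _log_emission_matrix(params, obs_seq)
    loglik, alpha = _forward_scaled(log_b, params.transition, params.initial_dist)
    with np.errstate(divide="ignore"):
        return loglik, np.log(alpha)


def ffbs_sample(params: SubjectParams, obs_seq: np.ndarray,
                rng: np.random.Generator,
                subject_id: str = "") -> StateSequence:
    """Draw a full state path from p(S_1..S_T | y, params) by FFBS."""
    log_b = _log_emission_matrix(params, obs_seq)
    _, alpha = _forward_scaled(log_b, params.transition, params.initial_dist)
    t_len, m = alpha.shape
    states = np.empty(t_len, dtype=int)
    states[-1] = rng.choice(m, p=alpha[-1])
    for t in range(t_len - 2, -1, -1):
        w = alpha[t] * params.transition[:, states[t + 1]]
        states[t] = rng.choice(m, p=w / w.sum())
    return StateSequence(subject_id=subject_id, states=states + 1)


def ffbs_path_logprob(params: SubjectParams, obs_seq: np.ndarray,
                      path: np.ndarray) -> float:
    """Log probability that :func:`ffbs_sample` draws ``path`` (1-based).

    The backward-sampling law factorises as p(S_T | y) * prod p(S_t | S_t+1, y);
    multiplying the realised conditionals gives the exact path posterior, so
    this is a deterministic handle on the sampling distribution.
    """
    path = np.asarray(path, dtype=int) - 1
    log_b = _log_emission_matrix(params, obs_seq)
    t_len, _ = log_b.shape
    with np.errstate(divide="ignore"):
        log_trans = np.log(params.transition)
        log_init = np.log(params.initial_dist)
    # unnormalised log forward; full log-space so that astronomically
    # unlikely paths still get a finite log probability
    la = np.empty_like(log_b)
    la[0] = log_init + log_b[0]
    for t in range(1, t_len):
        la[t] = logsumexp(la[t - 1][:, None] + log_trans, axis=0) + log_b[t]
    lp = la[-1, path[-1]] - logsumexp(la[-1])
    for t in range(t_len - 2, -1, -1):
        w = la[t] + log_trans[:, path[t + 1]]
        lp += w[path[t]] - logsumexp(w)
    return float(lp)


def viterbi(params: SubjectParams, obs_seq: np.ndarray,
            subject_id: str = "") -> StateSequence:
    """Most likely state path; ties break to the lower state index."""
    log_b = _log_emission_matrix(params, obs_seq)
    t_len, m = log_b.shape
    with np.errstate(divide="ignore"):
        log_trans = np.log(params.transition)
        log_init = np.log(params.initial_dist)
    score = log_init + log_b[0]
    back = np.zeros((t_len, m), dtype=int)
    for t in range(1, t_len):
        cand = score[:, None] + log_trans            # (from, to)
        back[t] = np.argmax(cand, axis=0)            # first max -> lowest index
        score = cand[back[t], np.arange(m)] + log_b[t]
    states = np.empty(t_len, dtype=int)
    states[-1] = int(np.argmax(score))
    best = float(score[states[-1]])
    for t in range(t_len - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return StateSequence(subject_id=subject_id, states=states + 1,
                         log_posterior_score=best)


# ---------------------------------------------------------------------------
# model selection and stationary distribution

def aic(loglik: float, n_free_params: int) -> float:
    """Akaike information criterion: -2 log L + 2 p."""
    return -2.0 * loglik + 2.0 * n_free_params


def stationary_dist(transition: np.ndarray):
    """Stationary distribution of a row-stochastic matrix.

    Returns ``(pi, unique)``; when the stationary distribution is not
    unique (multiplicity of the unit eigenvalue > 1) the uniform
    distribution is returned with ``unique=False``.
    """
    p = np.asarray(transition, dtype=float)
    m = p.shape[0]
    vals, vecs = np.linalg.eig(p.T)
    close = np.abs(vals - 1.0) < 1e-8
    if close.sum() != 1:
        return np.full(m, 1.0 / m), False
    v = np.real(vecs[:, close][:, 0])
    v = np.abs(v)
    return v / v.sum(), True


# ---------------------------------------------------------------------------
# single-level EM (Baum-Welch) used to initialise the Bayesian sampler

def _log_emissions_batch(y: np.ndarray, seen: np.ndarray, mu: np.ndarray,
                         sd: np.ndarray) -> np.ndarray:
    """(N, T, m) log emission densities; missing items contribute 0.

    ``mu``/``sd`` may be shared (m, q) or per-subject (N, m, q).
    """
    if mu.ndim == 2:
        mu = mu[None]
    sd = np.broadcast_to(sd, mu.shape) if np.ndim(sd) else np.asarray(sd)
    if sd.ndim == 2:
        sd = sd[None]
    yz = np.where(seen, y, 0.0)
    z = (yz[:, :, None, :] - mu[:, None, :, :]) / sd[:, None, :, :]
    per_item = -0.5 * z * z - np.log(sd)[:, None, :, :] - 0.5 * _LOG2PI
    return np.where(seen[:, :, None, :], per_item, 0.0).sum(axis=3)


def _em_e_step_batch(y: np.ndarray, seen: np.ndarray, params: SubjectParams):
    """Forward-backward sufficient statistics, vectorised over subjects.

    Returns (total loglik, gamma (N, T, m), xi_sum (m, m), gamma0 (m,)).
    """
    log_b = _log_emissions_batch(y, seen, params.emission_mean,
                                 params.emission_sd)
    n, t_len, m = log_b.shape
    trans = params.transition
    shift = log_b.max(axis=2)
    b = np.exp(log_b - shift[:, :, None])
    alpha = np.empty((n, t_len, m))
    a = params.initial_dist * b[:, 0]
    norm = a.sum(axis=1, keepdims=True)
    alpha[:, 0] = a / norm
    loglik = (np.log(norm[:, 0]) + shift[:, 0]).sum()
    for t in range(1, t_len):
        a = (alpha[:, t - 1] @ trans) * b[:, t]
        norm = a.sum(axis=1, keepdims=True)
        alpha[:, t] = a / norm
        loglik += (np.log(norm[:, 0]) + shift[:, t]).sum()
    beta = np.empty((n, t_len, m))
    beta[:, -1] = 1.0
    xi_sum = np.zeros((m, m))
    for t in range(t_len - 2, -1, -1):
        bb = b[:, t + 1] * beta[:, t + 1]
        beta[:, t] = bb @ trans.T
        xi = trans[None] * alpha[:, t, :, None] * bb[:, None, :]
        xi_sum += (xi / xi.sum(axis=(1, 2), keepdims=True)).sum(axis=0)
        beta[:, t] /= beta[:, t].max(axis=1, keepdims=True)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return float(loglik), gamma, xi_sum, gamma[:, 0].sum(axis=0)


def _quantile_start(y_all: np.ndarray, m: int, q: int,
                    sd_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic means/SDs start: per-item quantile blocks."""
    means = np.empty((m, q))
    sds = np.empty((m, q))
    for k in range(q):
        col = y_all[:, k]
        col = col[~np.isnan(col)]
        if col.size == 0:
            means[:, k], sds[:, k] = 50.0, 10.0
            continue
        edges = np.quantile(col, np.linspace(0, 1, m + 1))
        for i in range(m):
            blk = col[(col >= edges[i]) & (col <= edges[i + 1])]
            means[i, k] = blk.mean() if blk.size else col.mean()
        sds[:, k] = max(col.std() / m, sd_floor)
    return means, sds


def em_fit_single_level(panel, m: int, *, n_restarts: int = 10,
                        max_iter: int = 500, tol: float = 1e-6,
                        sd_floor: float = 0.5, seed: int = 0):
    """Pooled (single-level) Baum-Welch fit over all subjects.

    All subjects share one parameter set; subject sequences are treated as
    independent realisations.  Multi-start: one deterministic quantile-based
    start plus seeded jitters; the best local optimum is returned together
    with its log-likelihood.

    Returns ``(params, loglik, history)`` where history is the per-iteration
    loglik trace of the winning restart (non-decreasing).
    """
    y = panel.y
    n, t_len, q = y.shape
    rng = np.random.default_rng(seed)
    flat = y.reshape(-1, q)
    base_mu, base_sd = _quantile_start(flat, m, q, sd_floor)

    distinct = np.unique(flat[~np.isnan(flat).all(axis=1)], axis=0).shape[0]
    if m > distinct:
        import warnings
        warnings.warn(f"m={m} exceeds the {distinct} distinct observed "
                      "profiles; fit is best-effort", stacklevel=2)

    best = None
    for r in range(max(1, n_restarts)):
        mu = base_mu if r == 0 else base_mu + rng.normal(0, base_sd.mean(), base_mu.shape)
        sd = np.maximum(base_sd, sd_floor)
        trans = (np.full((m, m), 0.5 / (m - 1)) if m > 1
                 else np.ones((1, 1)))
        np.fill_diagonal(trans, 0.5 if m > 1 else 1.0)
        pi = np.full(m, 1.0 / m)
        params = SubjectParams(mu.copy(), sd.copy(), trans.copy(), pi.copy())
        prev = -np.inf
        history = []
        seen = ~np.isnan(y)
        yy = np.where(seen, y, 0.0)
        for _ in range(max_iter):
            tot, gamma, xi_tot, g0 = _em_e_step_batch(y, seen, params)
            g_sum = np.einsum("ntm,ntq->mq", gamma, seen.astype(float))
            gy_sum = np.einsum("ntm,ntq->mq", gamma, yy * seen)
            gy2_sum = np.einsum("ntm,ntq->mq", gamma, yy * yy * seen)
            history.append(tot)
            if tot - prev < tol * (abs(prev) + 1.0) and np.isfinite(prev):
                break
            prev = tot
            denom = np.maximum(g_sum, 1e-12)
            mu_new = gy_sum / denom
            var_new = gy2_sum / denom - mu_new ** 2
            sd_new = np.sqrt(np.maximum(var_new, sd_floor ** 2))
            trans_new = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), 1e-12)
            trans_new = np.clip(trans_new, 1e-8, None)
            trans_new /= trans_new.sum(axis=1, keepdims=True)
            pi_new = g0 / g0.sum()
            params = SubjectParams(mu_new, sd_new, trans_new, pi_new)
        if best is None or history[-1] > best[1]:
            best = (params, history[-1], history)
    params, loglik, history = best
    # severity ordering: states sorted by total emission mean across items
    order = np.argsort(params.emission_mean.sum(axis=1), kind="stable")
    params = SubjectParams(params.emission_mean[order],
                           params.emission_sd[order],
                           params.transition[np.ix_(order, order)],
                           params.initial_dist[order])
    return params, loglik, np.asarray(history)


# ---------------------------------------------------------------------------
# brute-force oracles (tiny problems only; used by the test-suite and kept
# here so independent code can cross-check the recursions)

def enumerate_path_logliks(params: SubjectParams, obs_seq: np.ndarray):
    """Joint log p(path, y) for every one of the m**T paths (tiny T only)."""
    log_b = _log_emission_matrix(params, obs_seq)
    t_len, m = log_b.shape
    if m ** t_len > 200_000:
        raise ValueError("path enumeration is for tiny problems only")
    with np.errstate(divide="ignore"):
        log_trans = np.log(params.transition)
        log_init = np.log(params.initial_dist)
    paths = np.stack(np.meshgrid(*([np.arange(m)] * t_len), indexing="ij"),
                     axis=-1).reshape(-1, t_len)
    lp = log_init[paths[:, 0]] + log_b[0, paths[:, 0]]
    for t in range(1, t_len):
        lp = lp + log_trans[paths[:, t - 1], paths[:, t]] + log_b[t, paths[:, t]]
    return paths + 1, lp


def brute_force_loglik(params: SubjectParams, obs_seq: np.ndarray) -> float:
    _, lp = enumerate_path_logliks(params, obs_seq)
    return float(logsumexp(lp))


def brute_force_viterbi(params: SubjectParams, obs_seq: np.ndarray):
    paths, lp = enumerate_path_logliks(params, obs_seq)
    best = int(np.argmax(lp))  # ties -> lexicographically smallest path
    return paths[best], float(lp[best])
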