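"""Bayesian multilevel HMM: hybrid Metropolis-within-Gibbs sampler.

Model
-----
Subject j's day-t item scores y_jt are Gaussian given the latent substate
S_jt: y_jtk ~ N(mu_jik, sigma2_ik) with subject emission means partially
pooled, mu_jik ~ N(mubar_ik, tau2_ik).  Each subject's transition rows are
multinomial-logit with the self-transition as reference; the m(m-1)
off-diagonal logits are Normal around gamma_bar + beta' x_j with
independent random-effect variances psi2 (x_j are optional 0/1 dummy
covariates such as severity-subgroup indicators).

Each MCMC iteration: (1) FFBS draw of every subject's state path; (2)
imputation of missing items from the emission distribution of the sampled
state; (3) conjugate Gibbs updates of subject means, group means,
between-subject and residual variances; (4) random-walk Metropolis on each
subject's transition-logit rows, with proposal scales adapted toward a
~0.35 acceptance rate during burn-in and frozen afterwards; (5) conjugate
Gibbs updates of the logit-level regression (gamma_bar, beta, psi2).

The main chain is initialised from a pooled single-level EM fit; extra
chains from randomised perturbations of it.  States are kept on a severity
ordering (increasing total group emission mean) which is re-asserted on
the stored draws after sampling.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PriorConfig
from .hmm import (SubjectParams, _log_emissions_batch, _offdiag_to_full,
                  em_fit_single_level, aic, forward_loglik, logits_to_probs,
                  probs_to_logits)
from .panel import DiaryPanel

__all__ = [
    "GroupParams",
    "PosteriorDraws",
    "fit_mhmm",
    "impute_missing",
    "subject_posterior_means",
    "subgroup_dummies",
    "multilevel_aic",
    "normal_posterior",
    "scaled_invchi2_posterior",
    "sample_scaled_invchi2",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# conjugate building blocks (exposed for direct verification)

def normal_posterior(prior_mean, prior_var, sum_y, n, lik_var):
    """Posterior (mean, var) of a Normal mean with known likelihood variance.

    Prior N(prior_mean, prior_var); data: n observations with sum ``sum_y``
    and per-observation variance ``lik_var``.  All arguments broadcast.
    """
    prec = n / lik_var + 1.0 / prior_var
    mean = (sum_y / lik_var + prior_mean / prior_var) / prec
    return mean, 1.0 / prec


def scaled_invchi2_posterior(df0, scale0, sse, n):
    """Posterior (df, scale) of a variance with scaled-inverse-chi^2 prior.

    Prior Scale-inv-chi2(df0, scale0); data: ``n`` residuals with sum of
    squares ``sse``.
    """
    df = df0 + n
    scale = (df0 * scale0 + sse) / df
    return df, scale


def regression_coef_posterior(x1: np.ndarray, resp: np.ndarray,
                              noise_var: float, prior_prec: np.ndarray):
    """Posterior (mean, cov) of Gaussian regression coefficients.

    Model resp = x1 @ coef + e, e ~ N(0, noise_var); prior coef ~
    N(0, prior_prec^{-1}).  Used for the transition-logit level
    (intercept = group logit mean, slopes = covariate coefficients).
    """
    a_mat = x1.T @ x1 / noise_var + prior_prec
    mean = np.linalg.solve(a_mat, x1.T @ resp / noise_var)
    return mean, np.linalg.inv(a_mat)


def sample_scaled_invchi2(rng: np.random.Generator, df, scale, size=None):
    """Draw from Scale-inv-chi2(df, scale) = df * scale / chi2_df."""
    df = np.asarray(df, float)
    scale = np.asarray(scale, float)
    if size is None:
        size = np.broadcast(df, scale).shape
    return df * scale / rng.chisquare(np.broadcast_to(df, size))


# ---------------------------------------------------------------------------
# containers

@dataclasses.dataclass
class GroupParams:
    """Group-level parameters of an m-state multilevel HMM."""

    mu_bar: np.ndarray               # (m, q) group emission means
    tau2: np.ndarray                 # (m, q) between-subject variances
    sigma2: np.ndarray               # (m, q) residual variances
    gamma_bar: np.ndarray            # (m, m-1) group transition-logit means
    psi2: np.ndarray                 # (m, m-1) logit random-effect variances
    beta: np.ndarray | None = None   # (C, m, m-1) covariate coefficients

    def __post_init__(self) -> None:
        m, q = np.shape(self.mu_bar)
        for name in ("tau2", "sigma2"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.shape(self.gamma_bar) != (m, m - 1):
            raise ValueError("gamma_bar must be (m, m-1)")

    @property
    def m(self) -> int:
        return self.mu_bar.shape[0]


@dataclasses.dataclass
class PosteriorDraws:
    """Kept MCMC draws from one or more chains.

    ``group`` maps parameter names (mu_bar, tau2, sigma2, gamma_bar, psi2,
    beta) to arrays of shape (n_chains, n_kept, ...).  Subject-level draws
    are stored every iteration; state paths are thinned (``path_thin``).
    """

    m: int
    q: int
    group: dict
    subject_mu: np.ndarray            # (n_chains, K, N, m, q)
    subject_logits: np.ndarray        # (n_chains, K, N, m, m-1)
    paths: np.ndarray                 # (n_chains, K_paths, N, T), 1-based
    path_thin: int
    accept_rate: np.ndarray           # (n_chains, N, m)
    covariates: np.ndarray | None
    subject_ids: list
    item_names: list
    iterations: int
    burn_in: int
    seed: int | None
    n_empty_state_events: int = 0

    @property
    def n_chains(self) -> int:
        return self.subject_mu.shape[0]

    @property
    def n_kept(self) -> int:
        return self.subject_mu.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.subject_mu.shape[2]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    def group_names_and_matrix(self):
        """Flatten group-level draws to (n_chains, n_kept, P) plus names."""
        cols, names = [], []
        for key in ("mu_bar", "tau2", "sigma2", "gamma_bar", "psi2", "beta"):
            if key not in self.group:
                continue
            arr = self.group[key]
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            cols.append(flat)
            idx = np.indices(arr.shape[2:]).reshape(len(arr.shape) - 2, -1).T
            names += [key + "[" + ",".join(map(str, ix)) + "]" for ix in idx]
        return names, np.concatenate(cols, axis=2)

    def summary(self) -> pd.DataFrame:
        """Posterior mean / SD / 95% CrI per group-level parameter."""
        names, mat = self.group_names_and_matrix()
        flat = mat.reshape(-1, mat.shape[-1])
        return pd.DataFrame({
            "parameter": names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": np.quantile(flat, 0.025, axis=0),
            "q97.5": np.quantile(flat, 0.975, axis=0),
        })

    def posterior_group_params(self, point: str = "mean") -> GroupParams:
        """Pooled-chain posterior point estimate of the group parameters."""
        fn = {"mean": np.mean, "median": np.median}[point]
        est = {k: fn(v, axis=(0, 1)) for k, v in self.group.items()}
        return GroupParams(mu_bar=est["mu_bar"], tau2=est["tau2"],
                           sigma2=est["sigma2"], gamma_bar=est["gamma_bar"],
                           psi2=est["psi2"], beta=est.get("beta"))


def subgroup_dummies(subgroup: np.ndarray):
    """0/1 dummy coding of an ordered categorical label, reference = first.

    Returns ``(X (N, G-1), categories)``.
    """
    cats = sorted(set(np.asarray(subgroup).tolist()))
    x = np.column_stack([(np.asarray(subgroup) == c).astype(float)
                         for c in cats[1:]]) if len(cats) > 1 else np.zeros((len(subgroup), 0))
    return x, cats


# ---------------------------------------------------------------------------
# initial values

def _severity_order(mu: np.ndarray) -> np.ndarray:
    return np.argsort(mu.sum(axis=1), kind="stable")


def _initial_values(panel: DiaryPanel, m: int, cov_x: np.ndarray | None,
                    rng: np.random.Generator, perturb: bool,
                    em_params: SubjectParams):
    q = panel.n_items
    n = panel.n_subjects
    c = 0 if cov_x is None else cov_x.shape[1]
    mu_bar = em_params.emission_mean.copy()
    sigma2 = np.maximum(em_params.emission_sd ** 2, 0.25)
    gamma_bar = probs_to_logits(np.clip(em_params.transition, 1e-4, None)
                                / np.clip(em_params.transition, 1e-4, None).sum(1, keepdims=True))
    if perturb:
        mu_bar = mu_bar + rng.normal(0.0, 5.0, mu_bar.shape)
        gamma_bar = gamma_bar + rng.normal(0.0, 0.5, gamma_bar.shape)
        sigma2 = sigma2 * np.exp(rng.normal(0.0, 0.3, sigma2.shape))
    init = {
        "mu_bar": mu_bar,
        "tau2": np.full((m, q), 25.0),
        "sigma2": sigma2,
        "gamma_bar": gamma_bar,
        "psi2": np.full((m, m - 1), 0.25),
        "beta": np.zeros((c, m, m - 1)),
        "subject_mu": np.tile(mu_bar, (n, 1, 1)) + rng.normal(0.0, 1.0, (n, m, q)),
        "subject_logits": np.tile(gamma_bar, (n, 1, 1))
        + rng.normal(0.0, 0.2, (n, m, m - 1)),
    }
    return init


# ---------------------------------------------------------------------------
# vectorised recursions over all subjects

def _stationary_batch(gamma: np.ndarray) -> np.ndarray:
    """Stationary rows of a batch (N, m, m) of strictly positive transition
    matrices, via the linear system pi (P - I) = 0, sum(pi) = 1."""
    n, m, _ = gamma.shape
    a = np.transpose(gamma, (0, 2, 1)) - np.eye(m)[None]
    a[:, -1, :] = 1.0
    b = np.zeros((n, m))
    b[:, -1] = 1.0
    pi = np.linalg.solve(a, b[..., None])[..., 0]
    pi = np.clip(pi, 1e-300, None)
    return pi / pi.sum(axis=1, keepdims=True)


def _ffbs_batch(log_b, gamma, pi, rng):
    """Joint state-path draw for all subjects; returns (N, T) 0-based."""
    n, t_len, m = log_b.shape
    shift = log_b.max(axis=2)
    b = np.exp(log_b - shift[:, :, None])
    alpha = np.empty((n, t_len, m))
    a = pi * b[:, 0]
    alpha[:, 0] = a / a.sum(axis=1, keepdims=True)
    for t in range(1, t_len):
        a = np.einsum("ni,nij->nj", alpha[:, t - 1], gamma) * b[:, t]
        alpha[:, t] = a / a.sum(axis=1, keepdims=True)
    states = np.empty((n, t_len), dtype=np.int64)
    u = rng.random((n, t_len))
    cum = np.cumsum(alpha[:, -1], axis=1)
    states[:, -1] = (u[:, -1, None] > cum).sum(axis=1)
    rows = np.arange(n)
    for t in range(t_len - 2, -1, -1):
        w = alpha[:, t] * gamma[rows, :, states[:, t + 1]]
        cum = np.cumsum(w, axis=1)
        states[:, t] = (u[:, t, None] * cum[:, -1:] > cum).sum(axis=1)
    return states


def _transition_counts(states: np.ndarray, m: int) -> np.ndarray:
    n, t_len = states.shape
    flat = states[:, :-1] * m + states[:, 1:]
    counts = np.zeros((n, m * m))
    np.add.at(counts, (np.repeat(np.arange(n), t_len - 1), flat.ravel()), 1.0)
    return counts.reshape(n, m, m)


def _row_loglik(logits, counts):
    """Multinomial-logit row log-likelihoods: (N, m) given counts (N, m, m)."""
    full = _offdiag_to_full(logits)
    mx = full.max(axis=-1, keepdims=True)
    log_p = full - mx - np.log(np.exp(full - mx).sum(axis=-1, keepdims=True))
    return (counts * log_p).sum(axis=-1)


# ---------------------------------------------------------------------------
# one chain

def _run_chain(y, cov_x, m, priors: PriorConfig, iterations, burn_in,
               init, rng, path_thin, adapt_target=0.35, fix_emissions=False):
    n, t_len, q = y.shape
    c = 0 if cov_x is None else cov_x.shape[1]
    seen = ~np.isnan(y)
    n_kept = iterations - burn_in
    pr = priors

    mu_bar = init["mu_bar"].copy()
    tau2 = init["tau2"].copy()
    sigma2 = init["sigma2"].copy()
    gamma_bar = init["gamma_bar"].copy()
    psi2 = init["psi2"].copy()
    beta = init["beta"].copy()
    subject_mu = init["subject_mu"].copy()
    subject_logits = init["subject_logits"].copy()

    log_step = np.full((n, m), np.log(0.4))
    acc_count = np.zeros((n, m))

    keep = {k: np.empty((n_kept,) + v.shape) for k, v in
            (("mu_bar", mu_bar), ("tau2", tau2), ("sigma2", sigma2),
             ("gamma_bar", gamma_bar), ("psi2", psi2), ("beta", beta))}
    keep_subject_mu = np.empty((n_kept, n, m, q))
    keep_subject_logits = np.empty((n_kept, n, m, m - 1))
    n_paths = max(1, int(np.ceil(n_kept / path_thin)))
    keep_paths = np.zeros((n_paths, n, t_len), dtype=np.int16)
    empty_events = 0

    x1 = np.column_stack([np.ones(n)] + ([cov_x] if c else []))
    prior_prec_coef = np.diag([1.0 / pr.logit_mean_var] + [1.0 / pr.coef_var] * c)

    rows = np.arange(n)
    for it in range(iterations):
        # (1) latent state paths
        gamma = logits_to_probs(subject_logits)
        pi = _stationary_batch(gamma)
        log_b = _log_emissions_batch(y, seen, subject_mu, np.sqrt(sigma2))
        states = _ffbs_batch(log_b, gamma, pi, rng)

        # (2) per-iteration imputation of missing items
        mu_sel = subject_mu[rows[:, None], states]            # (N, T, q)
        sd_sel = np.sqrt(sigma2)[states]
        ycomp = np.where(seen, y,
                         mu_sel + sd_sel * rng.standard_normal((n, t_len, q)))

        one_hot = states[:, :, None] == np.arange(m)          # (N, T, m)
        n_cnt = one_hot.sum(axis=1).astype(float)             # (N, m)
        if np.any(n_cnt.sum(axis=0) == 0):
            empty_events += 1

        if not fix_emissions:
            # (3) conjugate emission updates
            sum_y = np.einsum("ntm,ntq->nmq", one_hot, ycomp)
            mean, var = normal_posterior(mu_bar, tau2, sum_y,
                                         n_cnt[:, :, None], sigma2)
            subject_mu = mean + np.sqrt(var) * rng.standard_normal((n, m, q))

            mean, var = normal_posterior(pr.emission_mean_loc,
                                         pr.emission_mean_scale ** 2,
                                         subject_mu.sum(axis=0), float(n), tau2)
            mu_bar = mean + np.sqrt(var) * rng.standard_normal((m, q))

            sse = ((subject_mu - mu_bar) ** 2).sum(axis=0)
            df, scale = scaled_invchi2_posterior(pr.between_var_df,
                                                 pr.between_var_scale2, sse, n)
            tau2 = sample_scaled_invchi2(rng, df, scale)

            mu_sel = subject_mu[rows[:, None], states]
            resid2 = (ycomp - mu_sel) ** 2
            sse = np.einsum("ntm,ntq->mq", one_hot, resid2)
            n_tot = n_cnt.sum(axis=0)
            df, scale = scaled_invchi2_posterior(pr.resid_var_df,
                                                 pr.resid_var_scale2,
                                                 sse, n_tot[:, None])
            sigma2 = sample_scaled_invchi2(rng, df, scale)

        # (4) Metropolis on subject transition logits, row by row.  The
        # state-path likelihood factorises over rows through the transition
        # counts, but the initial-state term (stationary distribution of the
        # full matrix) couples rows, so rows are updated sequentially with
        # the stationary factor recomputed for each proposal.
        counts = _transition_counts(states, m)
        prior_mean = gamma_bar[None]
        if c:
            prior_mean = prior_mean + np.einsum("nc,cml->nml", cov_x, beta)
        s0 = states[:, 0]
        accept_all = np.empty((n, m), dtype=bool)
        for i in range(m):
            step = np.exp(log_step[:, i])[:, None]
            prop_row = (subject_logits[:, i, :]
                        + step * rng.standard_normal((n, m - 1)))
            prop = subject_logits.copy()
            prop[:, i, :] = prop_row
            gamma_cur = logits_to_probs(subject_logits)
            gamma_prop = logits_to_probs(prop)
            pi_cur = _stationary_batch(gamma_cur)
            pi_prop = _stationary_batch(gamma_prop)
            ll_cur = (_row_loglik(subject_logits, counts)[:, i]
                      + np.log(pi_cur[rows, s0]))
            ll_prop = (_row_loglik(prop, counts)[:, i]
                       + np.log(pi_prop[rows, s0]))
            lp_cur = -0.5 * ((subject_logits[:, i, :] - prior_mean[:, i, :]) ** 2
                             / psi2[i]).sum(axis=1)
            lp_prop = -0.5 * ((prop_row - prior_mean[:, i, :]) ** 2
                              / psi2[i]).sum(axis=1)
            accept = np.log(rng.random(n)) < (ll_prop + lp_prop
                                              - ll_cur - lp_cur)
            subject_logits[accept, i, :] = prop_row[accept]
            accept_all[:, i] = accept
        if it < burn_in:
            gain = 2.0 / (it + 10.0) ** 0.6
            log_step += gain * (accept_all.astype(float) - adapt_target)
            log_step = np.clip(log_step, np.log(1e-3), np.log(20.0))
        else:
            acc_count += accept_all

        # (5) logit-level regression: gamma_bar, beta, psi2
        for i in range(m):
            for l in range(m - 1):
                resp = subject_logits[:, i, l]
                mean, cov = regression_coef_posterior(
                    x1, resp, float(psi2[i, l]), prior_prec_coef)
                z = rng.standard_normal(1 + c)
                coef = mean + np.linalg.cholesky(cov) @ z
                gamma_bar[i, l] = coef[0]
                if c:
                    beta[:, i, l] = coef[1:]
                rss = float(((resp - x1 @ coef) ** 2).sum())
                df, scale = scaled_invchi2_posterior(pr.logit_var_df,
                                                     pr.logit_var_scale2, rss, n)
                psi2[i, l] = sample_scaled_invchi2(rng, df, scale, size=())

        if it >= burn_in:
            k = it - burn_in
            for key, val in (("mu_bar", mu_bar), ("tau2", tau2),
                             ("sigma2", sigma2), ("gamma_bar", gamma_bar),
                             ("psi2", psi2), ("beta", beta)):
                keep[key][k] = val
            keep_subject_mu[k] = subject_mu
            keep_subject_logits[k] = subject_logits
            if k % path_thin == 0:
                keep_paths[k // path_thin] = states + 1

    accept_rate = acc_count / max(1, iterations - burn_in)
    return keep, keep_subject_mu, keep_subject_logits, keep_paths, accept_rate, empty_events


# ---------------------------------------------------------------------------
# label handling

def _full_logit_permute(arr: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Permute state labels of (..., m, m-1) logit arrays (self logit = 0)."""
    full = _offdiag_to_full(arr)
    full = full[..., perm, :][..., :, perm]
    m = full.shape[-1]
    out = np.empty(arr.shape)
    for i in range(m):
        cols = [j for j in range(m) if j != i]
        out[..., i, :] = full[..., i, cols]
    return out


def _relabel_chain(keep, subject_mu, subject_logits, paths, perm):
    for key in ("mu_bar", "tau2", "sigma2"):
        keep[key] = keep[key][:, perm, :]
    for key in ("gamma_bar", "psi2"):
        keep[key] = _full_logit_permute(keep[key], perm)
    if keep["beta"].shape[0] and keep["beta"].shape[1]:
        keep["beta"] = _full_logit_permute(keep["beta"], perm)
    subject_mu = subject_mu[:, :, perm, :]
    subject_logits = _full_logit_permute(subject_logits, perm)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    paths = inv[paths - 1] + 1
    return keep, subject_mu, subject_logits, paths


# ---------------------------------------------------------------------------
# public entry points

def fit_mhmm(panel: DiaryPanel, m: int, *, priors: PriorConfig | None = None,
             iterations: int = 4000, burn_in: int = 1000,
             n_extra_chains: int = 2, covariates: np.ndarray | None = None,
             seed: int | None = None, path_thin: int = 10,
             em_restarts: int = 10, fix_emissions_to: GroupParams | None = None,
             ) -> PosteriorDraws:
    """Fit the multilevel Bayesian HMM by Metropolis-within-Gibbs MCMC.

    Parameters
    ----------
    panel : DiaryPanel
    m : number of latent substates (>= 2).
    covariates : optional (N, C) 0/1 dummy matrix (reference category
        omitted) entering the transition logits.
    n_extra_chains : extra chains with randomised starting values, used for
        convergence assessment (total chains = 1 + n_extra_chains).
    fix_emissions_to : condition on fixed group emission parameters (e.g.
        posterior means of a no-covariate fit) instead of re-estimating.

    Returns
    -------
    PosteriorDraws with ``iterations - burn_in`` kept draws per chain.
    """
    if m < 2:
        raise ValueError("need m >= 2 substates")
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    priors = priors or PriorConfig()
    priors.validate()
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != panel.n_subjects:
            raise ValueError("covariates must have one row per subject")
        if not np.isin(covariates, (0.0, 1.0)).all():
            raise ValueError("covariates must be 0/1 dummies")

    master = np.random.SeedSequence(seed)
    chain_seeds = master.spawn(1 + n_extra_chains)
    em_params, _, _ = em_fit_single_level(
        panel, m, n_restarts=em_restarts,
        seed=int(master.generate_state(1)[0] % (2 ** 31)))

    fix = fix_emissions_to is not None
    all_keep, all_mu, all_logit, all_paths, all_acc = [], [], [], [], []
    empty_total = 0
    for ci, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        init = _initial_values(panel, m, covariates, rng,
                               perturb=(ci > 0), em_params=em_params)
        if fix:
            init["mu_bar"] = np.asarray(fix_emissions_to.mu_bar, float).copy()
            init["tau2"] = np.asarray(fix_emissions_to.tau2, float).copy()
            init["sigma2"] = np.asarray(fix_emissions_to.sigma2, float).copy()
            init["subject_mu"] = np.tile(init["mu_bar"], (panel.n_subjects, 1, 1))
        keep, smu, slog, paths, acc, n_empty = _run_chain(
            panel.y, covariates, m, priors, iterations, burn_in, init, rng,
            path_thin, fix_emissions=fix)
        order = _severity_order(keep["mu_bar"].mean(axis=0))
        if not np.array_equal(order, np.arange(m)):
            keep, smu, slog, paths = _relabel_chain(keep, smu, slog, paths, order)
        all_keep.append(keep)
        all_mu.append(smu)
        all_logit.append(slog)
        all_paths.append(paths)
        all_acc.append(acc)
        empty_total += n_empty

    group = {k: np.stack([kp[k] for kp in all_keep]) for k in all_keep[0]}
    if covariates is None:
        del group["beta"]
    return PosteriorDraws(
        m=m, q=panel.n_items, group=group,
        subject_mu=np.stack(all_mu), subject_logits=np.stack(all_logit),
        paths=np.stack(all_paths), path_thin=path_thin,
        accept_rate=np.stack(all_acc), covariates=covariates,
        subject_ids=list(panel.subject_ids), item_names=list(panel.item_names),
        iterations=iterations, burn_in=burn_in, seed=seed,
        n_empty_state_events=empty_total)


def impute_missing(panel: DiaryPanel, paths: np.ndarray,
                   params: Sequence[SubjectParams],
                   rng: np.random.Generator) -> np.ndarray:
    """One multiple-imputation pass: fill missing items from the emission
    distribution of the sampled state.

    ``paths`` is (N, T) 1-based.  Returns a completed copy of ``panel.y``;
    the panel itself is never modified.
    """
    y = panel.y.copy()
    miss = np.isnan(y)
    if not miss.any():
        return y
    paths = np.asarray(paths, dtype=int) - 1
    for j, p in enumerate(params):
        mu = p.emission_mean[paths[j]]
        sd = p.emission_sd[paths[j]]
        draw = rng.normal(mu, sd)
        y[j] = np.where(miss[j], draw, y[j])
    return y


def subject_posterior_means(draws: PosteriorDraws) -> list[SubjectParams]:
    """Posterior-mean subject-level parameters.

    Emission means are averaged over kept draws; transition matrices are
    averaged in probability space (per-draw logit -> probability transform)
    and renormalised.
    """
    mu = draws.subject_mu.mean(axis=(0, 1))                    # (N, m, q)
    sd = np.sqrt(draws.group["sigma2"].mean(axis=(0, 1)))      # (m, q)
    probs = logits_to_probs(draws.subject_logits)              # (Ch, K, N, m, m)
    trans = probs.mean(axis=(0, 1))
    trans = trans / trans.sum(axis=2, keepdims=True)
    out = []
    for j in range(draws.n_subjects):
        out.append(SubjectParams(mu[j], np.maximum(sd, 1e-8), trans[j]))
    return out


def multilevel_aic(panel: DiaryPanel, draws: PosteriorDraws) -> float:
    """AIC of the multilevel fit.

    Marginal (forward-algorithm) log-likelihood evaluated at posterior
    medians of the group-level parameters with subject parameters set to
    the group means, counting only group-level free parameters:
    3mq (means + both variances) + 2m(m-1) (logit means + variances)
    + covariate coefficients when present.
    """
    gp = draws.posterior_group_params(point="median")
    params = SubjectParams(gp.mu_bar, np.sqrt(gp.sigma2),
                           logits_to_probs(gp.gamma_bar))
    loglik = 0.0
    for j in range(panel.n_subjects):
        ll, _ = forward_loglik(params, panel.y[j])
        loglik += ll
    m, q = draws.m, draws.q
    p = 3 * m * q + 2 * m * (m - 1) + draws.n_covariates * m * (m - 1)
    return aic(loglik, p)
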