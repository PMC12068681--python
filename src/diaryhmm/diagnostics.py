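"""Convergence assessment, posterior-predictive checks, residual checks.

Convergence uses the Brooks-Gelman (multivariate) potential scale
reduction factor over all group-level parameters, computed from the main
chain plus the extra randomised-start chains, with the conventional
threshold of 1.05.  Posterior-predictive checks regenerate full diary
panels from posterior draws through the same simulator used for synthetic
data, at the group level (new hypothetical subjects) and the individual
level (each real subject from their own fitted parameters).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import SubjectParams, logits_to_probs
from .panel import DiaryPanel
from .sampler import PosteriorDraws
from .simulate import simulate_observations

__all__ = [
    "ConvergenceReport",
    "PpcReport",
    "ResidualReport",
    "psrf",
    "mpsrf",
    "ppc_group",
    "ppc_individual",
    "residuals",
]


# ---------------------------------------------------------------------------
# potential scale reduction

@dataclasses.dataclass
class ConvergenceReport:
    psrf: pd.Series               # univariate PSRF per parameter
    mpsrf: float
    threshold: float
    passed: bool
    n_chains: int
    n_iterations: int
    zero_variance_params: list

    def to_dict(self) -> dict:
        return {
            "mpsrf": self.mpsrf,
            "threshold": self.threshold,
            "passed": bool(self.passed),
            "n_chains": self.n_chains,
            "n_iterations": self.n_iterations,
            "max_psrf": float(self.psrf.max()),
            "zero_variance_params": list(self.zero_variance_params),
        }


def psrf(chains: np.ndarray) -> np.ndarray:
    """Univariate potential scale reduction factor per parameter.

    ``chains`` has shape (M, n, P).  Zero-variance parameters get 1.0.
    """
    chains = np.asarray(chains, dtype=float)
    m, n, _ = chains.shape
    w = chains.var(axis=1, ddof=1).mean(axis=0)
    b_over_n = chains.mean(axis=1).var(axis=0, ddof=1)
    out = np.ones(chains.shape[2])
    ok = w > 0
    r2 = (n - 1) / n + ((m + 1) / m) * b_over_n[ok] / w[ok]
    out[ok] = np.sqrt(np.maximum(r2, 1.0))
    return out


def mpsrf(draws: PosteriorDraws | np.ndarray, names=None,
          threshold: float = 1.05) -> ConvergenceReport:
    """Brooks-Gelman univariate and multivariate PSRF.

    Accepts a :class:`PosteriorDraws` (group-level parameters are used) or
    a raw (n_chains, n_iter, P) array.  Requires >= 2 chains and >= 50 kept
    iterations.  The multivariate factor is
    (n-1)/n + ((M+1)/M) * lambda_max(W^{-1} B/n).
    """
    if isinstance(draws, PosteriorDraws):
        names, chains = draws.group_names_and_matrix()
    else:
        chains = np.asarray(draws, dtype=float)
        if names is None:
            names = [f"p{i}" for i in range(chains.shape[2])]
    m, n, p = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 50:
        raise ValueError("need at least 50 kept iterations per chain")

    uni = psrf(chains)
    flat_var = chains.reshape(-1, p).var(axis=0)
    keep = flat_var > 1e-300
    zero_names = [names[i] for i in range(p) if not keep[i]]
    sub = chains[:, :, keep]

    centered = sub - sub.mean(axis=1, keepdims=True)
    w = np.einsum("mni,mnj->ij", centered, centered) / (m * (n - 1))
    means = sub.mean(axis=1)
    md = means - means.mean(axis=0)
    b_over_n = np.einsum("mi,mj->ij", md, md) / (m - 1)
    # rescale by within-chain SDs so the computation (and any ridging) is
    # exactly invariant under affine reparameterisation of coordinates
    d = np.sqrt(np.diag(w))
    inv_d = 1.0 / d
    w = w * np.outer(inv_d, inv_d)
    b_over_n = b_over_n * np.outer(inv_d, inv_d)
    w = w + 1e-10 * np.eye(w.shape[0])
    try:
        lam = np.linalg.eigvals(np.linalg.solve(w, b_over_n))
        lam_max = float(np.max(lam.real))
    except np.linalg.LinAlgError:
        lam_max = float(np.trace(np.linalg.pinv(w) @ b_over_n))
    val = max(1.0, (n - 1) / n + ((m + 1) / m) * lam_max)

    series = pd.Series(uni, index=names)
    return ConvergenceReport(psrf=series, mpsrf=val, threshold=threshold,
                             passed=val <= threshold, n_chains=m,
                             n_iterations=n, zero_variance_params=zero_names)


# ---------------------------------------------------------------------------
# posterior predictive checks

@dataclasses.dataclass
class PpcReport:
    level: str                     # "group" or "individual"
    reps: int
    summary_names: list
    observed: np.ndarray           # (units, S) observed summaries
    replicates: np.ndarray         # (reps, units, S)
    p_values: np.ndarray           # (units, S) lower tail areas
    unit_names: list
    excluded_units: list

    def frame(self) -> pd.DataFrame:
        recs = []
        for u, name in enumerate(self.unit_names):
            for s, sname in enumerate(self.summary_names):
                recs.append((name, sname, self.observed[u, s],
                             self.replicates[:, u, s].mean(),
                             self.p_values[u, s]))
        return pd.DataFrame(recs, columns=["unit", "summary", "observed",
                                           "replicate_mean", "p_value"])


_DECILES = np.arange(0.1, 1.0, 0.1)
_SUMMARY_NAMES = ["mean", "sd"] + [f"q{int(round(d * 100))}" for d in _DECILES]


def _item_summaries(y: np.ndarray) -> np.ndarray:
    """Per-item summaries over all observed subject-days: (q, S)."""
    q = y.shape[-1]
    flat = y.reshape(-1, q)
    out = np.full((q, 2 + len(_DECILES)), np.nan)
    for k in range(q):
        col = flat[:, k]
        col = col[~np.isnan(col)]
        if col.size < 2:
            continue
        out[k, 0] = col.mean()
        out[k, 1] = col.std(ddof=1)
        out[k, 2:] = np.quantile(col, _DECILES)
    return out


def _tail_areas(observed: np.ndarray, replicates: np.ndarray) -> np.ndarray:
    """Lower tail area of the observed summary in the replicate distribution."""
    reps = replicates.shape[0]
    return ((replicates < observed[None]).sum(axis=0)
            + 0.5 * (replicates == observed[None]).sum(axis=0)) / reps


def _draw_indices(draws: PosteriorDraws, reps: int, rng: np.random.Generator):
    ch = rng.integers(0, draws.n_chains, size=reps)
    it = rng.integers(0, draws.n_kept, size=reps)
    return ch, it


def ppc_group(draws: PosteriorDraws, panel: DiaryPanel, reps: int = 500,
              rng: np.random.Generator | None = None) -> PpcReport:
    """Group-level posterior-predictive check.

    For each replicate a posterior draw of the group-level parameters is
    taken, a full cohort of hypothetical subjects is generated (subject
    parameters from the group distributions, then paths and observations
    through the shared simulator), the panel's missingness pattern is
    applied, and per-item summary statistics are compared with the
    observed ones via tail areas.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    rng = rng or np.random.default_rng()
    n, t_len, q = panel.y.shape
    miss = panel.missing_mask
    observed = _item_summaries(panel.y)
    ch, it = _draw_indices(draws, reps, rng)
    g = draws.group
    rep_stats = np.empty((reps, q, observed.shape[1]))
    cov = draws.covariates
    for r in range(reps):
        c, k = ch[r], it[r]
        mu_bar = g["mu_bar"][c, k]
        tau = np.sqrt(g["tau2"][c, k])
        sd = np.sqrt(g["sigma2"][c, k])
        gamma_bar = g["gamma_bar"][c, k]
        psi = np.sqrt(g["psi2"][c, k])
        beta = g.get("beta")
        params = []
        for j in range(n):
            mu_j = rng.normal(mu_bar, tau)
            loc = gamma_bar if beta is None else gamma_bar + np.einsum(
                "c,cml->ml", cov[j], beta[c, k])
            logits = rng.normal(loc, psi)
            params.append(SubjectParams(mu_j, np.maximum(sd, 1e-8),
                                        logits_to_probs(logits)))
        _, y_rep = simulate_observations(params, t_len, rng)
        y_rep = np.where(miss, np.nan, y_rep)
        rep_stats[r] = _item_summaries(y_rep)
    return PpcReport(level="group", reps=reps, summary_names=list(_SUMMARY_NAMES),
                     observed=observed, replicates=rep_stats,
                     p_values=_tail_areas(observed, rep_stats),
                     unit_names=list(panel.item_names), excluded_units=[])


def ppc_individual(draws: PosteriorDraws, panel: DiaryPanel, reps: int = 500,
                   rng: np.random.Generator | None = None) -> PpcReport:
    """Individual-level posterior-predictive check.

    Replicates are generated per real subject from posterior draws of that
    subject's own emission means and transition logits; per subject-item
    means and SDs are compared with the observed data.  Subjects with no
    observed data are excluded and flagged.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    rng = rng or np.random.default_rng()
    n, t_len, q = panel.y.shape
    miss = panel.missing_mask
    ch, it = _draw_indices(draws, reps, rng)

    keep_subj = [j for j in range(n) if not np.isnan(panel.y[j]).all()]
    excluded = [panel.subject_ids[j] for j in range(n) if j not in keep_subj]

    def subj_item_stats(y):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(y, axis=1)                # (N, q)
            sds = np.nanstd(y, axis=1, ddof=1)
        return np.stack([means, sds], axis=-1)           # (N, q, 2)

    with np.errstate(invalid="ignore"):
        obs = subj_item_stats(panel.y)[keep_subj]
    rep_stats = np.empty((reps, len(keep_subj), q, 2))
    for r in range(reps):
        c, k = ch[r], it[r]
        sd = np.sqrt(draws.group["sigma2"][c, k])
        params = []
        for j in keep_subj:
            mu_j = draws.subject_mu[c, k, j]
            trans = logits_to_probs(draws.subject_logits[c, k, j])
            params.append(SubjectParams(mu_j, np.maximum(sd, 1e-8), trans))
        _, y_rep = simulate_observations(params, t_len, rng)
        y_rep = np.where(miss[keep_subj], np.nan, y_rep)
        with np.errstate(invalid="ignore"):
            rep_stats[r] = subj_item_stats(y_rep)

    obs_flat = obs.reshape(len(keep_subj), -1)
    rep_flat = rep_stats.reshape(reps, len(keep_subj), -1)
    names = []
    for k in range(q):
        names += [f"{panel.item_names[k]}:mean", f"{panel.item_names[k]}:sd"]
    # reorder from (q, 2) to interleaved item stat pairs
    obs_flat = obs.transpose(0, 1, 2).reshape(len(keep_subj), q * 2)
    rep_flat = rep_stats.transpose(0, 1, 2, 3).reshape(reps, len(keep_subj), q * 2)
    return PpcReport(level="individual", reps=reps, summary_names=names,
                     observed=obs_flat, replicates=rep_flat,
                     p_values=_tail_areas(obs_flat, rep_flat),
                     unit_names=[panel.subject_ids[j] for j in keep_subj],
                     excluded_units=excluded)


# ---------------------------------------------------------------------------
# residual checks

@dataclasses.dataclass
class ResidualReport:
    table: pd.DataFrame            # subject, day, item, state, residual
    subject_item_tests: pd.DataFrame
    subject_tests: pd.DataFrame


def _safe_ttest(x: np.ndarray) -> float:
    if len(x) < 2:
        return np.nan
    if np.allclose(x, x[0]):
        return 1.0 if abs(x[0]) < 1e-12 else 0.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def _slope_test(day: np.ndarray, absres: np.ndarray) -> float:
    if len(day) < 3 or np.allclose(absres, absres[0]) or len(set(day)) < 2:
        return np.nan
    res = stats.linregress(day, absres)
    return float(res.pvalue)


def residuals(panel: DiaryPanel, sequences, subject_params,
              state_specific: bool = True) -> ResidualReport:
    """Per subject-item-day residuals from the decoded state sequence.

    The residual on day t for item k is the observed score minus the
    subject's fitted emission mean for item k — by default the mean of the
    Viterbi-decoded state on that day (``state_specific=True``); the
    state-blind variant subtracts the subject's grand fitted item mean.
    Missing days are excluded.  Tests: per subject-item zero-mean t-test,
    per subject-item homoscedasticity (slope of |residual| on day index),
    and per-subject aggregated zero-mean t-test.
    """
    recs = []
    for j, (seq, params) in enumerate(zip(sequences, subject_params)):
        states = np.asarray(seq.states, dtype=int)
        y = panel.y[j]
        occ, _ = _occupancy_weights(states, params.m)
        grand = occ @ params.emission_mean
        for t in range(panel.n_days):
            if states[t] < 1:
                continue
            mu = (params.emission_mean[states[t] - 1]
                  if state_specific else grand)
            for k in range(panel.n_items):
                if np.isnan(y[t, k]):
                    continue
                recs.append((panel.subject_ids[j], t + 1,
                             panel.item_names[k], states[t],
                             y[t, k] - mu[k]))
    table = pd.DataFrame(recs, columns=["subject", "day", "item", "state",
                                        "residual"])

    si_recs, s_recs = [], []
    for (subj, item), grp in table.groupby(["subject", "item"], sort=False):
        r = grp["residual"].to_numpy()
        si_recs.append((subj, item, r.mean(),
                        _safe_ttest(r),
                        _slope_test(grp["day"].to_numpy(), np.abs(r))))
    for subj, grp in table.groupby("subject", sort=False):
        r = grp["residual"].to_numpy()
        s_recs.append((subj, r.mean(), _safe_ttest(r)))
    return ResidualReport(
        table=table,
        subject_item_tests=pd.DataFrame(
            si_recs, columns=["subject", "item", "mean_residual",
                              "zero_mean_p", "homoscedasticity_p"]),
        subject_tests=pd.DataFrame(
            s_recs, columns=["subject", "mean_residual", "zero_mean_p"]))


def _occupancy_weights(states: np.ndarray, m: int):
    defined = states > 0
    if not defined.any():
        return np.full(m, 1.0 / m), 0
    cnt = np.bincount(states[defined] - 1, minlength=m).astype(float)
    return cnt / cnt.sum(), int(defined.sum())
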