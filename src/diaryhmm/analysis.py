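"""Downstream substate analyses.

Decoding per-subject substate trajectories from a fitted multilevel HMM,
characterising substates by severity bands, summarising trajectories
(switch counts, occupancy), cross-tabulating rarely endorsed auxiliary
items (perceptual disturbances) against decoded states, and comparing
subgroup transition probabilities from a covariate fit.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .diagnostics import mpsrf
from .hmm import StateSequence, SubjectParams, logits_to_probs, viterbi
from .panel import DiaryPanel
from .sampler import PosteriorDraws, subject_posterior_means

__all__ = [
    "SeverityBands",
    "SubgroupTransitionSummary",
    "decode_all",
    "switch_count",
    "occupancy",
    "severity_band",
    "ordinal_consistency",
    "binarize_aux",
    "crosstab_aux_by_state",
    "subgroup_transition_summary",
]

UNDEFINED = 0


@dataclasses.dataclass
class SeverityBands:
    """Score bands used to label substate emission means on the 0-100 scale."""

    negligible_upper: float = 10.0
    low_upper: float = 25.0
    moderate_upper: float = 75.0
    labels: Sequence[str] = ("negligible", "low", "moderate", "high")

    def __post_init__(self) -> None:
        if not (self.negligible_upper < self.low_upper < self.moderate_upper):
            raise ValueError("band thresholds must be strictly increasing")


def severity_band(value: float, bands: SeverityBands | None = None) -> str:
    """Label a mean score: <10 negligible, [10, 25) low, [25, 75] moderate,
    above that high."""
    bands = bands or SeverityBands()
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    if value < bands.negligible_upper:
        return bands.labels[0]
    if value < bands.low_upper:
        return bands.labels[1]
    if value <= bands.moderate_upper:
        return bands.labels[2]
    return bands.labels[3]


# ---------------------------------------------------------------------------
# decoding

def decode_all(panel: DiaryPanel, draws: PosteriorDraws, *,
               force: bool = False, mask_missing: bool = False,
               mpsrf_threshold: float = 1.05) -> list[StateSequence]:
    """Viterbi-decode every subject from subject-level posterior means.

    The recursion carries through all-missing days (their emission term is
    1), so decoding-through is the default for statistics;
    ``mask_missing=True`` marks those days undefined (0) for display.
    With >= 2 chains the fit must pass the MPSRF gate unless ``force``.
    """
    if draws.n_chains >= 2 and not force:
        report = mpsrf(draws, threshold=mpsrf_threshold)
        if not report.passed:
            raise RuntimeError(
                f"fit has not converged (MPSRF {report.mpsrf:.3f} > "
                f"{mpsrf_threshold}); pass force=True to decode anyway")
    params = subject_posterior_means(draws)
    out = []
    for j, p in enumerate(params):
        seq = viterbi(p, panel.y[j], subject_id=panel.subject_ids[j])
        if mask_missing:
            seq.states[panel.day_missing[j]] = UNDEFINED
        out.append(seq)
    return out


def switch_count(seq: StateSequence, bridge: bool = True) -> int:
    """Number of day-to-day substate changes.

    With ``bridge=True`` (default) undefined days are skipped and the
    nearest defined neighbours are compared, keeping counts comparable
    across subjects with different missingness; ``bridge=False`` counts
    only adjacent-day defined pairs.
    """
    s = np.asarray(seq.states, dtype=int)
    if bridge:
        s = s[s > UNDEFINED]
        return int(np.sum(s[1:] != s[:-1])) if s.size else 0
    ok = (s[1:] > UNDEFINED) & (s[:-1] > UNDEFINED)
    return int(np.sum((s[1:] != s[:-1]) & ok))


def occupancy(seq: StateSequence, m: int) -> np.ndarray:
    """Fraction of defined days spent in each of the m substates."""
    s = np.asarray(seq.states, dtype=int)
    s = s[s > UNDEFINED]
    if s.size == 0:
        raise ValueError("sequence has no defined days")
    cnt = np.bincount(s - 1, minlength=m).astype(float)
    return cnt / cnt.sum()


def ordinal_consistency(subject_means: np.ndarray, group_means: np.ndarray):
    """Check that each item's across-state ordering is shared by all subjects.

    ``subject_means`` is (N, m, q), ``group_means`` (m, q).  Returns
    ``(per_item_ok (q,), violations)`` where violations is a list of
    (item_index, subject_index) pairs.
    """
    subject_means = np.asarray(subject_means, float)
    group_means = np.asarray(group_means, float)
    n, m, q = subject_means.shape
    ok = np.ones(q, dtype=bool)
    violations = []
    for k in range(q):
        ref = np.argsort(group_means[:, k], kind="stable")
        for j in range(n):
            if not np.array_equal(np.argsort(subject_means[j, :, k],
                                             kind="stable"), ref):
                ok[k] = False
                violations.append((k, j))
    return ok, violations


# ---------------------------------------------------------------------------
# auxiliary (perceptual disturbance) items

def binarize_aux(score: float, threshold: float = 4.0) -> int:
    """Indicator for a 0-7 auxiliary item: 1 iff score >= threshold."""
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 7)):
        raise ValueError("auxiliary scores must lie in [0, 7]")
    return (arr >= threshold).astype(int) if arr.ndim else int(arr >= threshold)


def crosstab_aux_by_state(aux_events: np.ndarray,
                          sequences: Sequence[StateSequence], m: int):
    """Count auxiliary-item endorsement days per decoded substate.

    ``aux_events`` is (N, T) of 0/1 (NaN for missing days).  Returns a dict
    with per-state counts (1-based keys), days in an undefined state, and
    the total number of events.
    """
    events = np.asarray(aux_events, dtype=float)
    if events.shape[0] != len(sequences):
        raise ValueError("aux events and sequences are misaligned on subjects")
    counts = np.zeros(m, dtype=int)
    undefined = 0
    total = 0
    for j, seq in enumerate(sequences):
        s = np.asarray(seq.states, dtype=int)
        if events.shape[1] != s.size:
            raise ValueError("aux events and sequences are misaligned on days")
        ev = np.nan_to_num(events[j], nan=0.0) > 0
        total += int(ev.sum())
        undefined += int((ev & (s == UNDEFINED)).sum())
        for i in range(m):
            counts[i] += int((ev & (s == i + 1)).sum())
    return {"per_state": {i + 1: int(counts[i]) for i in range(m)},
            "undefined": undefined, "total": total}


# ---------------------------------------------------------------------------
# subgroup transition comparison

@dataclasses.dataclass
class SubgroupTransitionSummary:
    """Posterior summaries of subgroup-level transition matrices."""

    subgroups: list
    mean: np.ndarray               # (G, m, m) posterior-mean probabilities
    lower: np.ndarray              # (G, m, m) 2.5% quantile
    upper: np.ndarray              # (G, m, m) 97.5% quantile
    nonoverlap: dict               # (a, b) -> (m, m) bool: CrIs do not overlap

    def pairwise_nonoverlap(self, a, b) -> np.ndarray:
        key = (a, b) if (a, b) in self.nonoverlap else (b, a)
        return self.nonoverlap[key]


def subgroup_transition_summary(draws: PosteriorDraws,
                                subgroup_dummies_map: dict,
                                min_kept: int = 1) -> SubgroupTransitionSummary:
    """Posterior mean and 95% CrI of each subgroup's transition matrix.

    ``subgroup_dummies_map`` maps subgroup label -> length-C dummy vector
    (the reference subgroup maps to all zeros).  For every kept draw the
    subgroup logits gamma_bar + beta' x are transformed to probability
    space; summaries are taken over draws, and each pair of subgroups is
    flagged cell-wise where the 95% credible intervals do not overlap.
    """
    if draws.n_kept < min_kept:
        raise ValueError("not enough kept iterations")
    gamma = draws.group["gamma_bar"].reshape(-1, draws.m, draws.m - 1)
    beta = draws.group.get("beta")
    if beta is not None:
        beta = beta.reshape(-1, beta.shape[2], draws.m, draws.m - 1)
    labels = list(subgroup_dummies_map)
    g_count = len(labels)
    mean = np.empty((g_count, draws.m, draws.m))
    lower = np.empty_like(mean)
    upper = np.empty_like(mean)
    for gi, lab in enumerate(labels):
        x = np.asarray(subgroup_dummies_map[lab], dtype=float)
        logits = gamma
        if beta is not None and x.size:
            logits = gamma + np.einsum("c,dcml->dml", x, beta)
        probs = logits_to_probs(logits)                     # (draws, m, m)
        mean[gi] = probs.mean(axis=0)
        mean[gi] /= mean[gi].sum(axis=1, keepdims=True)
        lower[gi] = np.quantile(probs, 0.025, axis=0)
        upper[gi] = np.quantile(probs, 0.975, axis=0)
    nonoverlap = {}
    for a in range(g_count):
        for b in range(a + 1, g_count):
            nonoverlap[(labels[a], labels[b])] = (
                (upper[a] < lower[b]) | (upper[b] < lower[a]))
    return SubgroupTransitionSummary(subgroups=labels, mean=mean,
                                     lower=lower, upper=upper,
                                     nonoverlap=nonoverlap)
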