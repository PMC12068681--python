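"""Synthetic daily-diary panels from a known multilevel HMM.

The generator mirrors the structure of a 90-day diary study on the
psychosis continuum: 96 subjects in four severity subgroups (25/27/24/20),
six 0-100 items (four attenuated-psychotic, two affective), four latent
substates of increasing severity, subject-level random effects on emission
means and transition logits, subgroup shifts on the logits, ~6.9 missing
days per subject in runs of at most four, and two rarely endorsed 0-7
perceptual-disturbance items concentrated in the two most severe states.

The same low-level machinery (:func:`simulate_observations`) is reused by
the posterior-predictive checks so that model-based replicates and the
generator share a single code path.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .hmm import SubjectParams, logits_to_probs, stationary_dist
from .panel import DiaryPanel

__all__ = [
    "GenerativeConfig",
    "SimulatedTruth",
    "sample_subject_params",
    "simulate_panel",
    "simulate_observations",
    "apply_mar_missingness",
]

_DEFAULT_ITEMS = ("suspicious", "broadcasting", "disliked",
                  "external_control", "anxiety", "mood")
_DEFAULT_AUX = ("auditory_hallucinations", "visual_hallucinations")

# State-by-item group emission means on the 0-100 scale, placed inside the
# study's printed severity bands: state 1 negligible psychotic (<10) with
# low affect; state 2 low suspiciousness/disliked only, moderate affect;
# state 3 low levels of all psychotic items with broadcasting most
# prominent; state 4 moderate (25-75) on everything.
_DEFAULT_MEANS = np.array([
    # susp  broad  disl  ext   anx   mood
    [3.0,   2.0,   4.0,  2.0, 18.0, 15.0],   # minimal symptoms
    [18.0,  3.0,  20.0,  3.0, 35.0, 32.0],   # affective / low suspiciousness
    [15.0, 22.0,  18.0, 12.0, 40.0, 38.0],   # affective / low psychosis
    [45.0, 40.0,  48.0, 35.0, 55.0, 50.0],   # affective / moderate psychosis
])


def _default_logits(m: int) -> np.ndarray:
    """Off-diagonal transition logits decaying with state distance.

    Self logit is fixed at 0; adjacent states get -1.2, each extra step of
    distance another -0.6, giving daily self-transition probabilities around
    0.6-0.75 and a few dozen switches over 90 days.
    """
    out = np.empty((m, m - 1))
    for i in range(m):
        dests = [j for j in range(m) if j != i]
        for l, j in enumerate(dests):
            out[i, l] = -1.2 - 0.6 * (abs(i - j) - 1)
    return out


def _default_subgroup_effects(n_groups: int, m: int) -> np.ndarray:
    """Additive logit shifts per subgroup: severity raises flow into the two
    most severe states and dampens flow out of them; group 1 is the reference."""
    pattern = np.zeros((m, m - 1))
    severe = {m - 2, m - 1} if m >= 2 else set()
    for i in range(m):
        dests = [j for j in range(m) if j != i]
        for l, j in enumerate(dests):
            if j in severe and i not in severe:
                pattern[i, l] = 0.8
            elif i in severe and j not in severe:
                pattern[i, l] = -0.8
            elif i in severe and j in severe:
                pattern[i, l] = 0.4
    grades = np.linspace(0.0, 1.0, n_groups)
    return grades[:, None, None] * pattern[None]


@dataclasses.dataclass
class GenerativeConfig:
    """Ground-truth multilevel HMM used to simulate diary panels."""

    n_subjects: int = 96
    subgroup_sizes: Sequence[int] = (25, 27, 24, 20)
    n_days: int = 90
    m: int = 4
    q: int = 6
    item_names: Sequence[str] = _DEFAULT_ITEMS
    aux_names: Sequence[str] = _DEFAULT_AUX
    group_emission_means: np.ndarray | None = None       # (m, q)
    between_subject_sd: float | np.ndarray = 5.0         # (m, q) or scalar
    within_subject_sd: float | np.ndarray = 10.0
    group_transition_logits: np.ndarray | None = None    # (m, m-1)
    subgroup_logit_effects: np.ndarray | None = None     # (G, m, m-1)
    logit_re_sd: float = 0.5
    missing_rate: float = 6.9 / 90.0
    max_missing_run: int = 4
    aux_state_probs: Sequence[float] | None = None       # per-state P(score >= 4)
    aux_event_value: float = 5.0
    clip_to_scale: bool = False

    def __post_init__(self) -> None:
        if self.group_emission_means is None:
            if (self.m, self.q) == _DEFAULT_MEANS.shape:
                self.group_emission_means = _DEFAULT_MEANS.copy()
            else:
                # evenly spaced severity ladder as a generic fallback
                levels = np.linspace(5.0, 60.0, self.m)
                self.group_emission_means = np.tile(levels[:, None], (1, self.q))
        self.group_emission_means = np.asarray(self.group_emission_means, float)
        self.between_subject_sd = np.broadcast_to(
            np.asarray(self.between_subject_sd, float), (self.m, self.q)).copy()
        self.within_subject_sd = np.broadcast_to(
            np.asarray(self.within_subject_sd, float), (self.m, self.q)).copy()
        if self.group_transition_logits is None:
            self.group_transition_logits = _default_logits(self.m)
        self.group_transition_logits = np.asarray(self.group_transition_logits, float)
        n_groups = len(self.subgroup_sizes)
        if self.subgroup_logit_effects is None:
            self.subgroup_logit_effects = _default_subgroup_effects(n_groups, self.m)
        self.subgroup_logit_effects = np.asarray(self.subgroup_logit_effects, float)
        if self.aux_state_probs is None:
            p = np.zeros(self.m)
            if self.m >= 2:
                p[-1] = 0.10
                p[-2] = 0.04
            if self.m >= 4:
                p[0], p[1] = 0.001, 0.001
            self.aux_state_probs = p
        self.aux_state_probs = np.asarray(self.aux_state_probs, float)
        self.validate()

    def validate(self) -> None:
        if sum(self.subgroup_sizes) != self.n_subjects:
            raise ValueError("subgroup_sizes must sum to n_subjects")
        if self.group_emission_means.shape != (self.m, self.q):
            raise ValueError("group_emission_means must be (m, q)")
        if np.any(self.between_subject_sd < 0) or np.any(self.within_subject_sd < 0):
            raise ValueError("SDs must be non-negative")
        if np.any((self.aux_state_probs < 0) | (self.aux_state_probs > 1)):
            raise ValueError("aux_state_probs must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def subgroup_of_subject(self) -> np.ndarray:
        """1-based subgroup label per subject, in block order."""
        return np.repeat(np.arange(1, len(self.subgroup_sizes) + 1),
                         self.subgroup_sizes)


@dataclasses.dataclass
class SimulatedTruth:
    """Ground truth for a simulated panel: paths, realised subject params."""

    true_states: np.ndarray                  # (N, T), 1-based
    subject_params: list[SubjectParams]
    config: GenerativeConfig
    seed: int | None


def sample_subject_params(config: GenerativeConfig, subgroup: int,
                          rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's parameters from the group-level distributions.

    Emission means are Normal around the group means (between-subject SD);
    transition logits are group logits + the subgroup shift + Normal noise,
    mapped through the softmax transform.  ``subgroup`` is 1-based.
    """
    mu = rng.normal(config.group_emission_means, config.between_subject_sd)
    eff = config.subgroup_logit_effects[subgroup - 1]
    logits = rng.normal(config.group_transition_logits + eff, config.logit_re_sd)
    trans = logits_to_probs(logits)
    sd = np.maximum(config.within_subject_sd, 1e-8)
    return SubjectParams(mu, sd, trans)


def _stationary_or_uniform(trans: np.ndarray) -> np.ndarray:
    pi, unique = stationary_dist(trans)
    return pi if unique else np.full(trans.shape[0], 1.0 / trans.shape[0])


def simulate_observations(params_list: Sequence[SubjectParams], n_days: int,
                          rng: np.random.Generator,
                          clip_to_scale: bool = False):
    """Simulate state paths and observations for given subject parameters.

    This is the single code path shared by the panel generator and the
    posterior-predictive checks.  Returns ``(states (N, T) 1-based,
    y (N, T, q))``.
    """
    n = len(params_list)
    q = params_list[0].q
    states = np.empty((n, n_days), dtype=int)
    y = np.empty((n, n_days, q))
    for j, p in enumerate(params_list):
        init = p.initial_dist if p.initial_dist is not None else _stationary_or_uniform(p.transition)
        s = np.empty(n_days, dtype=int)
        s[0] = rng.choice(p.m, p=init)
        u = rng.random(n_days - 1)
        cum = np.cumsum(p.transition, axis=1)
        for t in range(1, n_days):
            s[t] = np.searchsorted(cum[s[t - 1]], u[t - 1], side="right")
        states[j] = s
        y[j] = rng.normal(p.emission_mean[s], p.emission_sd[s])
    if clip_to_scale:
        y = np.clip(y, 0.0, 100.0)
    return states + 1, y


def _missing_days_mask(n_days: int, rate: float, max_run: int,
                       rng: np.random.Generator) -> np.ndarray:
    """i.i.d. daily missingness, rejected until no run exceeds ``max_run``."""
    while True:
        mask = rng.random(n_days) < rate
        run, ok = 0, True
        for v in mask:
            run = run + 1 if v else 0
            if run > max_run:
                ok = False
                break
        if ok:
            return mask


def apply_mar_missingness(panel: DiaryPanel, missing_rate: float,
                          max_missing_run: int,
                          rng: np.random.Generator) -> DiaryPanel:
    """Blank whole days at random (MCAR), runs capped at ``max_missing_run``.

    Missingness is drawn independently of the item values and states, so
    the MAR assumption of the fitted model holds by construction.  Existing
    missing entries are preserved.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    y = panel.y.copy()
    aux = None if panel.aux is None else panel.aux.copy()
    for j in range(panel.n_subjects):
        if missing_rate > 0.0:
            mask = _missing_days_mask(panel.n_days, missing_rate,
                                      max_missing_run, rng)
            y[j, mask] = np.nan
            if aux is not None:
                aux[j, mask] = np.nan
    return DiaryPanel(y=y, subject_ids=panel.subject_ids,
                      item_names=panel.item_names, subgroup=panel.subgroup,
                      aux=aux, aux_names=panel.aux_names)


def simulate_panel(config: GenerativeConfig | None = None,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None):
    """Generate a full diary panel plus its ground truth.

    Returns ``(panel, truth)``.  Reproducible from ``(config, seed)``.
    """
    config = config or GenerativeConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    subgroups = config.subgroup_of_subject
    params = [sample_subject_params(config, g, rng) for g in subgroups]
    states, y = simulate_observations(params, config.n_days, rng,
                                      clip_to_scale=config.clip_to_scale)

    n_aux = len(config.aux_names)
    aux = None
    if n_aux:
        p_event = np.asarray(config.aux_state_probs)[states - 1]  # (N, T)
        events = rng.random((config.n_subjects, config.n_days, n_aux)) < p_event[..., None]
        aux = np.where(events, config.aux_event_value, 0.0)

    panel = DiaryPanel(
        y=y,
        subject_ids=[f"s{j + 1:03d}" for j in range(config.n_subjects)],
        item_names=list(config.item_names)[:config.q]
        if len(config.item_names) >= config.q
        else [f"item{k + 1}" for k in range(config.q)],
        subgroup=subgroups,
        aux=aux,
        aux_names=list(config.aux_names) if n_aux else None,
    )
    panel = apply_mar_missingness(panel, config.missing_rate,
                                  config.max_missing_run, rng)
    truth = SimulatedTruth(true_states=states, subject_params=params,
                           config=config, seed=seed)
    return panel, truth
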