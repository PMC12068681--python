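import numpy as np
import pytest

from diaryhmm import DiaryPanel, GenerativeConfig, SubjectParams, simulate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_subject_params(rng, m, q, mean_scale=50.0, sd_range=(1.0, 10.0)):
    """Random valid HMM parameters for oracle comparisons."""
    mu = rng.uniform(0.0, mean_scale, size=(m, q))
    sd = rng.uniform(*sd_range, size=(m, q))
    trans = rng.dirichlet(np.full(m, 1.0), size=m)
    trans = np.clip(trans, 1e-6, None)
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.dirichlet(np.full(m, 1.0))
    return SubjectParams(mu, sd, trans, init)


def random_obs(rng, t_len, q, missing_frac=0.2):
    y = rng.normal(25.0, 20.0, size=(t_len, q))
    y[rng.random((t_len, q)) < missing_frac] = np.nan
    return y


@pytest.fixture(scope="session")
def two_state_config():
    """Well-separated 2-state, 2-item generative setup for quick fits."""
    return GenerativeConfig(
        n_subjects=12, subgroup_sizes=(6, 6), n_days=60, m=2, q=2,
        group_emission_means=np.array([[10.0, 15.0], [60.0, 70.0]]),
        between_subject_sd=3.0, within_subject_sd=8.0,
        group_transition_logits=np.array([[-1.2], [-1.2]]),
        subgroup_logit_effects=np.zeros((2, 2, 1)),
        logit_re_sd=0.3, missing_rate=0.05, max_missing_run=4,
        aux_state_probs=(0.0, 0.1))


@pytest.fixture(scope="session")
def two_state_data(two_state_config):
    return simulate_panel(two_state_config, seed=7)


@pytest.fixture
def tiny_panel():
    """2 subjects x 3 days x 2 items, complete."""
    y = np.array([[[10.0, 20.0], [11.0, 21.0], [12.0, 22.0]],
                  [[30.0, 40.0], [31.0, 41.0], [32.0, 42.0]]])
    return DiaryPanel(y=y, subject_ids=["a", "b"], item_names=["i1", "i2"],
                      subgroup=np.array([1, 2]))
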