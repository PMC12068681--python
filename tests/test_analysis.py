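"""Substate analyses: decoding, trajectories, bands, aux items, subgroups."""

import numpy as np
import pytest

from diaryhmm import (GenerativeConfig, StateSequence, binarize_aux,
                      crosstab_aux_by_state, decode_all, fit_mhmm, occupancy,
                      ordinal_consistency, severity_band, simulate_panel,
                      subgroup_transition_summary, switch_count,
                      logits_to_probs)
from diaryhmm.analysis import SeverityBands
from test_sampler import _constant_draws


class TestDecodeAll:
    def test_noise_free_panel_decodes_truth(self):
        cfg = GenerativeConfig(
            n_subjects=4, subgroup_sizes=(4,), n_days=40, m=2, q=2,
            group_emission_means=np.array([[5.0, 5.0], [80.0, 80.0]]),
            between_subject_sd=1e-9, within_subject_sd=0.5,
            group_transition_logits=np.array([[-1.0], [-1.0]]),
            subgroup_logit_effects=np.zeros((1, 2, 1)),
            logit_re_sd=1e-9, missing_rate=0.0, aux_state_probs=(0.0, 0.0))
        panel, truth = simulate_panel(cfg, seed=2)
        draws = fit_mhmm(panel, 2, iterations=80, burn_in=40,
                         n_extra_chains=0, seed=3, em_restarts=2)
        seqs = decode_all(panel, draws, force=True)
        acc = np.mean([np.mean(s.states == truth.true_states[j])
                       for j, s in enumerate(seqs)])
        assert acc == 1.0

    def test_masked_mode_marks_missing_days(self, two_state_data):
        panel, _ = two_state_data
        draws = fit_mhmm(panel, 2, iterations=60, burn_in=30,
                         n_extra_chains=0, seed=4, em_restarts=2)
        seqs = decode_all(panel, draws, force=True, mask_missing=True)
        for j, s in enumerate(seqs):
            assert (s.states[panel.day_missing[j]] == 0).all()
            assert (s.states[~panel.day_missing[j]] > 0).all()

    def test_unconverged_fit_refused_without_force(self):
        from diaryhmm.sampler import PosteriorDraws
        rng = np.random.default_rng(0)
        d = _constant_draws(n_chains=2, k=60)
        # separate the chains grossly so the MPSRF gate trips
        d.group = {k: v + np.where(np.arange(2)[:, None, None, None] > 0,
                                   5.0, 0.0) + rng.normal(0, 0.1, v.shape)
                   for k, v in d.group.items()}
        from diaryhmm import DiaryPanel
        panel = DiaryPanel(y=np.zeros((3, 4, 2)),
                           subject_ids=["a", "b", "c"],
                           item_names=["i1", "i2"], subgroup=np.ones(3))
        with pytest.raises(RuntimeError, match="not converged"):
            decode_all(panel, d)


class TestTrajectoryStats:
    def test_constant_sequence_has_no_switches(self):
        assert switch_count(StateSequence("a", [2, 2, 2, 2])) == 0

    def test_alternating_sequence(self):
        assert switch_count(StateSequence("a", [1, 2, 1, 2])) == 3

    def test_bridging_over_undefined_day(self):
        seq = StateSequence("a", [1, 0, 2])
        assert switch_count(seq, bridge=True) == 1
        assert switch_count(seq, bridge=False) == 0

    def test_occupancy_constant_state(self):
        occ = occupancy(StateSequence("a", [2, 2, 2]), m=4)
        np.testing.assert_array_equal(occ, [0, 1, 0, 0])

    def test_occupancy_even_split(self):
        occ = occupancy(StateSequence("a", [1, 1, 2, 2]), m=2)
        np.testing.assert_array_equal(occ, [0.5, 0.5])

    def test_occupancy_ignores_undefined_and_sums_to_one(self, rng):
        states = rng.integers(0, 4, size=50)
        if not (states > 0).any():
            states[0] = 1
        occ = occupancy(StateSequence("a", states), m=3)
        assert occ.sum() == pytest.approx(1.0)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            occupancy(StateSequence("a", [0, 0]), m=2)


class TestSeverityBands:
    @pytest.mark.parametrize("value,label", [
        (9.9, "negligible"),   # below 10 is negligible
        (10.0, "low"),         # boundary joins the low band
        (24.9, "low"),
        (25.0, "moderate"),    # 25 belongs to the moderate band
        (75.0, "moderate"),
        (75.1, "high"),
    ])
    def test_band_assignment(self, value, label):
        assert severity_band(value) == label

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            SeverityBands(negligible_upper=30.0, low_upper=25.0)


class TestOrdinalConsistency:
    def test_zero_heterogeneity_is_consistent(self):
        group = np.array([[5.0, 10.0], [50.0, 20.0]])
        subj = np.tile(group, (4, 1, 1))
        ok, violations = ordinal_consistency(subj, group)
        assert ok.all() and violations == []

    def test_swapped_subject_flagged(self):
        group = np.array([[5.0, 10.0], [50.0, 20.0]])
        subj = np.tile(group, (3, 1, 1))
        subj[1, :, 0] = subj[1, ::-1, 0]          # swap item-0 ordering
        ok, violations = ordinal_consistency(subj, group)
        assert not ok[0] and ok[1]
        assert (0, 1) in violations

    def test_small_heterogeneity_preserves_order(self, rng):
        """With between-subject spread well below the state separation, the
        item-wise state ordering survives in nearly all subjects."""
        cfg = GenerativeConfig(between_subject_sd=0.1)
        subj = rng.normal(cfg.group_emission_means, 0.1, size=(30, 4, 6))
        ok, _ = ordinal_consistency(subj, cfg.group_emission_means)
        assert ok.all()


class TestAux:
    @pytest.mark.parametrize("score,expect", [(4, 1), (3, 0), (0, 0), (7, 1)])
    def test_threshold_indicator(self, score, expect):
        assert binarize_aux(score) == expect

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_aux(8.0)

    def test_crosstab_counts_and_conservation(self):
        seqs = [StateSequence("a", [2, 3, 3, 0]),
                StateSequence("b", [1, 1, 4, 4])]
        events = np.array([[1, 1, 1, 1], [0, 0, 1, 0]], dtype=float)
        tab = crosstab_aux_by_state(events, seqs, m=4)
        assert tab["per_state"] == {1: 0, 2: 1, 3: 2, 4: 1}
        assert tab["undefined"] == 1
        assert sum(tab["per_state"].values()) + tab["undefined"] == tab["total"]

    def test_no_events_all_zero(self):
        seqs = [StateSequence("a", [1, 2])]
        tab = crosstab_aux_by_state(np.zeros((1, 2)), seqs, m=2)
        assert tab["total"] == 0
        assert set(tab["per_state"].values()) == {0}

    def test_misaligned_inputs_rejected(self):
        seqs = [StateSequence("a", [1, 2, 1])]
        with pytest.raises(ValueError, match="misaligned"):
            crosstab_aux_by_state(np.zeros((2, 3)), seqs, m=2)

    def test_generator_events_concentrate_in_severe_states(self):
        panel, truth = simulate_panel(GenerativeConfig(), seed=6)
        seqs = [StateSequence(sid, truth.true_states[j])
                for j, sid in enumerate(panel.subject_ids)]
        events = (np.nan_to_num(panel.aux, nan=0.0) >= 4).any(axis=2).astype(float)
        tab = crosstab_aux_by_state(events, seqs, m=4)
        severe = tab["per_state"][3] + tab["per_state"][4]
        assert severe / max(tab["total"], 1) >= 0.8


class TestSubgroupSummary:
    def test_zero_coefficients_make_subgroups_identical(self):
        d = _constant_draws(n_chains=1, k=30)
        d.group["beta"] = np.zeros((1, 30, 2, 2, 1))
        d.covariates = np.zeros((3, 2))
        dummies = {1: [0, 0], 2: [1, 0], 3: [0, 1]}
        summ = subgroup_transition_summary(d, dummies)
        np.testing.assert_allclose(summ.mean[0], summ.mean[1], atol=1e-12)
        np.testing.assert_allclose(summ.mean[0], summ.mean[2], atol=1e-12)

    def test_single_draw_cri_collapses(self):
        d = _constant_draws(n_chains=1, k=1)
        d.group["beta"] = np.zeros((1, 1, 1, 2, 1))
        summ = subgroup_transition_summary(d, {1: [0], 2: [1]})
        np.testing.assert_allclose(summ.lower, summ.mean, atol=1e-12)
        np.testing.assert_allclose(summ.upper, summ.mean, atol=1e-12)

    def test_shifted_subgroup_raises_target_probability(self):
        d = _constant_draws(n_chains=1, k=40)
        rng = np.random.default_rng(0)
        for key in d.group:
            d.group[key] = d.group[key] + rng.normal(0, 0.05, d.group[key].shape)
        beta = np.zeros((1, 40, 1, 2, 1))
        beta[..., 0, 0] = 2.5            # big shift on the 1->2 logit
        d.group["beta"] = beta
        summ = subgroup_transition_summary(d, {1: [0], 2: [1]})
        assert summ.mean[1][0, 1] > summ.mean[0][0, 1]
        assert summ.pairwise_nonoverlap(1, 2)[0, 1]
        # CrI ordering invariant
        assert (summ.lower <= summ.upper + 1e-12).all()

    def test_group_level_matches_no_effect_reference(self):
        d = _constant_draws(n_chains=1, k=30)
        d.group["beta"] = np.zeros((1, 30, 1, 2, 1))
        summ = subgroup_transition_summary(d, {1: [0], 2: [1]})
        expected = logits_to_probs(np.array([[-1.0], [0.5]]))
        np.testing.assert_allclose(summ.mean[0], expected, atol=1e-9)
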