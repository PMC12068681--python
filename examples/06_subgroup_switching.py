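"""Compare substate switching between severity subgroups.

Refits the model with dummy-coded subgroup membership as a subject-level
covariate on the transition logits, transforms each MCMC draw of the
subgroup logits back to probability space, and summarises each subgroup's
transition matrix with posterior means and 95% credible intervals,
flagging cells whose intervals do not overlap between subgroups.
"""

import numpy as np

from diaryhmm import (GenerativeConfig, fit_mhmm, simulate_panel,
                      subgroup_dummies, subgroup_transition_summary)

eff = np.zeros((2, 2, 1))
eff[1, 0, 0] = 2.0      # severe subgroup: raised logit out of the mild state
cfg = GenerativeConfig(
    n_subjects=40, subgroup_sizes=(20, 20), n_days=90, m=2, q=2,
    group_emission_means=np.array([[10.0, 12.0], [60.0, 65.0]]),
    between_subject_sd=5.0, within_subject_sd=8.0,
    group_transition_logits=np.array([[-1.5], [-1.0]]),
    subgroup_logit_effects=eff, logit_re_sd=0.7,
    aux_state_probs=(0.0, 0.0))
panel, _ = simulate_panel(cfg, seed=23)

x, cats = subgroup_dummies(panel.subgroup)
draws = fit_mhmm(panel, 2, iterations=900, burn_in=300, n_extra_chains=0,
                 seed=24, covariates=x)

summ = subgroup_transition_summary(draws, {1: [0.0], 2: [1.0]})
for gi, lab in enumerate(summ.subgroups):
    p = summ.mean[gi]
    print(f"subgroup {lab}: P(1->2) = {p[0, 1]:.3f} "
          f"[{summ.lower[gi][0, 1]:.3f}, {summ.upper[gi][0, 1]:.3f}]")
non = summ.pairwise_nonoverlap(1, 2)
print(f"credible intervals for P(1->2) nonoverlapping: {bool(non[0, 1])}")
print("The generating model gives subgroup 2 a +2.0 shift on the 1->2")
print("switching logit, so its switching probability should be clearly")
print("elevated and separated from subgroup 1.")
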