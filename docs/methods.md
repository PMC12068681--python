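# Methods

## Model

`diaryhmm` fits a multilevel (random-effects) hidden Markov model to
daily-diary panels: for subject *j* on day *t*, a latent substate
S_jt ∈ {1..m} evolves as a first-order Markov chain, and the observed
item-score vector y_jt (q items on a 0–100 scale) is Gaussian given the
substate, with items conditionally independent given the state:

    y_jtk | S_jt = i  ~  Normal(mu_jik, sigma2_ik)

Subject emission means are partially pooled toward group means,

    mu_jik ~ Normal(mubar_ik, tau2_ik),

so every subject shares the substates' meaning while expressing them at
their own level.  Each subject's transition matrix is parameterised by
multinomial logits with the self-transition as the reference category
(the i→i logit is fixed at 0, so off-diagonal logits read directly as
switching propensities).  The m(m−1) subject logits are Normal around a
group mean plus optional dummy-coded subject-level covariate effects
(e.g. severity-subgroup membership):

    eta_jil ~ Normal(gammabar_il + beta_il' x_j, psi2_il),

with independent random-effect variances per logit.  The initial-state
distribution is the stationary distribution of the subject's transition
matrix (uniform if not unique), which avoids estimating m−1 extra free
parameters per subject from a single sequence.

Modelling assumptions worth stating plainly: transition probabilities are
constant over the assessment period; the chain is first-order; emissions
are unbounded Gaussians despite the 0–100 instrument range; items are
independent given the state (diagonal covariance); whole-day missingness
is missing at random.

## Priors

Weakly informative on the 0–100 scale, all overridable via `PriorConfig`:
group emission means Normal(50, 100²); between-subject and residual
variances scaled-inverse-χ²(ν₀=1, s²₀=100); group transition-logit means
Normal(0, 9) and covariate coefficients Normal(0, 9) (wide on the logit
scale); logit random-effect variances scaled-inverse-χ²(ν₀=3, s²₀=1).
Note that the logit-variance prior keeps 95% of its mass above ≈0.32 and
the emission-variance priors are right-skewed with medians far above
typical diary noise; simulation studies that assess interval coverage of
variance components should generate from values these priors are
comfortable with (the bundled recovery tests use τ²=36, ψ²=1).

## Estimation

A hybrid Metropolis-within-Gibbs sampler. Each iteration:

1. **State paths** — exact forward-filtering backward-sampling (FFBS) per
   subject, vectorised across subjects; days with all items missing
   contribute an emission term of 1 and the recursion carries through.
2. **Imputation** — missing items are drawn from the emission
   distribution of the day's sampled state; imputations are per-iteration
   (multiple imputation) and never written back to the data.
3. **Emission block** — conjugate Gibbs updates: subject means
   (Normal), group means (Normal), between-subject variances and residual
   variances (scaled-inverse-χ²).
4. **Transition block** — random-walk Metropolis on each subject's logit
   rows. The path likelihood factorises over rows through the transition
   counts, but the initial-state term (stationary distribution of the full
   matrix) couples rows, so rows are updated sequentially with the
   stationary factor recomputed for each proposal; omitting that factor
   measurably biases the no-data (prior-recovery) check. Proposal scales
   adapt per subject-row toward a 0.35 acceptance rate during burn-in
   (Robbins–Monro on the log scale, gain 2/(t+10)^0.6, clipped to
   [1e-3, 20]) and are frozen afterwards to preserve the Markov property.
5. **Logit level** — per logit, a conjugate Bayesian linear regression of
   subject logits on the dummy covariates gives joint draws of the group
   mean and coefficients; the random-effect variance follows by
   scaled-inverse-χ².

The main chain is initialised from a pooled single-level Baum–Welch EM
fit (multi-start: one deterministic per-item-quantile start plus seeded
jitters, 10 restarts by default, relative tolerance 1e-6, emission SDs
floored at 0.5 scale units); extra chains (default 2) start from
randomised perturbations of it.  The study-scale protocol is 4000
iterations with 1000 burn-in.

**Label switching.** States are kept on a severity ordering — increasing
sum of group emission means across items — imposed at EM initialisation
and re-asserted on the stored draws per chain after sampling (logit-shaped
arrays are permuted through their full m×m form, which is exact because
the self-logit is 0 under any labelling). In practice the multilevel
pooling plus EM start pins labels and the post-hoc permutation is almost
always the identity.

**Degenerate cases.** A state visited by zero subject-days in an
iteration simply receives draws from its conditional prior (the event is
counted and reported on the fit object). A panel with no observed data at
all is valid input and returns the priors — this is used as a correctness
check.

## Model selection

AIC = −2·logL + 2·p, with logL the marginal (forward-algorithm)
likelihood evaluated at posterior medians of the group-level parameters
and subject parameters set to the group means, and p counting group-level
free parameters only: 3mq + 2m(m−1), plus C·m(m−1) with covariates. This
convention is stated because a multilevel "the" likelihood is ambiguous;
it is cheap, reproducible, and selects the generating state count in the
bundled simulations when between-subject heterogeneity is moderate. Its
known failure mode: with strong random effects, a group-mean plug-in
likelihood rewards extra states that absorb between-subject variation, so
AIC comparisons should be read alongside the posterior-predictive checks
rather than alone.

## Diagnostics

**Convergence** uses Brooks–Gelman potential scale reduction factors over
all group-level parameters, from the main chain plus the
randomised-start chains, with the conventional 1.05 threshold; decoding
refuses an unconverged multi-chain fit unless forced. The computation
rescales by within-chain SDs so it is exactly invariant to affine
reparameterisation; zero-variance parameters are flagged and set to 1.
One caveat measured here: with P parameters and M chains the multivariate
statistic has an upward noise floor of roughly
(√P+√2)²·τ_int/(2·n_kept) even for well-mixed chains (the between-chain
covariance has rank M−1), so at P≈100 it demands chain lengths well beyond
what the univariate factors need — reports therefore include both MPSRF
and the maximum univariate PSRF.

**Posterior-predictive checks** regenerate complete panels through the
same simulator used for synthetic data (a single code path): at the group
level, new hypothetical cohorts with subject parameters drawn from the
group-level distributions of a random posterior draw; at the individual
level, each real subject from posterior draws of their own parameters.
The observed missingness pattern is applied to replicates so summaries
are comparable. Per-item (or per subject-item) means, SDs and deciles are
compared by lower tail areas; under the true model these are calibrated,
with the usual conservatism of posterior-predictive p-values.

**Residuals** subtract the subject's fitted emission mean of the
Viterbi-decoded state from each observed score (state-specific by
default; a state-blind variant subtracting the occupancy-weighted grand
mean exists for fidelity to simpler conventions, but is trivially
heteroscedastic across states). Tests: per subject-item zero-mean t-test;
homoscedasticity as the two-sided test of the slope of |residual| on the
day index; per-subject aggregated zero-mean t-test. Missing days are
excluded.

## Decoding and downstream summaries

Viterbi decoding uses posterior-mean subject parameters (emission means
averaged over draws; transition matrices averaged in probability space
then renormalised), with ties broken toward the lower state index. For
statistics, all-missing days are decoded through; for display they can be
masked as undefined. Switch counts bridge undefined days by comparing
nearest defined neighbours (a strict no-bridge mode exists); occupancy is
the fraction of defined days per state. Severity bands label emission
means as negligible (<10), low ([10, 25)), moderate ([25, 75]) or high
(>75) — the half-open convention resolves inconsistent interval notation
in the applied literature into one coherent function. Auxiliary 0–7 items
are binarised at ≥4 and cross-tabulated against decoded states with an
explicit undefined-state row so counts conserve.

Subgroup switching comparisons transform γ̄ + βᵀx to probability space per
kept draw, then summarise per subgroup cell with posterior means and 95%
credible intervals; pairwise differences are flagged by CrI nonoverlap
(conservative by design; posterior difference probabilities can be
computed from the same draws if a sharper criterion is wanted).

## Synthetic data

The generator emulates the structure of a 90-day diary study on the
psychosis continuum: N=96 subjects in four severity subgroups
(25/27/24/20), T=90 days, four substates of increasing severity, six
items (four attenuated-psychotic, two affective) with default group means
placed inside the severity bands above, between-subject SD 5, within-state
SD 10, transition logits decaying with state distance (self-transition
probabilities ≈0.6–0.75, a few dozen switches per subject), subgroup
shifts that raise flow into and retention within the two most severe
states in proportion to severity grade, logit random-effect SD 0.5,
whole-day MCAR missingness at rate 6.9/90 with runs capped at 4 by
rejection, and two auxiliary 0–7 items whose ≥4 endorsement probability
is concentrated on the two most severe states (0.1%/0.1%/4%/10%).

What it does not emulate: emissions are not clipped to [0, 100] by
default (keeping the fitted Gaussian model exactly true so recovery tests
are clean; a clipping mode exists), there are no response styles, weekly
cycles, floor effects, time-varying treatment effects, or informative
missingness. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model's own assumptions, not
robustness to the ways real diary data violate them.

## Problem sizes used by the bundled checks

The test-suite acceptance checks are the package's desk-scale defaults:
parameter recovery and missing-data robustness use 5 replications of
N=40, T=90, m=3, q=4 well-separated panels at 1300 iterations (800
kept); state-count selection uses 2 replications of N=30 at 700
iterations over m ∈ {2,3,4}; covariate recovery uses 2 replications of
N=60, m=2 at 900 iterations plus one large-effect run; the diagnostics
bundle uses one 3-chain fit with 6000 kept iterations; prior recovery
uses a 12000-iteration run on an all-missing 4-subject panel. Thresholds
match the full-scale protocol; only replication counts and chain lengths
are reduced. `scripts/acceptance.py` runs the full study-shaped pipeline
(N=96, m=4, three chains, 3000 iterations) in a few minutes.

## Known limitations

- Dwell times are geometric (no semi-Markov durations); transitions are
  time-constant; no higher-order dependence.
- Covariates enter transition logits only, not emissions.
- Random effects are independent across logits and across emission cells
  (no correlated random effects).
- The AIC convention above is one defensible choice among several; an
  alternative computing AIC from the single-level initialisation fit is
  available by applying `aic` to the EM output.
- CrI-nonoverlap subgroup comparison is conservative relative to
  posterior contrast probabilities.
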