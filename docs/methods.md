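# Methods

## The problem and the model

A randomised trial compares treatment (`r=1`) with control (`r=0`).  After
an interim result, everyone still at risk in the control arm is offered the
treatment at a known per-subject time `s_i` (the *offer* or potential
crossover time, observable for all subjects in both arms).  Two latent
strata are assumed: *insistors* (`c=1`), who would switch when offered if
randomised to control, and *ambivalents* (`c=0`), who would not.  Nobody
switches from treatment to control.  The stratum is revealed only for
control-arm subjects still under observation at their offer time; it is
never observed in the treatment arm, nor for control subjects who exit
before the offer.

Efficacy is defined on the ambivalents: they are the only stratum whose
members are observed under both treatments over the whole follow-up.
Randomisation makes the baseline insistor probability `pi` equal in both
arms; censoring is assumed independent of the stratum.

## Binomial model

Follow-up is split at the offer into periods `t=0,1`.  Cell probabilities
are built from the ambivalent control rates `alpha_t` via the efficacy
ratio `gamma_t = p_t10/p_t00`, the insistor ratio `omega_t = p_t11/p_t10`,
the pre-offer proportionality assumption `p_001 = omega_0 * alpha_0`, and a
post-crossover insistor effect `p_101 = gamma1* * omega_1 * alpha_1`.  The
primary model ties `gamma_0 = gamma_1 = gamma1*` and `omega_0 = omega_1`,
leaving (`alpha_0`, `alpha_1`, `omega`, `gamma`) plus the baseline insistor
probability `pi`.

The likelihood is a product of binomial kernels over the five observed
cells — both arms pre-offer and the treatment arm post-offer as
two-component mixtures over the latent stratum, and the two revealed
post-offer control rows per stratum.  Two derived quantities close the
model:

- `pi11`, the insistor probability among treatment-arm subjects still at
  risk at the offer, equals the expected number of insistors surviving the
  first period (enrolled insistors minus the insistor share of events and,
  using censoring-stratum independence, of censorings) divided by the
  observed post-offer risk-set size, clipped to [0, 1];
- `pi` itself is *profiled out*: it solves the same expected-survivor
  relation in the control arm equated to the **observed** revealed insistor
  count.  With the observed first-period event count plugged in, the
  relation is a quadratic polynomial in `pi` given `omega` (option
  `pi_rule="observed"`, the default); plugging the model-expected event
  count instead gives a linear relation (`pi_rule="expected"`).  The two
  differ only in the third decimal of the estimates.  Leaving `pi` as a
  free fifth parameter without this constraint makes the model saturated on
  a five-cell table, in which case the MLE of a common `gamma` degenerates
  to the pre-offer event-ratio and the revealed crossover count carries no
  information; the constraint is what lets the count table identify the
  mixture.

Fitting is by Nelder–Mead simplex on the log scale (log `alpha_t`, log
`omega`, log `gamma`), with an explicit `-inf` barrier when any implied
cell probability leaves (0, 1) — products such as `omega*gamma*alpha` can
exceed 1 inside an unconstrained logit parameterisation, which is why a
plain logit transform is not used.  A fixed list of five deterministic
start points (moment-based anchor plus spread in `omega` and `gamma`) is
searched and the best kept, with one restart at the incumbent; tolerance
1e-9 on the log-likelihood.  A constant-rate option
`alpha_t = 1 - exp(-alpha* T_t)` with user-supplied period lengths is
available behind `constant_rate` flags and is off by default.

Profile-likelihood confidence intervals re-maximise all other parameters
at each candidate value (warm-started from the neighbouring profile
point), bracket each endpoint by geometric expansion from the MLE, and
bisect the likelihood-drop sign to a relative tolerance of 1e-4; the
cutoff is the chi-square(1) quantile (3.841 at 95%).  An endpoint that
cannot be bracketed within a 1000-fold range is reported as open
(`0` or `inf`), not an exception.  Nested variants are compared by
likelihood-ratio tests with degrees of freedom equal to the difference in
free-parameter count.

Moment diagnostics (`moment_estimates`) give closed-form starting values
and checks: the pre-offer efficacy is the event-proportion ratio between
arms; the post-offer efficacy subtracts the insistor share out of both
arms with a plug-in `pi11` (the observed control event proportion is
de-mixed by `1 - pi + pi*omega` before entering the survivor relation).

## Proportional-hazards model

The hazard is `lambda_0i(t) * psi` with
`psi = exp[gamma*(r + I(t>=s)(1-r)c) + omega*c + x'beta]`: treated
subjects carry the log treatment effect `gamma` throughout, control
insistors acquire it from their own offer time onward, insistors differ
everywhere by `omega`.  Covariates are time-fixed; the baseline hazard may
be stratified by an explicit `stratum` label.

### Insistor-at-risk tracking

For the control arm, subjects are ordered by `t'_j = min(t_j, s_j)` and
classified: unknown-stratum event (`e=0`), revealed ambivalent (`e=1`),
revealed insistor (`e=2`), unknown-stratum censoring (`e=3`).  Starting
from a baseline count `u`, the running insistor count decrements by
`xi_j`: 0 or 1 for revealed updates, the current odds-weighted share
`pi*w / (1-pi+pi*w)` with `w = exp(omega)` for unknown events (an event is
`w` times as likely to be an insistor, per the proportional-hazards
relation between the two strata), and the current proportion for unknown
censorings (leaving the proportion unchanged, by censoring independence).
Tied update times share one reported proportion (the value after the last
member of the tied block).  If the count drifts outside `[0, pool]` under
extreme `omega` it is clipped and the trajectory flagged.

The baseline count `u` is estimated, given `omega`, by maximising a
Bernoulli likelihood over the revealed updates only: each contributes
`log pi` or `log(1-pi)` evaluated at the proportion *just before* the
update (before the first member of a tied block).  The literal "value at
`t'_j`" convention (after the update) degenerates — the final crossover
out of an emptied pool contributes `log 0` — and fails the alternating
revelation symmetry check (`u-hat = n0/2`), so the left-limit convention
is used.  `u` is continuous in `[0, n0]` (the likelihood is smooth in
`u`; integrality is never required) and maximised by bounded Brent search
with explicit boundary checks.

The treatment arm is tracked with the same rule, starting from the same
baseline proportion (randomisation), with every event treated as
unknown-stratum (`e=0`) and every censoring as `e=3` — the stratum is
never revealed there, and the estimate updates at each event in that arm.

### Partial likelihood

Each event contributes its hazard multiplier over the risk-set sum; a
subject whose stratum is unknown at the event time (treatment arm, or
control before their offer) enters through the mixture
`pi(t|arm)*psi(c=1) + (1-pi(t|arm))*psi(c=0)` with `pi(t|arm)` the tracked
left-limit proportion; a revealed control subject enters with their known
`psi`.  With baseline-hazard strata, per-stratum partial likelihoods are
summed.  Without covariates the risk-set sum collapses onto four
time-indexed block counts (treatment, unknown control, revealed
ambivalent, revealed insistor), so one evaluation is O(events);
with covariates precomputed risk-set masks are used.

`fit_partial` alternates: (given `omega`) estimate `u`, rebuild both
trajectories; (given trajectories) maximise over (`gamma`, `omega`,
`beta`) by Nelder–Mead; until the partial log-likelihood moves by less
than 1e-8 (at most 100 outer cycles).  The partial-likelihood estimator
requires strata to be independent of covariates unconditionally, so a
single independence group is supported here; per-group proportions belong
to the full-likelihood estimator.

### Baseline hazard

`lambda_0` is a step function with jumps `Delta_i` at the distinct event
times (tie multiplicities `w_i`; times closer than 1e-12 are tied).  The
score equation in `Delta_i` involves, for every subject at risk, a
positive "drag" term: for unknown-stratum subjects the mixture-weighted
product of hazard multiplier and survivor factor; for revealed subjects
past their offer simply `psi`; for revealed subjects whose offer is still
ahead the mixture over the survivor-to-offer factor.  Differencing the
score equations of consecutive event times telescopes away all common
terms, leaving only subjects exiting in the gap (events at the earlier
time, censorings between) and revealed subjects whose offer falls inside
the gap (whose drag switches form).  This yields the recursion
`w_{i+1}/Delta_{i+1} = w_i/Delta_i - D_i` with `D_i` computable from
quantities already known when `Delta_i` is, so the whole vector is a
function of the first jump.  The remaining equation — the score at the
last event time — is solved for the first jump by bracketed root finding
(initial bracket `[1e-12, 1e3/max psi]`, geometric x10 expansion up to 5
times, sign bisection while the upper end is infeasible, Brent refinement
on the feasible bracket, tolerance ~1e-12).  Jumps at the root are
checked positive.  With `psi == 1` and no latent strata the recursion
reproduces the Breslow/Nelson–Aalen increments `1/(risk-set size)`
exactly, and on small cohorts it matches joint numerical maximisation of
the full likelihood over all jumps to 1e-6 (tested).

Convention for a revealed control subject: the marginal survivor factor
runs to just before the offer (`Lambda_0(s-)`), and the jump at a time
equal to the offer belongs to the post-offer piece, matching the
`I(t>=s)` convention in `psi` and the classification of an event exactly
at the offer as revealed.

### Full likelihood and the profile cycle

Unknown-stratum subjects contribute the two-component mixture of
conditional likelihoods `[Delta psi]^delta * exp(-Lambda(t|c))`; revealed
control subjects contribute the *marginal* survivor to just before the
offer times the conditional hazard/survivor piece from the offer onward
with the revealed stratum.  `fit_full` starts from the partial-likelihood
solution and cycles: estimate the baseline insistor probability per
independence group (from the revealed-update likelihood, given `omega`);
fit the baseline hazard per stratum given `pi` and `theta`; re-fit
`theta` by simplex on the full log-likelihood; until the full
log-likelihood changes by less than 1e-8 (at most 200 cycles).  Because
the `pi` step is an external estimator rather than an ascent step, the
cycle is not exactly monotone; it exhibits geometrically decaying dips of
order 1e-3 and below.  The fit reports the iterate with the highest full
likelihood; decreases beyond 0.05 in one cycle are logged as warnings.
Inference is by profile likelihood on the full likelihood (the cycle
re-run with the target parameter held fixed, chi-square(1) cutoff);
Wald intervals from the partial likelihood are deliberately not offered,
as they treat the tracked proportions as known.

## Simulator

The generator emulates the standard eight-scenario design: 1000 subjects
per arm; insistor traits drawn independently per arm with probability
0.25; offer times uniform on [1, 2); exponential event times with rate
`base * exp(gamma*treated + omega*c)`, where control insistors switch to
the treated rate at their own offer time (memoryless restart).  The base
rate makes the event probability before the first possible crossover in
the lowest-hazard (arm, trait) cell equal 0.05 with censoring and 0.10
without.  With censoring, follow-up is capped at a horizon `F` chosen so
that the same cell has probability 0.05 of an event between the end of
the crossover window and `F`, with the post-crossover rate applied from
the end of the window (a simplification that only moves `F`, not the
estimands).  Uncensored scenarios follow everyone to the event.

What the generator does *not* emulate: covariates, non-exponential
baselines, staggered entry, stochastic (health-driven) crossover times,
or dependent censoring.  Passing the recovery tests therefore shows the
estimators are correct under the model's own assumptions, not that they
are robust to violations of them.  Replicate seeds are spawned from one
base seed and recorded per row.

## Bootstrap

Subjects are resampled with replacement within each randomised arm (arm
sizes preserved; arms sorted canonically so the draw is invariant to row
order), the estimator refitted, and the empirical variance of the
log-scale estimates over successful resamples reported.  Failed refits
are dropped and counted; more than 20% failures flags the result.  No
percentile or BCa machinery is provided — variance only.

## Diagnostics

`check_assumptions` is advisory and never blocks fitting: a chi-square
comparison of post-offer censoring fractions between revealed strata, a
rank test of covariate balance by revealed stratum, and a
Kolmogorov–Smirnov comparison of offer times by stratum.  Note a known
blind spot: under a shared administrative horizon, strata with different
hazards censor at different *fractions* even when the censoring
*mechanism* is stratum-independent, so the censoring flag fires on valid
designs with strong insistor effects.

## Problem sizes and determinism

The packaged analyses use the published count table directly.  The
simulation study is re-run at 100 replicates per scenario (the package's
choice of replication for routine verification); at that replication the
Monte-Carlo standard error of the scenario-4 mean treatment effect is
about 0.004 on the natural scale and of the scenario-1 mean insistor
percentage about 0.2 points.  All fits are deterministic given data and
options; all simulation randomness derives from explicit seeds.

## Known limitations

- Mortality-style endpoints, where a recurrence before the offer hides
  the stratum of a survivor, are out of scope (the count summarisation
  assumes strata are revealed for everyone at risk at the offer).
- No defiers: crossover from treatment to control is rejected at
  validation.
- No time-varying covariates; no Efron-style tie corrections beyond the
  tie rules described; no IPCW or g-estimation comparators.
- The binomial `pi11` is a plug-in derived quantity; its sampling
  variability is absorbed by the profile-likelihood intervals only
  through the profiled parameters.
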