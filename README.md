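# crossfx

Estimators of treatment efficacy for randomised trials with **selective
crossover**: one arm looks better at an interim analysis, a data-monitoring
committee recommends offering everybody the apparently superior treatment,
and part of the control arm switches.  Because the switchers ("insistors")
typically carry a different background risk than those who stay
("ambivalents"), both intention-to-treat and per-protocol contrasts are
distorted afterwards.  `crossfx` estimates the effect of treatment on the
ambivalents — the only stratum observed under both treatments for the whole
follow-up — using a two-latent-strata model.

The package is aimed at trial statisticians and methods researchers.  It
provides:

- a **binomial latent-strata model** on two-period count tables
  (events/at-risk before and after the offer, with the post-offer control
  rows split by revealed stratum), with maximum-likelihood fitting,
  profile-likelihood confidence intervals and nested-model tests;
- **proportional-hazards latent-strata estimators** on subject-level data:
  the hazard is `lambda_0(t) * exp(gamma*(r + I(t>=s)(1-r)c) + omega*c + x'beta)`,
  where `r` is the randomised arm, `c` the latent insistor stratum and `s`
  the offer time — a *partial-likelihood* estimator that weights unknown
  strata by the tracked proportion of insistors still at risk, and a
  *full-likelihood* estimator that adds a nonparametric step baseline hazard
  estimated by a score recursion;
- a **trial simulator** for the standard eight-scenario study design and a
  **per-arm bootstrap** for variance estimation.

## Worked example

The packaged fixture is the published two-period disease-free-survival
count table from the BIG 1-98 breast-cancer trial (letrozole vs tamoxifen;
the tamoxifen arm was unblinded after early results and 619 of 1975 women
still at risk chose to cross over):

```python
from crossfx import big198_counts, fit_binomial, profile_ci, lr_test

counts = big198_counts()
fit = fit_binomial(counts, "common")          # one efficacy, one insistor effect
lo, hi = profile_ci(counts, "common", "gamma", fit=fit)
print(fit.params.gamma0, (lo, hi))
```

Running `python examples/01_binomial_worked_example.py` prints:

```
efficacy gamma-hat = 0.86 (95% profile CI 0.77, 0.96)
insistor effect omega-hat = 0.59, baseline insistor fraction pi-hat = 0.293, pi11-hat = 0.309
period-specific: gamma0-hat = 0.84, gamma1-hat = 0.90
heterogeneity LR test: chi2(1) = 0.32, p = 0.57
intention-to-treat relative risk (cumulative counts) = 0.89
```

Reading the numbers: treatment reduces the event risk of the ambivalents by
an estimated 14% (risk ratio 0.86, CI 0.77–0.96).  The insistors' risk is
0.59 times the ambivalents' — the women who switched were at lower risk, which
is exactly why a per-protocol analysis censoring them would be biased.  The
ITT relative risk (0.89) is closer to 1 because after the offer a quarter of
the control arm was effectively treated.  The period-specific efficacies
(0.84 before, 0.90 after the offer) do not differ significantly
(LR = 0.32 on 1 df), supporting a single overall efficacy.

The other examples fit the proportional-hazards estimators on simulated
trials (`02`, `03`) and run the bootstrap and assumption diagnostics (`04`).
A thin CLI mirrors the library: `crossfx fit-binomial`, `fit-ph`,
`simulate`, `bootstrap`, `check-assumptions`, `make-fixture`.

## Layout

```
src/crossfx/    data.py (containers, ingestion, diagnostics)
                binomial.py (two-period model, profile CIs, LR tests)
                ph.py (trajectories, partial & full likelihood, baseline hazard)
                simulate.py, bootstrap.py, fixtures.py, report.py, cli.py
examples/       one narrative script per capability
tests/          pytest suite (unit, property and acceptance tests)
docs/methods.md model, algorithms, numerical choices and limitations
```
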