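"""Bootstrap variance and assumption diagnostics on one simulated trial.

Resamples subjects with replacement within each arm, refits the
partial-likelihood estimator, and reports the bootstrap variance of the
log treatment effect; then runs the advisory censoring/stratum
diagnostics on the same cohort.
"""

from crossfx import (SimScenario, bootstrap_variance, check_assumptions,
                     fit_partial, simulate_trial)
from crossfx.simulate import ESTIMATORS

scenario = SimScenario.preset(1, n_per_arm=400)
cohort = simulate_trial(scenario, seed=11)
fit = fit_partial(cohort)
print(f"point estimate: gamma-hat (log) = {fit.params.gamma:.3f}")

result = bootstrap_variance(cohort, ESTIMATORS["PL"], B=60, seed=3)
print(f"bootstrap variance of log gamma-hat over B={result.B}: "
      f"{result.variance('gamma'):.4f} "
      f"({result.failures} failed resamples)")
print("Across-replicate variance at this design is of the same order; "
      "the per-arm bootstrap is the recommended route to uncertainty.")

report = check_assumptions(cohort)
print("\nassumption diagnostics (advisory):")
print("  censoring by revealed stratum:", report.censoring or "n/a")
print("  offer time by revealed stratum:", report.entry_time or "n/a")
print("  flags:", report.flags or "none")
print("\nNote: with a shared administrative horizon, strata with "
      "different hazards reach the horizon at different rates, so the "
      "censoring-fraction flag fires even though the censoring mechanism "
      "itself is stratum-independent -- the report is advisory, never a "
      "gate on fitting.")
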