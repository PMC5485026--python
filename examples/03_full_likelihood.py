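"""Full-likelihood estimation with a nonparametric baseline hazard.

Simulates a censored trial (scenario: treatment hazard ratio 0.7,
insistors protected at 0.2x), fits the full-likelihood estimator
(partial-likelihood start, then the profile cycle over insistor
proportion, step baseline hazard and effect parameters) and prints the
estimated cumulative baseline hazard at round times.
"""

import math

import numpy as np

from crossfx import SimScenario, fit_full, simulate_trial

scenario = SimScenario.preset(1, n_per_arm=600)
cohort = simulate_trial(scenario, seed=7)
print(f"simulated {len(cohort)} subjects, "
      f"{int(cohort.df.event.sum())} events (follow-up capped)")

fit = fit_full(cohort)
print(f"exp(gamma-hat) = {math.exp(fit.params.gamma):.3f}  (truth 0.700)")
print(f"exp(omega-hat) = {math.exp(fit.params.omega):.3f}  (truth 0.200)")
print(f"baseline insistor fraction = {fit.pi_baseline:.3f}  (truth 0.250)")
print(f"converged after {len(fit.history)} outer cycles, "
      f"log-likelihood {fit.loglik:.1f}")

bh = fit.baselines["_all"]
grid = [0.5, 1.0, 1.5, 2.0, 2.5]
cum = bh.cumhaz(np.array(grid))
print("\ncumulative baseline hazard (control ambivalent):")
for t, c in zip(grid, cum):
    print(f"  Lambda0({t:.1f}) = {c:.3f}   (truth {0.3664 * t:.3f})")
print("The step estimate follows the exponential truth; jumps sit at "
      "observed event times.")
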