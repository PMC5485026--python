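"""Partial-likelihood estimation on a simulated crossover trial.

Simulates one trial (1000 per arm, 25% insistors, treatment halves the
hazard ratio to 0.7, insistors at twice the ambivalent hazard, no
censoring), fits the partial-likelihood estimator and shows the
tracked insistor-at-risk trajectory in the control arm.
"""

import math

from crossfx import SimScenario, fit_partial, simulate_trial

scenario = SimScenario.preset(4)   # exp(gamma)=0.7, exp(omega)=2, no censoring
cohort = simulate_trial(scenario, seed=14)
print(f"simulated {len(cohort)} subjects, "
      f"{int(cohort.df.event.sum())} events")

fit = fit_partial(cohort)
print(f"exp(gamma-hat) = {math.exp(fit.params.gamma):.3f}  (truth 0.700)")
print(f"exp(omega-hat) = {math.exp(fit.params.omega):.3f}  (truth 2.000)")
print(f"baseline insistor fraction = {fit.pi_baseline:.3f}  (truth 0.250)")

traj = fit.trajectories[0].to_frame()
print("\ncontrol-arm insistor trajectory around the crossover window:")
window = traj[(traj.time > 0.9) & (traj.time < 2.1)]
print(window.iloc[:: max(1, len(window) // 8)].to_string(index=False))
print("\npi_hat falls through [1, 2) as insistors reveal themselves by "
      "crossing over and leave the latent pool.")
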