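"""Trial simulator for the selective-crossover model.

Cohorts are generated from exponential survival with three follow-up
phases: before the crossover window, during it (offer times uniform on
[1, 2)), and after.  Each subject draws an insistor trait at baseline
(independently per arm), a pre-crossover survival time at the rate of
their (arm, trait) group, and, if they survive to their own offer
time, a fresh post-crossover residual time at the post-crossover rate
(control insistors acquire the treatment effect from the offer
onward).  The base rate is calibrated so a stated fraction of events
falls before the first crossover in the lowest-hazard group; with
censoring, follow-up ends at a horizon calibrated so the same fraction
falls after the last crossover.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import SubjectCohort
from .errors import CalibrationError
from .ph import fit_full, fit_partial

logger = logging.getLogger(__name__)

#: the eight standard scenarios: (exp(gamma), exp(omega), censoring)
PRESETS = {
    1: (7 / 10, 0.2, True),
    2: (7 / 10, 0.2, False),
    3: (7 / 10, 2.0, True),
    4: (7 / 10, 2.0, False),
    5: (10 / 7, 0.2, True),
    6: (10 / 7, 0.2, False),
    7: (10 / 7, 2.0, True),
    8: (10 / 7, 2.0, False),
}


@dataclass
class SimScenario:
    """Configuration of one simulated trial scenario.

    Defaults follow the standard study design: 1000 subjects per arm,
    25% insistors, crossover offers uniform on [1, 2), exponential
    event times, and a base rate set so that 5% (censored design) or
    10% (uncensored) of events in the lowest-hazard group fall before
    the first crossover.
    """

    n_per_arm: int = 1000
    pi: float = 0.25
    exp_gamma: float = 7 / 10
    exp_omega: float = 2.0
    censoring: bool = False
    crossover_window: tuple[float, float] = (1.0, 2.0)
    pre_fraction: float | None = None  # default 0.05 censored / 0.10 not

    @classmethod
    def preset(cls, k: int, **overrides) -> "SimScenario":
        eg, ew, cens = PRESETS[k]
        return cls(exp_gamma=eg, exp_omega=ew, censoring=cens, **overrides)

    @property
    def gamma(self) -> float:
        return math.log(self.exp_gamma)

    @property
    def omega(self) -> float:
        return math.log(self.exp_omega)


@dataclass
class CalibratedRates:
    """Hazard rates per (arm, trait) group and the follow-up horizon."""

    base: float                      # rate of the lowest-hazard group / its multiplier
    lam_pre: dict                    # (r, c) -> pre-crossover rate
    lam_post: dict                   # (r, c) -> post-crossover rate
    horizon: float                   # max follow-up F (inf when uncensored)
    lowest: tuple[int, int]          # the lowest-hazard (arm, trait) group


def calibrate_rates(scenario: SimScenario) -> CalibratedRates:
    """Calibrate group hazards and the censoring horizon.

    The lowest-hazard group is the (arm, trait) cell with the smallest
    pre-crossover multiplier ``exp(gamma*r + omega*c)``.  Its rate
    solves ``P(T < 1) = q`` with ``q = 0.05`` (censored design) or
    ``0.10`` (uncensored).  With censoring, the horizon ``F`` solves
    ``P(2 < T < F) = 0.05`` in that group, with the post-crossover rate
    applying from the end of the crossover window.
    """
    g, om = scenario.gamma, scenario.omega
    t_first, t_last = scenario.crossover_window
    q = scenario.pre_fraction
    if q is None:
        q = 0.05 if scenario.censoring else 0.10

    def mult_pre(r, c):
        return math.exp(g * r + om * c)

    def mult_post(r, c):
        # treated throughout in arm 1; control insistors treated after s
        return math.exp(g * (r + (1 - r) * c) + om * c)

    groups = [(r, c) for r in (0, 1) for c in (0, 1)]
    lowest = min(groups, key=lambda rc: mult_pre(*rc))
    lam_low = -math.log(1.0 - q) / t_first
    base = lam_low / mult_pre(*lowest)
    lam_pre = {rc: base * mult_pre(*rc) for rc in groups}
    lam_post = {rc: base * mult_post(*rc) for rc in groups}

    if scenario.censoring:
        s2 = math.exp(-lam_pre[lowest] * t_last)
        if s2 <= q:
            raise CalibrationError(
                f"tail mass {s2:.4f} at the end of the crossover window is "
                f"below the requested post-crossover event fraction {q}")
        horizon = t_last + math.log(s2 / (s2 - q)) / lam_post[lowest]
    else:
        horizon = float("inf")
    return CalibratedRates(base=base, lam_pre=lam_pre, lam_post=lam_post,
                           horizon=horizon, lowest=lowest)


def simulate_trial(scenario: SimScenario, seed: int,
                   rates: CalibratedRates | None = None) -> SubjectCohort:
    """Generate one trial cohort.

    Per subject: draw the insistor trait, an offer time uniform on the
    crossover window, a pre-crossover exponential survival time and a
    post-crossover residual; the uncensored time is the pre-crossover
    draw if it precedes the offer, else offer plus residual; observed
    time and event status truncate at the horizon.  The revealed
    crossover status is stored only for control subjects observed past
    their offer.
    """
    if rates is None:
        rates = calibrate_rates(scenario)
    rng = np.random.default_rng(seed)
    lo, hi = scenario.crossover_window
    frames = []
    for r in (0, 1):
        n = scenario.n_per_arm
        c = (rng.uniform(size=n) < scenario.pi).astype(int)
        s = rng.uniform(lo, hi, size=n)
        pre = np.array([rates.lam_pre[(r, ci)] for ci in c])
        post = np.array([rates.lam_post[(r, ci)] for ci in c])
        t1 = rng.exponential(1.0 / pre)
        t2 = rng.exponential(1.0 / post)
        tu = np.where(t1 <= s, t1, s + t2)
        t = np.minimum(tu, rates.horizon)
        d = (t < rates.horizon).astype(int)
        crossed = np.where((r == 0) & (t >= s), c.astype(float), np.nan)
        frames.append(pd.DataFrame({
            "arm": r, "time": t, "event": d, "offer_time": s,
            "crossed": crossed, "trait": c}))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "id", [f"r{seed}_{i}" for i in range(len(df))])
    cohort = SubjectCohort(
        df[["id", "arm", "time", "event", "offer_time", "crossed"]].copy(),
        meta={"scenario": scenario, "seed": seed,
              "truth": df["trait"].to_numpy()})
    return cohort.validate()


ESTIMATORS: dict[str, Callable] = {
    "PL": lambda cohort: fit_partial(cohort, on_fail="raise"),
    "FL": lambda cohort: fit_full(cohort, on_fail="warn"),
}


@dataclass
class ScenarioSummary:
    """Replicate-level results and the usual summary of one scenario."""

    scenario: SimScenario
    results: pd.DataFrame          # one row per replicate per estimator
    n_requested: int
    n_failed: int = 0
    unreliable: bool = False

    def table(self) -> pd.DataFrame:
        """Mean % bias, variance (raw and x100) and pi-hat summary."""
        truth = {"gamma": self.scenario.gamma, "omega": self.scenario.omega}
        rows = []
        for est, grp in self.results.groupby("estimator"):
            row = {"estimator": est, "n_reps": len(grp)}
            for par in ("gamma", "omega"):
                vals = grp[par].to_numpy(float)
                row[f"bias_pct_{par}"] = 100.0 * (vals.mean() / truth[par] - 1.0)
                row[f"var_{par}"] = float(np.var(vals, ddof=1))
                row[f"var100_{par}"] = 100.0 * row[f"var_{par}"]
            pis = grp["pi0"].to_numpy(float) * 100.0
            row["pi_mean_pct"] = float(pis.mean())
            row["pi_sd_pct"] = float(pis.std(ddof=1))
            rows.append(row)
        return pd.DataFrame(rows)


def run_scenarios(scenarios: Sequence[SimScenario], estimators: Sequence[str],
                  reps: int, base_seed: int,
                  progress: bool = False) -> list[ScenarioSummary]:
    """Run a grid of scenarios, fitting each estimator to each replicate.

    Replicate seeds are spawned deterministically from ``base_seed``;
    failed fits are logged and excluded (a summary with more than 10%
    failures is flagged unreliable).
    """
    out = []
    for si, scenario in enumerate(scenarios):
        rates = calibrate_rates(scenario)
        rows = []
        failed = 0
        seeds = np.random.SeedSequence(base_seed + si).generate_state(reps)
        for rep in range(reps):
            seed = int(seeds[rep] % (2 ** 31))
            cohort = simulate_trial(scenario, seed, rates)
            for est in estimators:
                try:
                    fit = ESTIMATORS[est](cohort)
                except Exception as exc:   # noqa: BLE001 - recorded, not hidden
                    failed += 1
                    logger.warning("replicate %d estimator %s failed: %s",
                                   rep, est, exc)
                    continue
                rows.append({"rep": rep, "seed": seed, "estimator": est,
                             "gamma": fit.params.gamma,
                             "omega": fit.params.omega,
                             "pi0": (fit.pi_baseline
                                     if np.isscalar(fit.pi_baseline)
                                     else float(np.mean(list(
                                         fit.pi_baseline.values()))))})
            if progress and (rep + 1) % 10 == 0:
                logger.info("scenario %d: %d/%d replicates done",
                            si + 1, rep + 1, reps)
        summary = ScenarioSummary(
            scenario=scenario, results=pd.DataFrame(rows),
            n_requested=reps * len(estimators), n_failed=failed,
            unreliable=failed > 0.1 * reps * len(estimators))
        out.append(summary)
    return out
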