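"""Packaged fixtures: the published count table and small demo cohorts.

``big198_counts`` is the two-period disease-free-survival count table
from the BIG 1-98 breast-cancer trial (letrozole vs tamoxifen, with the
tamoxifen arm unblinded after early results and ~25% crossing over).
Only aggregate counts are public; ``big198_cohort`` builds a synthetic
subject-level cohort whose two-period summary reproduces those margins
exactly, for end-to-end demonstrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import BinomialCounts, SubjectCohort
from .errors import CrossfxError

#: BIG 1-98 disease-free survival, two periods split at unblinding.
#: Counts: events y / at-risk n per period and arm; post-offer control
#: split by revealed crossover status (100 = did not cross, 101 = crossed).
BIG198_COUNTS = dict(
    y00=418, n00=2459,   # tamoxifen (control), before unblinding
    y01=352, n01=2463,   # letrozole (treatment), before unblinding
    y11=294, n11=2045,   # letrozole, after unblinding
    y100=251, n100=1356,  # tamoxifen, stayed
    y101=58, n101=619,    # tamoxifen, crossed over
)


def big198_counts() -> BinomialCounts:
    """The published two-period count table as a validated object."""
    return BinomialCounts(**BIG198_COUNTS).validate()


def big198_cohort() -> SubjectCohort:
    """Synthetic subject-level cohort matching the published margins.

    Individual records are not public; this cohort places events at
    nominal times (0.5 within period 0, 1.5 within period 1, censoring
    at 0.5 or 2.0) under a common offer time of 1, so that its
    two-period summary equals :func:`big198_counts` exactly.  It is a
    stand-in for demonstration and round-trip testing only.
    """
    c = big198_counts()
    rows = []

    def block(n, arm, t, event, crossed):
        for _ in range(n):
            rows.append((arm, t, event, crossed))

    # control arm: period-0 events and censorings, then revealed strata
    block(c.y00, 0, 0.5, 1, np.nan)
    block(c.d00, 0, 0.5, 0, np.nan)
    block(c.y100, 0, 1.5, 1, 0.0)
    block(c.n100 - c.y100, 0, 2.0, 0, 0.0)
    block(c.y101, 0, 1.5, 1, 1.0)
    block(c.n101 - c.y101, 0, 2.0, 0, 1.0)
    # treatment arm: stratum never revealed
    block(c.y01, 1, 0.5, 1, np.nan)
    block(c.d01, 1, 0.5, 0, np.nan)
    block(c.y11, 1, 1.5, 1, np.nan)
    block(c.n11 - c.y11, 1, 2.0, 0, np.nan)

    df = pd.DataFrame(rows, columns=["arm", "time", "event", "crossed"])
    df.insert(0, "id", [f"s{i:04d}" for i in range(len(df))])
    df["offer_time"] = 1.0
    df = df[["id", "arm", "time", "event", "offer_time", "crossed"]]
    return SubjectCohort(df, meta={"offer_rule": 1.0,
                                   "synthetic": True}).validate()


def toy_cohort() -> SubjectCohort:
    """A 20-subject hand-checkable cohort (offer at time 1)."""
    rng = np.random.default_rng(20)
    rows = []
    for i in range(20):
        arm = i % 2
        t = round(float(rng.uniform(0.2, 3.0)), 3)
        event = int(rng.uniform() < 0.7)
        crossed = np.nan
        if arm == 0 and t >= 1.0:
            crossed = float(rng.uniform() < 0.3)
        rows.append((f"t{i:02d}", arm, t, event, 1.0, crossed))
    df = pd.DataFrame(rows, columns=["id", "arm", "time", "event",
                                     "offer_time", "crossed"])
    return SubjectCohort(df, meta={"offer_rule": 1.0}).validate()


def make_fixture(name: str, path: str):
    """Write a named fixture to ``path``; returns the path written.

    Known names: ``big198_counts`` (JSON count table), ``toy_cohort``
    (20-row CSV) and ``scenario_<k>[:seed]`` (simulated cohort CSV for
    simulation scenario ``k`` in 1..8).
    """
    if name == "big198_counts":
        big198_counts().to_json(path)
    elif name == "toy_cohort":
        toy_cohort().to_csv(path)
    elif name.startswith("scenario_"):
        from .simulate import SimScenario, simulate_trial
        base, _, seed = name.partition(":")
        k = int(base.split("_")[1])
        scenario = SimScenario.preset(k)
        simulate_trial(scenario, seed=int(seed) if seed else 0).to_csv(path)
    else:
        raise CrossfxError(
            "unknown fixture name %r; known: big198_counts, toy_cohort, "
            "scenario_<k in 1..8>[:seed]" % name)
    return path
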