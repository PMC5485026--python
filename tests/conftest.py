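import numpy as np
import pandas as pd
import pytest

from crossfx import SubjectCohort, big198_counts


@pytest.fixture(scope="session")
def table1():
    """The packaged two-period count table."""
    return big198_counts()


def random_cohort(seed: int, n: int = 40, pi: float = 0.3,
                  cens: float = 0.3) -> SubjectCohort:
    """Small random cohort with strata revealed where observable."""
    rng = np.random.default_rng(seed)
    arm = rng.integers(0, 2, n)
    trait = (rng.uniform(size=n) < pi).astype(int)
    s = rng.uniform(0.8, 2.2, n)
    t = rng.exponential(1.2, n) + 0.05
    ev = (rng.uniform(size=n) > cens).astype(int)
    crossed = np.where((arm == 0) & (t >= s), trait.astype(float), np.nan)
    df = pd.DataFrame({"id": [f"s{seed}_{i}" for i in range(n)],
                       "arm": arm, "time": t, "event": ev,
                       "offer_time": s, "crossed": crossed})
    return SubjectCohort(df).validate()


@pytest.fixture()
def small_cohort():
    return random_cohort(11, n=60)
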