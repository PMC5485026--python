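"""Trial-data containers, ingestion and summarisation.

The package models trials in which one arm (the control) is offered a
switch to the experimental treatment part-way through follow-up.  Each
participant belongs to one of two latent strata: *insistors*, who would
cross over to treatment when offered if randomised to control, and
*ambivalents*, who would not.  The stratum is observable only in the
control arm, and only for participants still at risk when the offer
reaches them.

Two data shapes are supported:

``SubjectCohort``
    one row per participant (follow-up time, event indicator, arm,
    offer time, revealed crossover status, optional covariates and
    baseline-hazard stratum), used by the proportional-hazards
    estimators;

``BinomialCounts``
    a two-period event/at-risk table with the post-offer control rows
    split by revealed stratum, used by the binomial estimator.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, DegenerateDataError, SchemaError

logger = logging.getLogger(__name__)

#: canonical column order for the subject-level table
CANONICAL_COLUMNS = ["id", "arm", "time", "event", "offer_time", "crossed"]
OPTIONAL_COLUMNS = ["stratum", "group"]

#: strings accepted as a missing crossover status
MISSING_MARKERS = {"", "NA", "na", "NaN", "nan", "None"}


@dataclass
class SubjectCohort:
    """Ordered collection of trial participants.

    ``df`` holds one row per subject with canonical columns
    ``id, arm, time, event, offer_time, crossed`` (``crossed`` is NaN
    where the latent stratum is unobserved) plus optional ``stratum``
    (baseline-hazard group), ``group`` (stratum-independence group) and
    covariate columns listed in ``covariates``.
    """

    df: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SubjectCohort):
            return NotImplemented
        if self.covariates != other.covariates:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(x.astype(float), y.astype(float),
                                   equal_nan=True, rtol=0, atol=1e-12):
                    return False
            elif not (x.astype(str) == y.astype(str)).all():
                return False
        return True

    def arm(self, r: int) -> pd.DataFrame:
        return self.df[self.df["arm"] == r]

    def validate(self) -> "SubjectCohort":
        df = self.df
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].head(5).tolist()
            raise ConsistencyError(f"duplicate subject ids: {dups}")
        bad = df[(df["time"] <= 0) | (df["offer_time"] <= 0)]
        if len(bad):
            raise ConsistencyError(
                f"non-positive time/offer_time for ids {bad['id'].head(5).tolist()}")
        if not df["event"].isin([0, 1]).all():
            raise ConsistencyError("event indicator must be 0 or 1")
        if not df["arm"].isin([0, 1]).all():
            raise ConsistencyError("arm must be 0 (control) or 1 (treatment)")
        c = df["crossed"]
        known = c.notna()
        # no one in the treatment arm switches, so status is never revealed there
        offenders = df.loc[(df["arm"] == 1) & known, "id"]
        if len(offenders):
            raise ConsistencyError(
                "crossover status given for treatment-arm ids "
                f"{offenders.head(5).tolist()} (no switching from treatment)")
        pre = (df["arm"] == 0) & (df["time"] < df["offer_time"])
        offenders = df.loc[pre & known, "id"]
        if len(offenders):
            raise ConsistencyError(
                "crossover status given before the offer could be observed "
                f"for ids {offenders.head(5).tolist()}")
        post = (df["arm"] == 0) & (df["time"] >= df["offer_time"])
        offenders = df.loc[post & ~known, "id"]
        if len(offenders):
            raise ConsistencyError(
                "crossover status missing for post-offer control ids "
                f"{offenders.head(5).tolist()}")
        if not c[known].isin([0, 1]).all():
            raise ConsistencyError("crossed must be 0, 1 or missing")
        return self

    def to_csv(self, path_or_buf) -> None:
        cols = CANONICAL_COLUMNS + [c for c in OPTIONAL_COLUMNS
                                    if c in self.df.columns] + self.covariates
        self.df[cols].to_csv(path_or_buf, index=False)


def read_subject_table(source,
                       column_map: Mapping[str, str] | None = None,
                       offer: float | str = "column",
                       covariates: Sequence[str] = (),
                       ) -> SubjectCohort:
    """Read a delimited subject-level table into a validated cohort.

    Parameters
    ----------
    source
        Path, file object or string buffer holding CSV/TSV text with a
        header row.
    column_map
        Optional mapping from canonical names (``id``, ``arm``, ``time``,
        ``event``, ``offer_time``, ``crossed``, ``stratum``, ``group``)
        to the column names used in the file.
    offer
        ``"column"`` (default) to read per-subject offer times from the
        ``offer_time`` column, or a positive number to assign one
        calendar offer time to everybody.
    covariates
        Names of covariate columns to carry along.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python",
                     keep_default_na=False, dtype=str)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)

    mandatory = ["id", "arm", "time", "event"]
    if offer == "column":
        mandatory.append("offer_time")
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    out = pd.DataFrame()
    out["id"] = df["id"].astype(str)
    out["arm"] = pd.to_numeric(df["arm"]).astype(int)
    out["time"] = pd.to_numeric(df["time"]).astype(float)
    out["event"] = pd.to_numeric(df["event"]).astype(int)
    if offer == "column":
        out["offer_time"] = pd.to_numeric(df["offer_time"]).astype(float)
    else:
        out["offer_time"] = float(offer)
    if "crossed" in df.columns:
        raw = df["crossed"].astype(str).str.strip()
        missing = raw.isin(MISSING_MARKERS)
        vals = pd.to_numeric(raw.where(~missing), errors="raise")
        out["crossed"] = vals.astype(float)
    else:
        out["crossed"] = np.nan
    for col in OPTIONAL_COLUMNS:
        if col in df.columns:
            out[col] = df[col].astype(str)
    for col in covariates:
        if col not in df.columns:
            raise SchemaError(f"missing covariate column {col!r}")
        out[col] = pd.to_numeric(df[col]).astype(float)

    cohort = SubjectCohort(out, covariates=list(covariates),
                           meta={"offer_rule": offer}).validate()
    logger.info("read %d subjects (%d control, %d treatment)",
                len(cohort), len(cohort.arm(0)), len(cohort.arm(1)))
    return cohort


@dataclass
class BinomialCounts:
    """Two-period event/at-risk table with post-offer control split.

    Period 0 runs from randomisation to the offer of crossover, period 1
    from the offer to the end of follow-up.  ``y``/``n`` are events and
    numbers at risk at the period start; ``d0r`` is the number censored
    in period 0 in arm ``r``; the control-arm period-1 row is split by
    the revealed stratum (``*100`` ambivalent, ``*101`` insistor).
    """

    y00: int
    n00: int
    y01: int
    n01: int
    y11: int
    n11: int
    y100: int
    n100: int
    y101: int
    n101: int

    @property
    def n10(self) -> int:
        return self.n100 + self.n101

    @property
    def y10(self) -> int:
        return self.y100 + self.y101

    @property
    def d00(self) -> int:
        return self.n00 - self.y00 - self.n10

    @property
    def d01(self) -> int:
        return self.n01 - self.y01 - self.n11

    def validate(self) -> "BinomialCounts":
        vals = asdict(self)
        for k, v in vals.items():
            if v < 0 or int(v) != v:
                raise ConsistencyError(f"count {k}={v} must be a non-negative integer")
        pairs = [("y00", "n00"), ("y01", "n01"), ("y11", "n11"),
                 ("y100", "n100"), ("y101", "n101")]
        for yk, nk in pairs:
            if vals[yk] > vals[nk]:
                raise ConsistencyError(f"{yk}={vals[yk]} exceeds {nk}={vals[nk]}")
        if self.d00 < 0:
            raise ConsistencyError(
                "control period-1 risk set exceeds period-0 survivors")
        if self.d01 < 0:
            raise ConsistencyError(
                "treatment period-1 risk set exceeds period-0 survivors")
        return self

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source) -> "BinomialCounts":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(**{k: int(v) for k, v in doc.items()}).validate()


def summarize_to_binomial(cohort: SubjectCohort) -> BinomialCounts:
    """Collapse a subject-level cohort to the two-period count table.

    Period 0 is ``[0, s_i)`` and period 1 ``[s_i, t_i]`` on each
    subject's own offer time: an event or censoring strictly before the
    offer counts in period 0, anybody still under observation at the
    offer enters the period-1 risk set (an event exactly at the offer
    time is a period-1 event with stratum revealed).
    """
    df = cohort.df
    out = {}
    for r in (0, 1):
        sub = df[df["arm"] == r]
        pre = sub["time"] < sub["offer_time"]
        out[f"n0{r}"] = len(sub)
        out[f"y0{r}"] = int(((sub["event"] == 1) & pre).sum())
        post = sub[~pre]
        if r == 1:
            out["n11"] = len(post)
            out["y11"] = int((post["event"] == 1).sum())
        else:
            for k in (0, 1):
                grp = post[post["crossed"] == k]
                out[f"n10{k}"] = len(grp)
                out[f"y10{k}"] = int((grp["event"] == 1).sum())
    if out["n100"] + out["n101"] == 0 or out["n11"] == 0:
        raise DegenerateDataError("no subjects at risk after the offer in one arm")
    return BinomialCounts(
        y00=out["y00"], n00=out["n00"], y01=out["y01"], n01=out["n01"],
        y11=out["y11"], n11=out["n11"],
        y100=out["y100"], n100=out["n100"],
        y101=out["y101"], n101=out["n101"]).validate()


@dataclass
class AssumptionReport:
    """Advisory diagnostics for the censoring/stratum independence assumptions.

    The report never blocks fitting; sections are empty dictionaries
    when the data carry no information for them.
    """

    censoring: dict = field(default_factory=dict)
    covariate_balance: dict = field(default_factory=dict)
    entry_time: dict = field(default_factory=dict)

    @property
    def flags(self) -> list[str]:
        out = []
        if self.censoring.get("p_value", 1.0) < 0.05:
            out.append("censoring differs between revealed strata (p < 0.05)")
        for name, sec in self.covariate_balance.items():
            if sec.get("p_value", 1.0) < 0.05:
                out.append(f"covariate {name} imbalanced between revealed strata")
        if self.entry_time.get("p_value", 1.0) < 0.05:
            out.append("offer time associated with revealed stratum")
        return out


def check_assumptions(cohort: SubjectCohort) -> AssumptionReport:
    """Compare censoring, covariates and offer times across revealed strata.

    Uses post-offer control-arm subjects, the only place the latent
    stratum is observed: a chi-square test of post-offer censoring by
    stratum (censoring independent of strata), rank tests of covariate
    balance by stratum, and a Kolmogorov-Smirnov comparison of offer
    times by stratum.
    """
    report = AssumptionReport()
    df = cohort.df
    post = df[(df["arm"] == 0) & (df["time"] >= df["offer_time"])]
    if len(post) == 0 or post["crossed"].nunique() < 2:
        return report

    cens = (post["event"] == 0)
    table = pd.crosstab(post["crossed"], cens)
    if table.shape == (2, 2) and (table.values.sum(axis=1) > 0).all() \
            and (table.values.sum(axis=0) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table.values, correction=False)
        rates = post.groupby("crossed")["event"].apply(lambda e: float((e == 0).mean()))
        report.censoring = {"statistic": float(chi2), "p_value": float(p),
                            "censoring_rate": rates.to_dict()}

    for name in cohort.covariates:
        a = post.loc[post["crossed"] == 0, name].to_numpy(float)
        b = post.loc[post["crossed"] == 1, name].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        report.covariate_balance[name] = {
            "mean_ambivalent": float(a.mean()), "mean_insistor": float(b.mean()),
            "statistic": float(u), "p_value": float(p)}

    s0 = post.loc[post["crossed"] == 0, "offer_time"].to_numpy(float)
    s1 = post.loc[post["crossed"] == 1, "offer_time"].to_numpy(float)
    if len(np.unique(np.concatenate([s0, s1]))) > 1 and len(s0) and len(s1):
        ks, p = stats.ks_2samp(s0, s1)
        report.entry_time = {"statistic": float(ks), "p_value": float(p)}
    return report
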