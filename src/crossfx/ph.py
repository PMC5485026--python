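"""Proportional-hazards latent-strata estimators.

The hazard for subject ``i`` is ``lambda_0i(t) * psi(t)`` with

    psi = exp[ gamma * (r_i + I(t >= s_i) * (1 - r_i) * c_i)
               + omega * c_i + x_i . beta ]

so that treated subjects (``r=1``) carry the log treatment effect
``gamma`` throughout, control insistors (``r=0, c=1``) acquire it from
their crossover time ``s_i`` onward, and insistors differ from
ambivalents by the log insistor effect ``omega`` everywhere.

Two estimators are provided.  The *partial-likelihood* estimator
replaces unknown strata by the estimated proportion of insistors still
at risk, tracked through time by an iterative decrement rule on the
control arm (where strata are revealed at the offer) and mirrored in
the treatment arm.  The *full-likelihood* estimator adds a
nonparametric step baseline hazard whose increments are estimated by a
score recursion, and cycles (insistor proportion | theta) ->
(baseline | pi, theta) -> (theta | pi, baseline) until the full
log-likelihood converges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import SubjectCohort
from .errors import (ConvergenceError, CrossfxError, DegenerateDataError,
                     IdentifiabilityError)

logger = logging.getLogger(__name__)

TIE_TOL = 1e-12  # times closer than this are tied


@dataclass
class PHParams:
    """Log-scale parameters of the proportional-hazards model."""

    gamma: float
    omega: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def as_dict(self) -> dict:
        d = {"gamma": self.gamma, "omega": self.omega}
        for k, b in enumerate(np.atleast_1d(self.beta)):
            d[f"beta{k + 1}"] = float(b)
        return d


def psi(t: float, r: int, s: float, c: int, x: Sequence[float] | None,
        params: PHParams) -> float:
    """Hazard multiplier for a subject with known stratum ``c`` at time ``t``."""
    treated = r + (1 - r) * c * (1.0 if t >= s else 0.0)
    lin = params.gamma * treated + params.omega * c
    if x is not None and len(np.atleast_1d(params.beta)):
        lin += float(np.dot(np.atleast_1d(x), np.atleast_1d(params.beta)))
    return math.exp(lin)


# ---------------------------------------------------------------------------
# proportion of insistors at risk through time
# ---------------------------------------------------------------------------

@dataclass
class InsistorTrajectory:
    """Step-function estimate of the insistor proportion in the latent pool.

    Updates happen at ``t'_j = min(t_j, s_j)`` (control arm: event,
    censoring, or revelation at the offer; treatment arm: event or
    censoring, the stratum never being revealed).  ``e`` codes the
    update: 0 event with unknown stratum, 1 revealed ambivalent,
    2 revealed insistor, 3 censored with unknown stratum.  ``xi`` is the
    decrement applied to the running insistor count ``u_hat``;
    ``pi_hat`` the proportion among the ``n0 - j`` subjects not yet
    updated.
    """

    times: np.ndarray
    e: np.ndarray
    xi: np.ndarray
    u_hat: np.ndarray
    pi_hat: np.ndarray
    n0: int
    u0: float
    arm: int = 0
    clipped: bool = False
    # collapsed step function (one value per distinct update time)
    step_times: np.ndarray = field(default=None, repr=False)
    step_pi: np.ndarray = field(default=None, repr=False)

    @property
    def baseline_pi(self) -> float:
        return self.u0 / self.n0 if self.n0 else float("nan")

    def pi_at(self, t) -> np.ndarray:
        """Left-limit lookup: the proportion just before time ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.step_times, t - TIE_TOL, side="left") - 1
        out = np.where(idx >= 0, self.step_pi[np.clip(idx, 0, None)],
                       self.baseline_pi)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "e": self.e, "xi": self.xi,
                             "u_hat": self.u_hat, "pi_hat": self.pi_hat})


def _update_arrays(records: pd.DataFrame, observed: bool):
    """Sorted update times and classification codes for one arm."""
    t = records["time"].to_numpy(float)
    delta = records["event"].to_numpy(int)
    if observed:
        s = records["offer_time"].to_numpy(float)
        c = records["crossed"].to_numpy(float)
        tprime = np.minimum(t, s)
        e = np.where(s <= t, 1 + np.nan_to_num(c, nan=0.0),
                     np.where(delta == 1, 0, 3)).astype(int)
    else:
        tprime = t
        e = np.where(delta == 1, 0, 3).astype(int)
    order = np.argsort(tprime, kind="stable")
    return tprime[order], e[order]


def _run_trajectory(tprime, e, u: float, omega: float):
    """Sequential decrement recursion; returns per-update sequences."""
    n0 = len(tprime)
    w = math.exp(omega)
    xi = np.empty(n0)
    u_seq = np.empty(n0)
    pi_seq = np.empty(n0)
    u_run = float(u)
    clipped = False
    for j in range(n0):
        pool_prev = n0 - j
        pi_prev = u_run / pool_prev if pool_prev else 0.0
        ej = e[j]
        if ej == 0:
            d = (1.0 - pi_prev) + pi_prev * w
            x = pi_prev * w / d if d > 0 else pi_prev
        elif ej == 1:
            x = 0.0
        elif ej == 2:
            x = 1.0
        else:
            x = pi_prev
        u_run -= x
        pool = n0 - j - 1
        if u_run < 0.0 or u_run > pool:
            clipped = True
            u_run = min(max(u_run, 0.0), float(pool))
        xi[j] = x
        u_seq[j] = u_run
        pi_seq[j] = u_run / pool if pool else 0.0
    return xi, u_seq, pi_seq, clipped


def insistor_trajectory(records: pd.DataFrame, u: float, omega: float,
                        observed: bool = True, arm: int = 0
                        ) -> InsistorTrajectory:
    """Track the proportion of insistors at risk through one arm.

    ``records`` holds one row per subject (columns ``time``, ``event``
    and, for the observed control arm, ``offer_time`` and ``crossed``).
    ``u`` is the (possibly fractional) number of insistors at baseline,
    ``omega`` the log insistor effect.  With ``observed=False`` the arm
    is treated as never revealing strata: every event updates the pool
    with the unknown-stratum rule and every censoring leaves the
    proportion unchanged.

    Tied update times share one proportion: within a tied block the
    running count after the last member is reported for all of them.
    """
    n0 = len(records)
    if not 0.0 <= u <= n0:
        raise CrossfxError(f"u={u} outside [0, {n0}]")
    tprime, e = _update_arrays(records, observed)
    xi, u_seq, pi_seq, clipped = _run_trajectory(tprime, e, u, omega)
    if clipped:
        logger.debug("insistor count clipped into [0, pool] during tracking")
    # collapse ties: the last value at each distinct time stands for the block
    u_rep, pi_rep = u_seq.copy(), pi_seq.copy()
    step_times, last_idx = [], []
    j = 0
    while j < n0:
        k = j
        while k + 1 < n0 and tprime[k + 1] - tprime[j] <= TIE_TOL:
            k += 1
        u_rep[j:k + 1] = u_seq[k]
        pi_rep[j:k + 1] = pi_seq[k]
        step_times.append(tprime[k])
        last_idx.append(k)
        j = k + 1
    return InsistorTrajectory(
        times=tprime, e=e, xi=xi, u_hat=u_rep, pi_hat=pi_rep,
        n0=n0, u0=float(u), arm=arm, clipped=clipped,
        step_times=np.asarray(step_times),
        step_pi=pi_seq[np.asarray(last_idx, dtype=int)] if n0 else np.empty(0))


def insistor_count_loglik(records: pd.DataFrame, u: float, omega: float,
                          observed: bool = True) -> float:
    """Log-likelihood of the baseline insistor count ``u`` given ``omega``.

    Only updates where the stratum is revealed (codes 1 and 2)
    contribute: a Bernoulli term in the tracked proportion just before
    the update (before the first member of a tied block, so tied
    revelations share one proportion).
    """
    n0 = len(records)
    if not 0.0 <= u <= n0:
        raise CrossfxError(f"u={u} outside [0, {n0}]")
    tprime, e = _update_arrays(records, observed)
    _, _, pi_seq, _ = _run_trajectory(tprime, e, u, omega)
    # proportion just before update j (pool still includes subject j)
    pi_before = np.concatenate([[u / n0 if n0 else 0.0], pi_seq[:-1]])
    ll = 0.0
    block_start = 0
    for j in range(n0):
        if j > 0 and tprime[j] - tprime[block_start] > TIE_TOL:
            block_start = j
        if e[j] not in (1, 2):
            continue
        p = pi_before[block_start]
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        ll += math.log(p) if e[j] == 2 else math.log(1.0 - p)
    return ll


def fit_baseline_insistors(records: pd.DataFrame, omega: float,
                           observed: bool = True,
                           xatol: float = 1e-6) -> tuple[float, float]:
    """Maximum-likelihood baseline insistor count given the insistor effect.

    Maximises the revealed-update likelihood over continuous
    ``u`` in ``[0, n0]`` by bounded one-dimensional search and returns
    ``(u_hat, loglik)``.
    """
    tprime, e = _update_arrays(records, observed)
    if not np.isin(e, (1, 2)).any():
        raise IdentifiabilityError(
            "no revealed crossover updates: baseline insistor count "
            "is not identified")
    n0 = len(records)

    def negll(u):
        return -insistor_count_loglik(records, u, omega, observed)

    r = optimize.minimize_scalar(negll, bounds=(0.0, float(n0)),
                                 method="bounded",
                                 options={"xatol": xatol})
    # guard the boundaries, where the bounded search cannot land exactly
    cands = [(r.x, r.fun)]
    for u_edge in (0.0, float(n0)):
        cands.append((u_edge, negll(u_edge)))
    u_best, f_best = min(cands, key=lambda p: p[1])
    return float(u_best), -float(f_best)


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

def _cohort_arrays(cohort: SubjectCohort):
    df = cohort.df
    x = df[cohort.covariates].to_numpy(float) if cohort.covariates else None
    return (df["time"].to_numpy(float), df["event"].to_numpy(int),
            df["arm"].to_numpy(int), df["offer_time"].to_numpy(float),
            df["crossed"].to_numpy(float), x)


class _PLData:
    """Precomputed risk-set structure for fast partial-likelihood evaluation.

    The risk-set sum at each event time splits into four blocks whose
    membership does not depend on the parameters: treatment arm
    (stratum always unknown), control with the offer still ahead
    (unknown), and revealed control ambivalents/insistors.  Without
    covariates only the block counts are needed, so one likelihood
    evaluation is O(number of events).
    """

    def __init__(self, cohort: SubjectCohort, traj0: InsistorTrajectory,
                 traj1: InsistorTrajectory):
        t, delta, r, s, c, x = _cohort_arrays(cohort)
        ev = delta == 1
        te = t[ev]
        order = np.argsort(te, kind="stable")
        self.te = te[order]
        m = len(self.te)
        if m == 0:
            raise DegenerateDataError("no events in cohort")
        # risk-set block counts at each event time
        t1s = np.sort(t[r == 1])
        self.R1 = len(t1s) - np.searchsorted(t1s, self.te - TIE_TOL, "left")
        t0 = t[r == 0]
        s0 = s[r == 0]
        c0 = c[r == 0]
        t0s = np.sort(t0)
        R0 = len(t0s) - np.searchsorted(t0s, self.te - TIE_TOL, "left")
        rev = s0 <= t0
        counts = {}
        for k in (0, 1):
            mask = rev & (c0 == k)
            ss, ts = np.sort(s0[mask]), np.sort(t0[mask])
            n_srev = np.searchsorted(ss, self.te + TIE_TOL, "right")
            n_gone = np.searchsorted(ts, self.te - TIE_TOL, "left")
            counts[k] = n_srev - n_gone  # s_j <= te <= t_j
        self.A0 = counts[0]
        self.I0 = counts[1]
        self.R0u = R0 - self.A0 - self.I0
        self.pi0 = traj0.pi_at(self.te)
        self.pi1 = traj1.pi_at(self.te)
        # numerator class of each event subject
        re_, se, ce = r[ev][order], s[ev][order], c[ev][order]
        self.cls = np.where(re_ == 1, 0,
                            np.where(se > self.te, 1, 2 + np.nan_to_num(ce)))
        self.cls = self.cls.astype(int)
        if x is not None:
            self.x = x
            self.xe = x[ev][order]
            tt = self.te[:, None]
            at_risk = t[None, :] >= tt - TIE_TOL
            self.M1 = at_risk & (r == 1)[None, :]
            known = at_risk & (r == 0)[None, :] & (s[None, :] <= tt + TIE_TOL)
            self.M0u = at_risk & (r == 0)[None, :] & ~known
            self.Mamb = known & (c == 0)[None, :]
            self.Mins = known & (c == 1)[None, :]
        else:
            self.x = None

    def loglik(self, gamma: float, omega: float,
               beta: np.ndarray | None = None) -> float:
        eg, ew = math.exp(gamma), math.exp(omega)
        mix1 = 1.0 + self.pi1 * (ew - 1.0)
        mix0 = 1.0 + self.pi0 * (ew - 1.0)
        if self.x is None:
            S = eg * mix1 * self.R1 + mix0 * self.R0u + self.A0 \
                + eg * ew * self.I0
            num = np.choose(self.cls,
                            [eg * mix1, mix0,
                             np.ones_like(mix0), np.full_like(mix0, eg * ew)])
        else:
            w = np.exp(self.x @ np.atleast_1d(beta))
            S = (eg * mix1 * (self.M1 @ w) + mix0 * (self.M0u @ w)
                 + self.Mamb @ w + eg * ew * (self.Mins @ w))
            num = np.choose(self.cls,
                            [eg * mix1, mix0,
                             np.ones_like(mix0), np.full_like(mix0, eg * ew)])
            num = num * np.exp(self.xe @ np.atleast_1d(beta))
        if np.any(S <= 0) or np.any(num <= 0):
            return float("-inf")
        return float(np.sum(np.log(num) - np.log(S)))


def partial_loglik(params: PHParams, cohort: SubjectCohort,
                   traj0: InsistorTrajectory,
                   traj1: InsistorTrajectory) -> float:
    """Cox-type partial log-likelihood with latent-strata mixture weights.

    Each event contributes the log-ratio of its hazard multiplier to
    the risk-set sum; subjects whose stratum is unknown at the event
    time enter through the mixture weighted by the tracked insistor
    proportion ``pi(t|arm)``.
    """
    data = _PLData(cohort, traj0, traj1)
    return data.loglik(params.gamma, params.omega, params.beta)


@dataclass
class PHFit:
    """Result of a proportional-hazards latent-strata fit."""

    params: PHParams
    loglik: float
    method: str
    converged: bool
    u0: float | dict
    pi_baseline: float | dict
    trajectories: dict = field(default_factory=dict)
    baselines: dict | None = None
    history: list = field(default_factory=list)
    pi_subject: np.ndarray | None = None
    start_loglik: float = float("nan")

    def summary(self) -> dict:
        d = {"method": self.method, "loglik": self.loglik,
             "converged": self.converged,
             "estimates_log": self.params.as_dict(),
             "estimates_exp": {k: math.exp(v)
                               for k, v in self.params.as_dict().items()},
             "pi_baseline": self.pi_baseline}
        return d


def _nm_maximize(fun: Callable, z0: np.ndarray, fatol: float = 1e-10):
    neg = lambda z: -fun(z)
    r = optimize.minimize(neg, z0, method="Nelder-Mead",
                          options=dict(xatol=1e-8, fatol=fatol,
                                       maxiter=5000, maxfev=5000))
    r2 = optimize.minimize(neg, r.x, method="Nelder-Mead",
                           options=dict(xatol=1e-8, fatol=fatol,
                                        maxiter=5000, maxfev=5000))
    return (r2.x, -r2.fun) if r2.fun <= r.fun else (r.x, -r.fun)


def fit_partial(cohort: SubjectCohort, tol: float = 1e-8,
                max_outer: int = 100, fixed: Mapping[str, float] | None = None,
                on_fail: str = "raise") -> PHFit:
    """Partial-likelihood estimator of (gamma, omega, beta).

    Alternates (i) given ``omega``: estimate the baseline insistor
    count on the control arm, rebuild the at-risk insistor trajectories
    in both arms (the treatment arm starts from the same baseline
    proportion, by randomisation); (ii) given the trajectories:
    maximise the partial likelihood by simplex search; until the
    partial log-likelihood changes by less than ``tol``.
    """
    fixed = dict(fixed or {})
    cohort.validate()
    arm0 = cohort.arm(0)
    arm1 = cohort.arm(1)
    if len(arm0) == 0 or len(arm1) == 0:
        raise DegenerateDataError("both arms are required")
    m = len(cohort.covariates)
    names = [n for n in (["gamma", "omega"] +
                         [f"beta{k + 1}" for k in range(m)])
             if n not in fixed]

    state = {"gamma": fixed.get("gamma", 0.0), "omega": fixed.get("omega", 0.0)}
    for k in range(m):
        state.setdefault(f"beta{k + 1}", fixed.get(f"beta{k + 1}", 0.0))
    prev = float("-inf")
    history = []
    converged = False
    traj0 = traj1 = None
    u0 = 0.0
    for it in range(max_outer):
        u0, _ = fit_baseline_insistors(arm0, state["omega"])
        traj0 = insistor_trajectory(arm0, u0, state["omega"], arm=0)
        u1 = u0 / len(arm0) * len(arm1)
        traj1 = insistor_trajectory(arm1, u1, state["omega"],
                                    observed=False, arm=1)
        data = _PLData(cohort, traj0, traj1)

        def fun(z):
            vals = dict(zip(names, z))
            vals.update(fixed)
            beta = np.array([vals.get(f"beta{k + 1}", state[f"beta{k + 1}"])
                             for k in range(m)])
            return data.loglik(vals.get("gamma", state["gamma"]),
                               vals.get("omega", state["omega"]), beta)

        z0 = np.array([state[n] for n in names])
        z, pl = _nm_maximize(fun, z0)
        state.update(dict(zip(names, z)))
        history.append({"iter": it, "pl": pl, "u0": u0, **dict(state)})
        if abs(pl - prev) < tol:
            converged = True
            prev = pl
            break
        prev = pl
    if not converged:
        if on_fail == "raise":
            raise ConvergenceError(
                f"partial-likelihood outer loop did not converge in "
                f"{max_outer} iterations", history=history)
        logger.warning("partial-likelihood fit not converged")
    params = PHParams(gamma=state["gamma"], omega=state["omega"],
                      beta=np.array([state[f"beta{k + 1}"]
                                     for k in range(m)]))
    return PHFit(params=params, loglik=prev, method="partial",
                 converged=converged, u0=u0,
                 pi_baseline=u0 / len(arm0),
                 trajectories={0: traj0, 1: traj1}, history=history)


# ---------------------------------------------------------------------------
# baseline hazard and full likelihood
# ---------------------------------------------------------------------------

@dataclass
class BaselineHazard:
    """Nonparametric step baseline hazard for one baseline-hazard group.

    ``times`` are the distinct event times (ascending), ``w`` their tie
    multiplicities and ``delta`` the estimated jumps; the cumulative
    hazard is the right-continuous step function with those jumps.
    """

    times: np.ndarray
    delta: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self._cum = np.cumsum(self.delta)

    def cumhaz(self, t) -> np.ndarray:
        if len(self.times) == 0:
            return np.zeros_like(np.asarray(t, float))
        idx = np.searchsorted(self.times, np.asarray(t, float) + TIE_TOL,
                              "left") - 1
        return np.where(idx >= 0, self._cum[np.clip(idx, 0, None)], 0.0)

    def cumhaz_before(self, t) -> np.ndarray:
        """Cumulative hazard strictly before ``t`` (left limit)."""
        if len(self.times) == 0:
            return np.zeros_like(np.asarray(t, float))
        idx = np.searchsorted(self.times, np.asarray(t, float) - TIE_TOL,
                              "left") - 1
        return np.where(idx >= 0, self._cum[np.clip(idx, 0, None)], 0.0)

    def delta_at(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        idx = np.searchsorted(self.times, t - TIE_TOL, "left")
        idx_c = np.clip(idx, 0, len(self.times) - 1)
        ok = np.abs(self.times[idx_c] - t) <= TIE_TOL
        if not np.all(ok):
            raise CrossfxError("no baseline-hazard jump at an event time")
        return self.delta[idx_c]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "delta": self.delta,
                             "cumhaz": self._cum})


class _StratumData:
    """Per-stratum arrays for the full likelihood and the score recursion."""

    def __init__(self, df: pd.DataFrame, covariates: list[str]):
        self.t = df["time"].to_numpy(float)
        self.delta = df["event"].to_numpy(int)
        self.r = df["arm"].to_numpy(int)
        self.s = df["offer_time"].to_numpy(float)
        self.c = df["crossed"].to_numpy(float)
        self.x = df[covariates].to_numpy(float) if covariates else None
        self.revealed = (self.r == 0) & (self.s <= self.t)
        te = np.sort(self.t[self.delta == 1])
        taus, w = [], []
        for v in te:
            if taus and v - taus[-1] <= TIE_TOL:
                w[-1] += 1
            else:
                taus.append(v)
                w.append(1)
        self.taus = np.asarray(taus)
        self.w = np.asarray(w, dtype=float)
        m = len(taus)
        if m:
            # gap index of each subject's exit / crossover for the recursion
            self.gap_of_t = np.searchsorted(self.taus, self.t + TIE_TOL) - 1
            self.gap_of_s = np.searchsorted(self.taus, self.s + TIE_TOL) - 1
        # event-time index for likelihood evaluation
        self.ev_idx = None
        if m:
            idx = np.searchsorted(self.taus, self.t - TIE_TOL)
            idx_c = np.clip(idx, 0, m - 1)
            self.t_on_tau = np.abs(self.taus[idx_c] - self.t) <= TIE_TOL
            self.ev_idx = idx_c

    def multipliers(self, params: PHParams):
        """Per-subject hazard multipliers by latent class and regime."""
        g, om = params.gamma, params.omega
        xb = (self.x @ np.atleast_1d(params.beta)
              if self.x is not None and len(np.atleast_1d(params.beta))
              else np.zeros(len(self.t)))
        base = np.exp(xb)
        r = self.r
        # unknown-status multipliers: treatment carries gamma throughout,
        # control pre-offer carries none
        psi1 = np.exp(g * r + om) * base
        psi0 = np.exp(g * r) * base
        # control-arm regime multipliers for revealed subjects
        pre1 = np.exp(om) * base
        pre0 = base
        post1 = np.exp(g + om) * base
        post0 = base
        return psi0, psi1, pre0, pre1, post0, post1


def _score_rho_unknown(pi_j, psi0, psi1, delta, lam):
    # survivor factors normalised by the larger one to avoid underflow
    shift = -min(psi0, psi1) * lam
    e1 = math.exp(-psi1 * lam - shift)
    e0 = math.exp(-psi0 * lam - shift)
    if delta:
        num = pi_j * psi1 * psi1 * e1 + (1 - pi_j) * psi0 * psi0 * e0
        den = pi_j * psi1 * e1 + (1 - pi_j) * psi0 * e0
    else:
        num = pi_j * psi1 * e1 + (1 - pi_j) * psi0 * e0
        den = pi_j * e1 + (1 - pi_j) * e0
    return num / den if den > 0 else min(psi0, psi1)


def _score_rho_prestar(pi_j, pre0, pre1, lam_s):
    shift = -min(pre0, pre1) * lam_s
    f1 = math.exp(-pre1 * lam_s - shift)
    f0 = math.exp(-pre0 * lam_s - shift)
    den = pi_j * f1 + (1 - pi_j) * f0
    if den <= 0:
        return min(pre0, pre1)
    return (pi_j * pre1 * f1 + (1 - pi_j) * pre0 * f0) / den


def fit_baseline_hazard(params: PHParams, pi, cohort: SubjectCohort,
                        max_expand: int = 5) -> dict:
    """Estimate the step baseline hazard(s) given theta and pi.

    For each baseline-hazard group the score equations in the jumps
    reduce, by telescoping differences between consecutive event times
    (with correction terms for censorings and control-arm crossovers
    falling in the gap), to a recursion driven by the first jump; the
    remaining one-dimensional score root is found by bracketed
    bisection (bracket ``[1e-12, 1e3 / max psi]``, geometrically
    expanded up to ``max_expand`` times) and the recursion unrolled.

    Returns a dict mapping stratum label -> :class:`BaselineHazard`.
    """
    cohort.validate()
    df = cohort.df
    pi = np.broadcast_to(np.asarray(pi, float), (len(df),))
    labels = df["stratum"] if "stratum" in df.columns \
        else pd.Series(["_all"] * len(df), index=df.index)
    out = {}
    for lab in labels.unique():
        mask = (labels == lab).to_numpy()
        sd = _StratumData(df[mask], cohort.covariates)
        if len(sd.taus) == 0:
            raise DegenerateDataError(
                f"baseline-hazard group {lab!r} has no events")
        out[lab] = _fit_baseline_one(params, pi[mask], sd, max_expand)
    return out


def _recursion(sd: _StratumData, mult, pi, delta1: float):
    """Unroll the score recursion from the first jump.

    Returns ``(deltas, G_last)`` or ``(None, -inf)`` when the candidate
    first jump makes some jump non-positive (infeasible).
    """
    psi0, psi1, pre0, pre1, post0, post1 = mult
    taus, w = sd.taus, sd.w
    m = len(taus)
    t, s, dlt, rev, c = sd.t, sd.s, sd.delta, sd.revealed, sd.c
    gap_t, gap_s = sd.gap_of_t, sd.gap_of_s

    # subjects grouped by the gap in which they exit / cross over
    exits = [[] for _ in range(m)]
    crossers = [[] for _ in range(m)]
    for j in range(len(t)):
        gi = gap_t[j]
        if gi >= 0:
            exits[gi].append(j)
        if rev[j] and gap_s[j] >= 0:
            gi_s = gap_s[j]
            # stays at risk past the end of the crossover gap
            if gi_s < m - 1 and gap_t[j] > gi_s:
                crossers[gi_s].append(j)

    deltas = np.empty(m)
    deltas[0] = delta1
    cum = 0.0
    G = None
    for i in range(m):
        di = deltas[i]
        if not (di > 0) or not math.isfinite(di):
            return None, float("-inf")
        cum += di
        D = 0.0
        for j in exits[i]:
            if rev[j]:
                if s[j] <= taus[i] + TIE_TOL:
                    D += post1[j] if c[j] == 1 else post0[j]
                else:
                    D += _score_rho_prestar(pi[j], pre0[j], pre1[j], cum)
            else:
                D += _score_rho_unknown(pi[j], psi0[j], psi1[j],
                                        dlt[j], cum)
        if i < m - 1:
            for j in crossers[i]:
                rho2 = _score_rho_prestar(pi[j], pre0[j], pre1[j], cum)
                rho1 = post1[j] if c[j] == 1 else post0[j]
                D += rho2 - rho1
            denom = w[i] / di - D
            if denom <= 0 or not math.isfinite(denom):
                return None, float("-inf")
            deltas[i + 1] = w[i + 1] / denom
        else:
            G = w[i] / di - D
    return deltas, G


def _fit_baseline_one(params: PHParams, pi, sd: _StratumData,
                      max_expand: int) -> BaselineHazard:
    mult = sd.multipliers(params)
    max_psi = max(float(np.max(m)) for m in mult)

    def G_of(d1):
        _, g = _recursion(sd, mult, pi, d1)
        return g

    lo, hi = 1e-12, 1e3 / max_psi
    f_lo = G_of(lo)
    for _ in range(max_expand):
        if f_lo > 0:
            break
        lo /= 10.0
        f_lo = G_of(lo)
    f_hi = G_of(hi)
    for _ in range(max_expand):
        if not (f_hi > 0):
            break
        hi *= 10.0
        f_hi = G_of(hi)
    if not (f_lo > 0) or f_hi > 0:
        raise ConvergenceError(
            "baseline-hazard score has no sign change in the expanded "
            f"bracket [{lo:g}, {hi:g}] (G(lo)={f_lo:g}, G(hi)={f_hi:g})")
    # bisect on the score sign (infeasible points count as negative) until
    # both ends are finite, then hand over to Brent for fast refinement
    f_hi = G_of(hi)
    for _ in range(200):
        if math.isfinite(f_hi):
            break
        mid = math.sqrt(lo * hi) if hi / lo > 10 else 0.5 * (lo + hi)
        f_mid = G_of(mid)
        if f_mid > 0:
            lo = mid
        else:
            hi, f_hi = mid, f_mid
    if math.isfinite(f_hi) and hi > lo:
        d1 = float(optimize.brentq(G_of, lo, hi, xtol=1e-14, rtol=1e-12))
    else:  # pragma: no cover - pathological score surface
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if G_of(mid) > 0:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-10 * max(1.0, lo):
                break
        d1 = 0.5 * (lo + hi)
    deltas, _ = _recursion(sd, mult, pi, d1)
    if deltas is None or np.any(deltas <= 0):
        raise ConvergenceError("baseline-hazard recursion produced "
                               "non-positive jumps at the root")
    return BaselineHazard(times=sd.taus, delta=deltas, w=sd.w)


def full_loglik(params: PHParams, baselines: Mapping | BaselineHazard,
                pi, cohort: SubjectCohort) -> float:
    """Full log-likelihood given a step baseline hazard and baseline pi.

    Subjects with unknown stratum contribute the two-component mixture
    of their conditional likelihoods; control-arm subjects observed
    past the offer contribute the product of the marginal survivor
    function to just before the offer and the conditional
    hazard/survivor piece from the offer onward with the revealed
    stratum.
    """
    cohort.validate()
    df = cohort.df
    pi = np.broadcast_to(np.asarray(pi, float), (len(df),))
    if isinstance(baselines, BaselineHazard):
        baselines = {"_all": baselines}
        labels = pd.Series(["_all"] * len(df), index=df.index)
    else:
        labels = df["stratum"] if "stratum" in df.columns \
            else pd.Series(["_all"] * len(df), index=df.index)
    total = 0.0
    for lab, bh in baselines.items():
        mask = (labels == lab).to_numpy()
        if not mask.any():
            continue
        sd = _StratumData(df[mask], cohort.covariates)
        total += _full_loglik_one(params, bh, pi[mask], sd)
    return total


def _baseline_cache(sd: _StratumData, bh: BaselineHazard):
    """Baseline-dependent per-subject arrays, reusable across theta."""
    lam_t = bh.cumhaz(sd.t)
    lam_s = bh.cumhaz_before(sd.s)
    dlt = sd.delta.astype(bool)
    log_d = np.zeros(len(sd.t))
    if dlt.any():
        log_d[dlt] = np.log(bh.delta_at(sd.t[dlt]))
    return lam_t, lam_s, log_d


def _full_loglik_one(params: PHParams, bh: BaselineHazard, pi,
                     sd: _StratumData, cache=None) -> float:
    psi0, psi1, pre0, pre1, post0, post1 = sd.multipliers(params)
    lam_t, lam_s, log_d = cache if cache is not None \
        else _baseline_cache(sd, bh)
    rev = sd.revealed
    unk = ~rev
    ll = 0.0
    # unknown stratum: mixture of conditional likelihoods
    if unk.any():
        l1 = sd.delta[unk] * (log_d[unk] + np.log(psi1[unk])) \
            - psi1[unk] * lam_t[unk]
        l0 = sd.delta[unk] * (log_d[unk] + np.log(psi0[unk])) \
            - psi0[unk] * lam_t[unk]
        hi = np.maximum(l1, l0)
        ll += float(np.sum(hi + np.log(pi[unk] * np.exp(l1 - hi)
                                       + (1 - pi[unk]) * np.exp(l0 - hi))))
    # revealed: marginal survivor to the offer, conditional piece after
    if rev.any():
        astar = pi[rev] * np.exp(-pre1[rev] * lam_s[rev]) \
            + (1 - pi[rev]) * np.exp(-pre0[rev] * lam_s[rev])
        post = np.where(sd.c[rev] == 1, post1[rev], post0[rev])
        gap = lam_t[rev] - lam_s[rev]
        ll += float(np.sum(np.log(astar)
                           + sd.delta[rev] * (log_d[rev] + np.log(post))
                           - post * gap))
    return ll


def fit_full(cohort: SubjectCohort, tol: float = 1e-8, max_outer: int = 200,
             fixed: Mapping[str, float] | None = None,
             fixed_pi: float | None = None,
             start: PHFit | None = None, on_fail: str = "warn") -> PHFit:
    """Full-likelihood estimator with nonparametric step baseline hazard.

    Starts from the partial-likelihood solution and cycles: estimate
    each subject's baseline insistor probability given theta (per
    independence group, from the control-arm revealed updates); fit the
    baseline hazard per stratum given pi and theta; re-fit theta by
    simplex search on the full log-likelihood; until the full
    log-likelihood changes by less than ``tol``.
    """
    fixed = dict(fixed or {})
    cohort.validate()
    df = cohort.df
    if start is None:
        start = fit_partial(cohort, fixed=fixed, on_fail="warn")
    m = len(cohort.covariates)
    state = start.params.as_dict()
    state.update(fixed)
    names = [n for n in (["gamma", "omega"] +
                         [f"beta{k + 1}" for k in range(m)]) if n not in fixed]
    groups = df["group"] if "group" in df.columns \
        else pd.Series(["_all"] * len(df), index=df.index)
    labels = df["stratum"] if "stratum" in df.columns \
        else pd.Series(["_all"] * len(df), index=df.index)
    strata = {lab: ((labels == lab).to_numpy(),
                    _StratumData(df[(labels == lab).to_numpy()],
                                 cohort.covariates))
              for lab in labels.unique()}
    arm0_by_group = {g: df[(groups == g).to_numpy()
                           & (df["arm"] == 0).to_numpy()]
                     for g in groups.unique()}

    prev = float("-inf")
    history = []
    converged = False
    baselines = None
    pi_sub = np.full(len(df), np.nan)
    u_by_group, pi_by_group = {}, {}
    for it in range(max_outer):
        for g, arm0 in arm0_by_group.items():
            if fixed_pi is not None:
                u_g = fixed_pi * len(arm0)
            else:
                u_g, _ = fit_baseline_insistors(arm0, state["omega"])
            u_by_group[g] = u_g
            pi_by_group[g] = u_g / len(arm0)
            pi_sub[(groups == g).to_numpy()] = pi_by_group[g]
        params = PHParams(state["gamma"], state["omega"],
                          np.array([state[f"beta{k + 1}"] for k in range(m)]))
        baselines, caches = {}, {}
        for lab, (mask, sd) in strata.items():
            if len(sd.taus) == 0:
                raise DegenerateDataError(
                    f"baseline-hazard group {lab!r} has no events")
            baselines[lab] = _fit_baseline_one(params, pi_sub[mask], sd, 5)
            caches[lab] = _baseline_cache(sd, baselines[lab])

        def fun(z):
            vals = dict(zip(names, z))
            vals.update(fixed)
            p = PHParams(vals.get("gamma", state["gamma"]),
                         vals.get("omega", state["omega"]),
                         np.array([vals.get(f"beta{k + 1}",
                                            state[f"beta{k + 1}"])
                                   for k in range(m)]))
            return sum(_full_loglik_one(p, baselines[lab], pi_sub[mask],
                                        sd, caches[lab])
                       for lab, (mask, sd) in strata.items())

        z0 = np.array([state[n] for n in names])
        if it == 0:
            start_loglik = fun(z0)
            best = None
        z, ll = _nm_maximize(fun, z0)
        state.update(dict(zip(names, z)))
        history.append({"iter": it, "loglik": ll, **{g: u_by_group[g]
                                                     for g in u_by_group}})
        if best is None or ll > best["loglik"]:
            best = {"loglik": ll, "state": dict(state),
                    "pi_sub": pi_sub.copy(), "baselines": dict(baselines),
                    "u": dict(u_by_group), "pi": dict(pi_by_group)}
        if ll < prev - 0.05:
            logger.warning("full log-likelihood decreased by %g at outer "
                           "iteration %d", prev - ll, it)
        elif ll < prev - tol:
            # small dips are expected: the insistor-proportion step is an
            # external estimator, not a likelihood ascent step
            logger.debug("full log-likelihood dipped by %g at outer "
                         "iteration %d", prev - ll, it)
        if abs(ll - prev) < tol:
            converged = True
            prev = ll
            break
        prev = ll
    if not converged:
        msg = f"full-likelihood outer loop did not converge in {max_outer} iterations"
        if on_fail == "raise":
            raise ConvergenceError(msg, history=history)
        logger.warning(msg)
    # the cycle is not exactly monotone (the pi step is an external
    # estimator): report the iterate with the highest full likelihood
    state, pi_sub = best["state"], best["pi_sub"]
    baselines, u_by_group, pi_by_group = best["baselines"], best["u"], best["pi"]
    params = PHParams(state["gamma"], state["omega"],
                      np.array([state[f"beta{k + 1}"] for k in range(m)]))
    single = len(pi_by_group) == 1
    return PHFit(params=params, loglik=best["loglik"], method="full",
                 converged=converged,
                 u0=next(iter(u_by_group.values())) if single else u_by_group,
                 pi_baseline=(next(iter(pi_by_group.values())) if single
                              else pi_by_group),
                 trajectories=start.trajectories, baselines=baselines,
                 history=history, pi_subject=pi_sub,
                 start_loglik=start_loglik)


def profile_ci_ph(cohort: SubjectCohort, param: str = "gamma",
                  level: float = 0.95, fit: PHFit | None = None,
                  rel_tol: float = 1e-3) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one log-scale parameter.

    Profiles the full log-likelihood over ``param`` (re-running the
    full-likelihood cycle with it held fixed), finds where twice the
    drop equals the chi-square(1) quantile by geometric bracketing and
    bisection.  Returned on the log scale.
    """
    if fit is None:
        fit = fit_full(cohort)
    mle = fit.params.as_dict()[param]
    cutoff = fit.loglik - stats.chi2(1).ppf(level) / 2.0

    def drop(v):
        f = fit_full(cohort, fixed={param: v}, start=fit, on_fail="warn")
        return f.loglik - cutoff

    def solve(direction):
        step = 0.25
        inner, outer = mle, mle
        for k in range(30):
            outer = outer + direction * step * (1.5 ** k)
            if drop(outer) < 0:
                break
            inner = outer
        else:
            return direction * float("inf")
        lo, hi = inner, outer
        while abs(hi - lo) > rel_tol * max(1.0, abs(mle)):
            mid = 0.5 * (lo + hi)
            if drop(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    return (solve(-1), solve(+1))
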