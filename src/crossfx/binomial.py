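"""Two-period binomial latent-strata model of selective crossover.

The trial is collapsed to two periods split at the offer of crossover.
Within period ``t`` (0 before, 1 after the offer), arm ``r`` (0 control,
1 treatment) and latent stratum ``k`` (0 ambivalent, 1 insistor) the
event probability is parameterised as::

    p_t00 = alpha_t                (control ambivalent)
    p_t10 = gamma_t * alpha_t      (treated ambivalent)
    p_t11 = omega_t * gamma_t * alpha_t
    p_001 = omega_0 * alpha_0      (control insistor, pre-offer)
    p_101 = gamma1_star * omega_1 * alpha_1   (insistor who crossed over)

``gamma_t`` is the efficacy of treatment among ambivalents, ``omega_t``
the multiplicative insistor effect, and ``gamma1_star`` the effect of
treatment on insistors after they cross over (tied to ``gamma_1`` in the
primary model).  Mixture cells use the insistor probability at the start
of the period: ``pi`` at baseline in both arms (randomisation), and the
derived ``pi11`` among treatment-arm subjects still at risk at the
offer.

The proportion of insistors at baseline is identified by the revealed
insistor count in the control arm at the offer: the expected count
subtracts the expected insistor share of events and censorings from the
insistors enrolled, and equating it to the observed count expresses
``pi`` in terms of the other parameters, which are then estimated by
maximising the product of binomial likelihoods over the five observed
cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .data import BinomialCounts
from .errors import ConvergenceError, DegenerateDataError, CrossfxError

logger = logging.getLogger(__name__)


#: named model variants -> restriction flags
VARIANTS = {
    "common": dict(common_gamma=True, common_omega=True, tie_gamma1_star=True),
    "by-period": dict(common_gamma=False, common_omega=True, tie_gamma1_star=True),
    "free-gamma1star": dict(common_gamma=False, common_omega=True,
                            tie_gamma1_star=False),
}


@dataclass
class BinomialParams:
    """Parameter set of the binomial latent-strata model.

    Per-period values are always populated; the restriction flags record
    which of them are tied.  ``pi`` is the baseline insistor
    probability; it is profiled out of the likelihood (solved from the
    observed insistor count at the offer) rather than free.
    """

    alpha0: float
    alpha1: float
    omega0: float
    omega1: float
    gamma0: float
    gamma1: float
    gamma1_star: float
    pi: float = float("nan")
    common_gamma: bool = True
    common_omega: bool = True
    tie_gamma1_star: bool = True
    constant_rate: bool = False
    period_lengths: tuple[float, float] | None = None

    @property
    def n_free(self) -> int:
        n = 4  # alpha0, alpha1, omega, gamma (pi is profiled)
        if self.constant_rate:
            n -= 1
        if not self.common_gamma:
            n += 1
        if not self.common_omega:
            n += 1
        if not self.tie_gamma1_star:
            n += 1
        return n

    def cell_probabilities(self, pi11: float) -> dict[str, float]:
        m0 = 1.0 - self.pi + self.pi * self.omega0
        m1 = 1.0 - pi11 + pi11 * self.omega1
        return {
            "p00": self.alpha0 * m0,
            "p01": self.gamma0 * self.alpha0 * m0,
            "p100": self.alpha1,
            "p101": self.gamma1_star * self.omega1 * self.alpha1,
            "p11": self.gamma1 * self.alpha1 * m1,
        }


def make_params(variant: str | dict = "common", **values) -> BinomialParams:
    """Build a :class:`BinomialParams` from a variant name and raw values.

    ``values`` may use the tied names (``omega``, ``gamma``) or the
    per-period names; tied flags propagate the shared value.
    """
    flags = dict(VARIANTS[variant]) if isinstance(variant, str) else dict(variant)
    omega = values.pop("omega", None)
    gamma = values.pop("gamma", None)
    v = dict(values)
    if omega is not None:
        v.setdefault("omega0", omega)
        v.setdefault("omega1", omega)
    if gamma is not None:
        v.setdefault("gamma0", gamma)
        v.setdefault("gamma1", gamma)
    if flags.get("common_omega", True):
        v["omega1"] = v.get("omega0", v.get("omega1"))
    if flags.get("common_gamma", True):
        v["gamma1"] = v.get("gamma0", v.get("gamma1"))
    if flags.get("tie_gamma1_star", True):
        v["gamma1_star"] = v["gamma1"]
    return BinomialParams(
        alpha0=v["alpha0"], alpha1=v["alpha1"],
        omega0=v["omega0"], omega1=v["omega1"],
        gamma0=v["gamma0"], gamma1=v["gamma1"],
        gamma1_star=v["gamma1_star"], pi=v.get("pi", float("nan")),
        **{k: flags[k] for k in ("common_gamma", "common_omega",
                                 "tie_gamma1_star") if k in flags},
        constant_rate=flags.get("constant_rate", False),
        period_lengths=flags.get("period_lengths"))


def expected_insistors(params: BinomialParams, counts: BinomialCounts,
                       arm: int) -> float:
    """Expected number of insistors still at risk at the offer, by arm.

    Subtracts the expected insistor share of events and (by the
    stratum-independent-censoring assumption) of censorings from the
    expected insistors enrolled.  For the control arm this is the
    quantity matched to the observed revealed count; for the treatment
    arm it yields the derived probability ``pi11``.
    """
    pi = params.pi
    if arm == 0:
        n, d = counts.n00, counts.d00
        if n == 0:
            raise DegenerateDataError("no control subjects enrolled")
        event_rate_ins = params.alpha0 * params.omega0
    else:
        n, d = counts.n01, counts.d01
        if n == 0:
            raise DegenerateDataError("no treatment subjects enrolled")
        event_rate_ins = params.gamma0 * params.alpha0 * params.omega0
    # E(N_1r1) = pi*n - E(Y_0r) * P(insistor | event) - d * pi
    #          = pi * (n * (1 - alpha_eff * omega-path) - d)
    return pi * (n * (1.0 - event_rate_ins) - d)


def pi11_from(params: BinomialParams, counts: BinomialCounts) -> float:
    """Derived insistor probability in treatment after the offer, clipped to [0, 1]."""
    if counts.n11 == 0:
        raise DegenerateDataError("no treatment subjects at risk after the offer")
    raw = expected_insistors(params, counts, arm=1) / counts.n11
    if raw < 0.0 or raw > 1.0:
        logger.debug("pi11=%g clipped into [0, 1]", raw)
    return min(1.0, max(0.0, raw))


def profile_pi(params: BinomialParams, counts: BinomialCounts,
               rule: str = "observed") -> float:
    """Solve the baseline insistor probability from the revealed count.

    Equates the expected number of insistors at risk in control at the
    offer to the observed ``n101``.  With the insistor share of events
    taken at its expected value the relation is linear in ``pi``
    (``rule="expected"``); with the observed period-0 event count
    plugged in it is quadratic (``rule="observed"``).  Returns NaN when
    no root lies in (0, 1).
    """
    n00, y00, d00, n101 = counts.n00, counts.y00, counts.d00, counts.n101
    om = params.omega0
    if rule == "expected":
        denom = n00 * (1.0 - params.alpha0 * om) - d00
        pi = n101 / denom if denom > 0 else float("nan")
    elif rule == "observed":
        # pi*(n00 - d00)*m - pi*y00*om = n101*m,  m = 1 + (om-1)*pi
        b = om - 1.0
        N = n00 - d00
        A = N * b
        B = N - y00 * om - n101 * b
        C = -float(n101)
        if abs(A) < 1e-12:
            pi = -C / B if B != 0 else float("nan")
        else:
            disc = B * B - 4 * A * C
            if disc < 0:
                return float("nan")
            roots = [(-B + math.sqrt(disc)) / (2 * A),
                     (-B - math.sqrt(disc)) / (2 * A)]
            inside = [r for r in roots if 0.0 < r < 1.0]
            pi = inside[0] if inside else float("nan")
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown pi rule {rule!r}")
    if not (0.0 < pi < 1.0):
        return float("nan")
    return pi


def binomial_loglik(params: BinomialParams, counts: BinomialCounts,
                    pi_rule: str | None = "observed") -> float:
    """Log-likelihood of the count table under the latent-strata model.

    The likelihood is the product of binomial kernels over the five
    observed cells: the two pre-offer arms and the post-offer treatment
    arm are two-component mixtures over the latent stratum, while the
    post-offer control rows are observed per stratum.  Returns ``-inf``
    (rather than raising) when any implied cell probability falls
    outside (0, 1).

    With ``pi_rule`` set (the default), ``params.pi`` is replaced by the
    profiled value solved from the observed insistor count; pass
    ``pi_rule=None`` to evaluate at ``params.pi`` as given.
    """
    counts.validate()
    p = params
    if pi_rule is not None:
        p = replace(params, pi=profile_pi(params, counts, pi_rule))
    if not (0.0 <= p.pi <= 1.0) or min(p.alpha0, p.alpha1, p.omega0, p.omega1,
                                       p.gamma0, p.gamma1, p.gamma1_star) <= 0:
        return float("-inf")
    pi11 = pi11_from(p, counts)
    cells = p.cell_probabilities(pi11)
    if any(not (0.0 < v < 1.0) for v in cells.values()):
        return float("-inf")
    c = counts
    y = np.array([c.y00, c.y01, c.y100, c.y101, c.y11], dtype=float)
    n = np.array([c.n00, c.n01, c.n100, c.n101, c.n11], dtype=float)
    pr = np.array([cells["p00"], cells["p01"], cells["p100"],
                   cells["p101"], cells["p11"]])
    # binomial log-pmf via gammaln (identical to scipy's, much less overhead)
    return float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
                        + y * np.log(pr) + (n - y) * np.log1p(-pr)))


@dataclass
class BinomialFit:
    """Result of a maximum-likelihood binomial fit."""

    params: BinomialParams
    loglik: float
    converged: bool
    pi11: float
    expected_counts: dict[str, float]
    trace: list = field(default_factory=list)
    counts: BinomialCounts | None = None
    pi_rule: str = "observed"

    @property
    def gamma(self) -> float:
        return self.params.gamma0

    def summary(self) -> dict:
        p = self.params
        return {
            "variant": {"common_gamma": p.common_gamma,
                        "common_omega": p.common_omega,
                        "tie_gamma1_star": p.tie_gamma1_star},
            "estimates": {
                "alpha0": p.alpha0, "alpha1": p.alpha1,
                "omega0": p.omega0, "omega1": p.omega1,
                "gamma0": p.gamma0, "gamma1": p.gamma1,
                "gamma1_star": p.gamma1_star,
                "pi": p.pi, "pi11": self.pi11},
            "loglik": self.loglik,
            "converged": self.converged,
            "expected_counts": self.expected_counts,
        }


def _free_names(flags: dict) -> list[str]:
    names = ["alpha_star"] if flags.get("constant_rate") else ["alpha0", "alpha1"]
    names.append("omega0" if not flags.get("common_omega", True) else "omega")
    if not flags.get("common_omega", True):
        names.append("omega1")
    names.append("gamma0" if not flags.get("common_gamma", True) else "gamma")
    if not flags.get("common_gamma", True):
        names.append("gamma1")
    if not flags.get("tie_gamma1_star", True):
        names.append("gamma1_star")
    return names


def _build(flags: dict, free: dict) -> BinomialParams:
    v = dict(free)
    if flags.get("constant_rate"):
        t0, t1 = flags["period_lengths"]
        a = v.pop("alpha_star")
        v["alpha0"] = 1.0 - math.exp(-a * t0)
        v["alpha1"] = 1.0 - math.exp(-a * t1)
    return make_params(flags, **v)


def _start_points(counts: BinomialCounts, flags: dict) -> list[dict]:
    """Deterministic multi-start list anchored at the moment estimates."""
    mom = moment_estimates(counts, pi11=0.3)
    a0 = max(min(counts.y00 / max(counts.n00, 1), 0.9), 1e-3)
    base = {"alpha0": a0, "alpha1": max(mom["alpha1"], 1e-3),
            "omega": 0.7, "gamma": max(min(mom["gamma0"], 2.0), 0.05)}
    starts = [base]
    for om, gshift in [(0.4, 1.0), (1.5, 1.0), (0.7, 0.85), (0.7, 1.15)]:
        s = dict(base)
        s["omega"] = om
        s["gamma"] = base["gamma"] * gshift
        starts.append(s)
    out = []
    for s in starts:
        d = {}
        if flags.get("constant_rate"):
            t0, _ = flags["period_lengths"]
            d["alpha_star"] = -math.log(1 - s["alpha0"]) / t0
        else:
            d["alpha0"], d["alpha1"] = s["alpha0"], s["alpha1"]
        if flags.get("common_omega", True):
            d["omega"] = s["omega"]
        else:
            d["omega0"] = d["omega1"] = s["omega"]
        if flags.get("common_gamma", True):
            d["gamma"] = s["gamma"]
        else:
            d["gamma0"] = d["gamma1"] = s["gamma"]
        if not flags.get("tie_gamma1_star", True):
            d["gamma1_star"] = s["gamma"]
        out.append(d)
    return out


def _maximize(counts: BinomialCounts, flags: dict, pi_rule: str,
              fixed: dict | None = None, starts: Iterable[dict] | None = None,
              tol: float = 1e-9):
    """Nelder-Mead maximisation on the log scale with restart at the incumbent."""
    fixed = dict(fixed or {})
    names = [n for n in _free_names(flags) if n not in fixed]
    if starts is None:
        starts = _start_points(counts, flags)

    def objective(z):
        free = {n: math.exp(v) for n, v in zip(names, z)}
        free.update(fixed)
        ll = binomial_loglik(_build(flags, free), counts, pi_rule)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    trace = []
    for s in starts:
        z0 = np.log([s.get(n, 0.5) for n in names])
        r = optimize.minimize(objective, z0, method="Nelder-Mead",
                              options=dict(xatol=1e-10, fatol=tol,
                                           maxiter=20000, maxfev=20000))
        # restart at the incumbent to escape simplex collapse
        r2 = optimize.minimize(objective, r.x, method="Nelder-Mead",
                               options=dict(xatol=1e-10, fatol=tol,
                                            maxiter=20000, maxfev=20000))
        cand = r2 if r2.fun <= r.fun else r
        trace.append({"start": s, "loglik": -cand.fun, "nfev": r.nfev + r2.nfev,
                      "success": bool(cand.fun < 1e11)})
        if best is None or cand.fun < best.fun:
            best = cand
    if best is None or best.fun >= 1e11:
        raise ConvergenceError("binomial likelihood maximisation failed "
                               "from every start point", history=trace)
    free = {n: math.exp(v) for n, v in zip(names, best.x)}
    free.update(fixed)
    return _build(flags, free), -best.fun, trace


def fit_binomial(counts: BinomialCounts, variant: str | dict = "common",
                 pi_rule: str = "observed", tol: float = 1e-9,
                 n_starts: int = 5) -> BinomialFit:
    """Fit the binomial latent-strata model by maximum likelihood.

    Parameters are optimised on the log scale by a derivative-free
    simplex search from a fixed list of five start points (the best kept),
    so the fit is deterministic.  ``variant`` selects the restriction
    pattern: ``"common"`` (the primary model: one efficacy, one insistor
    effect), ``"by-period"`` (period-specific efficacy) or
    ``"free-gamma1star"`` (additionally frees the post-crossover
    insistor effect).
    """
    counts.validate()
    if min(counts.n00, counts.n01, counts.n11, counts.n10) == 0:
        raise DegenerateDataError("both arms must be populated in both periods")
    flags = dict(VARIANTS[variant]) if isinstance(variant, str) else dict(variant)
    starts = _start_points(counts, flags)[:max(1, n_starts)]
    params, ll, trace = _maximize(counts, flags, pi_rule, starts=starts,
                                  tol=tol)
    params = replace(params, pi=profile_pi(params, counts, pi_rule))
    pi11 = pi11_from(params, counts)
    cells = params.cell_probabilities(pi11)
    expected = {
        "y00": cells["p00"] * counts.n00, "y01": cells["p01"] * counts.n01,
        "y100": cells["p100"] * counts.n100, "y101": cells["p101"] * counts.n101,
        "y11": cells["p11"] * counts.n11,
        "n101": expected_insistors(params, counts, arm=0)}
    return BinomialFit(params=params, loglik=ll, converged=True, pi11=pi11,
                       expected_counts=expected, trace=trace, counts=counts,
                       pi_rule=pi_rule)


def profile_loglik(counts: BinomialCounts, variant: str | dict, param: str,
                   value: float, pi_rule: str = "observed",
                   start: dict | None = None) -> float:
    """Log-likelihood re-maximised over all parameters but ``param``."""
    flags = dict(VARIANTS[variant]) if isinstance(variant, str) else dict(variant)
    starts = [start] if start is not None else None
    _, ll, _ = _maximize(counts, flags, pi_rule, fixed={param: value},
                         starts=starts)
    return ll


def profile_ci(counts: BinomialCounts, variant: str | dict = "common",
               param: str = "gamma", level: float = 0.95,
               pi_rule: str = "observed", fit: BinomialFit | None = None,
               rel_tol: float = 1e-4) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one parameter.

    Each endpoint solves ``2 * (l_max - l_profile(theta)) = chi2_1
    quantile``; the roots are bracketed by geometric expansion away from
    the MLE and then refined by bisection.  An endpoint that cannot be
    bracketed within a wide search range is returned as ``inf``/``0``
    (open-interval flag) rather than raising.
    """
    if fit is None:
        fit = fit_binomial(counts, variant, pi_rule)
    flags = dict(VARIANTS[variant]) if isinstance(variant, str) else dict(variant)
    p = fit.params
    lookup = {"gamma": p.gamma0, "gamma0": p.gamma0, "gamma1": p.gamma1,
              "gamma1_star": p.gamma1_star, "omega": p.omega0,
              "omega0": p.omega0, "omega1": p.omega1,
              "alpha0": p.alpha0, "alpha1": p.alpha1}
    mle = lookup[param]
    start = {"alpha0": p.alpha0, "alpha1": p.alpha1,
             "omega": p.omega0, "omega0": p.omega0, "omega1": p.omega1,
             "gamma": p.gamma0, "gamma0": p.gamma0, "gamma1": p.gamma1,
             "gamma1_star": p.gamma1_star}
    cutoff = fit.loglik - stats.chi2(1).ppf(level) / 2.0
    names = [n for n in _free_names(flags) if n != param]
    warm = {side: dict(start) for side in (-1, +1)}

    def drop(value, side):
        # warm-start continuation: reuse the nuisance optimum from the
        # previous profile point on the same side
        prm, ll, _ = _maximize(counts, flags, pi_rule, fixed={param: value},
                               starts=[warm[side]])
        for n in names:
            warm[side][n] = {"alpha0": prm.alpha0, "alpha1": prm.alpha1,
                             "omega": prm.omega0, "omega0": prm.omega0,
                             "omega1": prm.omega1, "gamma": prm.gamma0,
                             "gamma0": prm.gamma0, "gamma1": prm.gamma1,
                             "gamma1_star": prm.gamma1_star}[n]
        return ll - cutoff

    def solve(direction: int) -> float:
        factor = 1.05
        inner, outer = mle, mle
        for _ in range(200):
            outer = outer * factor if direction > 0 else outer / factor
            if drop(outer, direction) < 0:
                break
            inner = outer
            factor = factor ** 1.5  # geometric expansion of the bracket
            if outer > mle * 1e3 or outer < mle * 1e-3:
                return float("inf") if direction > 0 else 0.0
        else:  # pragma: no cover
            return float("inf") if direction > 0 else 0.0
        lo, hi = (inner, outer) if direction > 0 else (outer, inner)
        # bisection on the likelihood-drop sign to relative tolerance
        while (hi - lo) > rel_tol * mle:
            mid = 0.5 * (lo + hi)
            if (drop(mid, direction) > 0) == (direction > 0):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    return (solve(-1), solve(+1))


def lr_test(counts: BinomialCounts, variant_null: str | dict,
            variant_alt: str | dict, pi_rule: str = "observed",
            n_starts: int = 5):
    """Likelihood-ratio test of a restricted variant against a nesting one.

    Returns ``(statistic, df, p_value)``.  The statistic is clipped at
    zero to absorb optimiser jitter on identical fits.
    """
    fn = dict(VARIANTS[variant_null]) if isinstance(variant_null, str) else dict(variant_null)
    fa = dict(VARIANTS[variant_alt]) if isinstance(variant_alt, str) else dict(variant_alt)
    restrictions = ["common_gamma", "common_omega", "tie_gamma1_star"]
    if not all(fn.get(k, True) or not fa.get(k, True) for k in restrictions):
        raise CrossfxError("null variant is not nested in the alternative")
    fit_n = fit_binomial(counts, fn, pi_rule, n_starts=n_starts)
    fit_a = fit_binomial(counts, fa, pi_rule, n_starts=n_starts)
    df = fit_a.params.n_free - fit_n.params.n_free
    if df <= 0:
        if fn == fa:
            return 0.0, 0, 1.0
        raise CrossfxError("alternative has no extra free parameters")
    statistic = max(0.0, 2.0 * (fit_a.loglik - fit_n.loglik))
    return statistic, df, float(stats.chi2(df).sf(statistic))


def moment_estimates(counts: BinomialCounts, pi: float | None = None,
                     omega: float | None = None,
                     pi11: float | None = None) -> dict[str, float]:
    """Closed-form moment diagnostics for the binomial model.

    ``gamma0`` is the pre-offer event-proportion ratio between arms;
    ``alpha1`` the post-offer event proportion among revealed
    ambivalents; ``gamma1`` subtracts the insistor share out of both
    arms using a plug-in ``pi11`` (supplied directly, or derived from
    ``(pi, omega)`` through the expected-insistor count).
    """
    c = counts.validate()
    if min(c.n00, c.n01, c.n100, c.n101, c.n11) == 0:
        raise DegenerateDataError("moment estimates need all cells populated")
    gamma0 = (c.y01 / c.n01) / (c.y00 / c.n00)
    alpha1 = c.y100 / c.n100
    out = {"gamma0": gamma0, "alpha1": alpha1}
    if pi11 is None and pi is not None and omega is not None:
        # the observed control rate is the stratum mixture; de-mix it to
        # get the ambivalent rate alpha0 before deriving pi11
        mix = 1.0 - pi + pi * omega
        params = make_params("common", alpha0=(c.y00 / c.n00) / mix,
                             alpha1=alpha1, omega=omega, gamma=gamma0, pi=pi)
        pi11 = pi11_from(params, c)
    if pi11 is not None:
        num = c.y11 / c.n11 - pi11 * c.y101 / c.n101
        den = (1.0 - pi11) * c.y100 / c.n100
        out["gamma1"] = num / den
        out["pi11"] = pi11
    return out
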