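"""Maximum-likelihood fitting of the logistic psychometric function.

Session data are aggregated into (level, n presented, k correct) triples
and fitted with three free parameters — threshold (at the criterion
probability, 0.75), spread, and lapse rate — by Nelder–Mead simplex search
on the negative log-likelihood, with the guess rate fixed by the task.
Goodness of fit uses the deviance (twice the log-likelihood ratio of the
saturated binomial model to the fit), with a Monte-Carlo (parametric
bootstrap) p-value, and fits are screened by the inclusion ranges
theta in [1, 500] arcsec, sigma in [0.01, 7], p(Dev) > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .bayes import model_probability
from .model import PROB_CLIP, TaskSpec
from .staircase import Session

__all__ = [
    "AggregatedData",
    "FitResult",
    "InclusionRanges",
    "aggregate",
    "negative_log_likelihood",
    "fit_ml",
    "deviance",
    "p_deviance",
    "passes_inclusion",
]

#: constraint box used in the fits: lapse in (0, LAPSE_MAX)
LAPSE_MAX = 0.06

_PENALTY = 1e12


class EmptyDataError(ValueError):
    pass


class NonIdentifiableError(RuntimeError):
    """All responses correct (or incorrect): the likelihood has no interior
    optimum."""


@dataclass(frozen=True)
class AggregatedData:
    """Per-level counts: distinct sorted levels, trials presented, correct."""

    level: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        level = np.asarray(self.level, float)
        n = np.asarray(self.n, int)
        k = np.asarray(self.k, int)
        if len(level) == 0:
            raise EmptyDataError("no data")
        if np.any(np.diff(level) <= 0):
            raise ValueError("levels must be distinct and sorted")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= k <= n")
        object.__setattr__(self, "level", level)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @property
    def total_trials(self) -> int:
        return int(self.n.sum())


@dataclass(frozen=True)
class FitResult:
    """ML estimates with goodness of fit.  ``theta`` is in log10 arcsec."""

    theta: float
    sigma: float
    lapse: float
    guess: float
    pi: float
    nll: float
    dev: float
    p_dev: Optional[float] = None
    included: Optional[bool] = None

    @property
    def theta_arcsec(self) -> float:
        return float(10.0 ** self.theta)


def aggregate(session: Session, exclude_practice: bool = True) -> AggregatedData:
    """Collapse a trial log into per-level (n, k) counts."""
    trials = [
        t for t in session.trials if not (exclude_practice and t.practice)
    ]
    if not trials:
        raise EmptyDataError("session has no (non-practice) trials")
    levels = {}
    for t in trials:
        n, k = levels.get(t.level, (0, 0))
        levels[t.level] = (n + 1, k + int(t.response))
    lv = np.array(sorted(levels))
    n = np.array([levels[x][0] for x in lv])
    k = np.array([levels[x][1] for x in lv])
    return AggregatedData(level=lv, n=n, k=k)


def negative_log_likelihood(
    theta: float,
    sigma: float,
    lapse: float,
    data: AggregatedData,
    guess: float,
    pi: float = 0.75,
) -> float:
    """Binomial negative log-likelihood of (theta, sigma, lapse).

    Constraint violations (sigma <= 0, lapse outside (0, 0.06), infeasible
    criterion) return a large finite penalty rather than raising, so probe
    evaluations during optimization stay well-defined.
    """
    if not (np.isfinite(theta) and np.isfinite(sigma) and np.isfinite(lapse)):
        return _PENALTY
    if sigma <= 0 or lapse < 0 or lapse >= LAPSE_MAX or lapse >= 1.0 - pi:
        return _PENALTY
    task = TaskSpec(round(1.0 / guess))
    p = np.clip(
        model_probability(data.level, theta, sigma, lapse, task, pi),
        PROB_CLIP, 1.0 - PROB_CLIP,
    )
    return float(-(data.k * np.log(p) + (data.n - data.k) * np.log(1 - p)).sum())


def _fitted_probabilities(fit: FitResult, data: AggregatedData) -> np.ndarray:
    task = TaskSpec(round(1.0 / fit.guess))
    return np.clip(
        model_probability(data.level, fit.theta, fit.sigma, fit.lapse, task,
                          fit.pi),
        PROB_CLIP, 1.0 - PROB_CLIP,
    )


def fit_ml(
    data: AggregatedData,
    guess: float,
    pi: float = 0.75,
    lapse_max: float = LAPSE_MAX,
) -> FitResult:
    """Fit (theta, sigma, lapse) by multi-start Nelder-Mead.

    The search runs in a transformed space — theta in log10 arcsec
    (unbounded; theta > 0 arcsec always holds), log sigma, and a logistic
    transform mapping the lapse into (0, lapse_max) — so the simplex never
    meets the constraint boundary.  Starts cover a coarse lattice of
    threshold/spread values crossed with three lapse levels; the best
    likelihood wins.
    """
    if np.all(data.k == data.n) or np.all(data.k == 0):
        raise NonIdentifiableError("all responses identical; cannot fit")

    def unpack(z):
        theta = z[0]
        sigma = np.exp(z[1])
        lapse = lapse_max / (1.0 + np.exp(-z[2]))
        return theta, sigma, lapse

    def objective(z):
        return negative_log_likelihood(*unpack(z), data, guess, pi)

    lo, hi = data.level[0], data.level[-1]
    theta_starts = (lo + 0.35 * (hi - lo), lo + 0.65 * (hi - lo))
    best = None
    for th0, sg0, lp0 in product(theta_starts, (0.6, 1.8),
                                 (0.001, 0.02, 0.05)):
        z0 = np.array([
            th0,
            np.log(sg0),
            np.log(lp0 / (lapse_max - lp0)),
        ])
        res = minimize(objective, z0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    theta, sigma, lapse = unpack(best.x)
    fit = FitResult(theta=float(theta), sigma=float(sigma), lapse=float(lapse),
                    guess=guess, pi=pi, nll=float(best.fun), dev=np.nan)
    dev = deviance(data, fit)
    return FitResult(theta=fit.theta, sigma=fit.sigma, lapse=fit.lapse,
                     guess=guess, pi=pi, nll=fit.nll, dev=dev)


def deviance(data: AggregatedData, fit: FitResult) -> float:
    """Deviance of the fit against the saturated binomial model:
    2 sum[k ln(k/(n p)) + (n-k) ln((n-k)/(n(1-p)))], with 0 ln 0 = 0."""
    p = _fitted_probabilities(fit, data)
    k = data.k.astype(float)
    n = data.n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / (n * p)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n * (1 - p))), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _warm_refit_deviance(data: AggregatedData, fit: FitResult,
                         lapse_max: float = LAPSE_MAX) -> float:
    """Deviance after a single warm-started simplex refit (used for the
    bootstrap reference distribution)."""
    def unpack(z):
        return z[0], np.exp(z[1]), lapse_max / (1.0 + np.exp(-z[2]))

    def objective(z):
        return negative_log_likelihood(*unpack(z), data, fit.guess, fit.pi)

    lp = min(max(fit.lapse, 1e-4), lapse_max - 1e-4)
    z0 = np.array([fit.theta, np.log(fit.sigma),
                   np.log(lp / (lapse_max - lp))])
    res = minimize(objective, z0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
    theta, sigma, lapse = unpack(res.x)
    refit = FitResult(theta=float(theta), sigma=float(sigma),
                      lapse=float(lapse), guess=fit.guess, pi=fit.pi,
                      nll=float(res.fun), dev=np.nan)
    return deviance(data, refit)


def p_deviance(
    data: AggregatedData,
    fit: FitResult,
    B: int = 1000,
    rng: Optional[np.random.Generator] = None,
    refit: bool = True,
) -> float:
    """Monte-Carlo p-value of the observed deviance.

    Parametric bootstrap: B datasets are simulated from the fitted model at
    the same (level, n) design; each is refitted (warm-started at the
    original estimates) and its deviance computed, giving the reference
    distribution; p is the fraction of simulated deviances at least as
    large as the observed one.  Refitting matters: comparing against
    non-refitted deviances ignores the three fitted degrees of freedom and
    makes the test strongly conservative.  ``refit=False`` gives that
    cheaper conservative variant.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    p = _fitted_probabilities(fit, data)
    n = data.n
    k_sim = rng.binomial(n[None, :], p[None, :], size=(B, len(n)))
    if refit:
        devs = np.empty(B)
        for b in range(B):
            sim = AggregatedData(data.level, n, k_sim[b])
            devs[b] = _warm_refit_deviance(sim, fit)
    else:
        kf = k_sim.astype(float)
        nf = n.astype(float)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(kf > 0, kf * np.log(kf / (nf * p[None, :])), 0.0)
            t2 = np.where(
                nf - kf > 0,
                (nf - kf) * np.log((nf - kf) / (nf * (1 - p[None, :]))),
                0.0)
        devs = 2.0 * (t1 + t2).sum(axis=1)
    return float(np.mean(devs >= fit.dev))


@dataclass(frozen=True)
class InclusionRanges:
    """Validity screen applied to each fit before analysis."""

    theta_arcsec: tuple[float, float] = (1.0, 500.0)
    sigma: tuple[float, float] = (0.01, 7.0)
    p_dev_min: float = 0.05


def passes_inclusion(
    fit: FitResult, ranges: InclusionRanges = InclusionRanges()
) -> bool:
    """True iff theta, sigma, and p(Dev) all fall in the valid ranges."""
    if fit.p_dev is None:
        raise ValueError("fit has no p_dev; run p_deviance first")
    lo, hi = ranges.theta_arcsec
    slo, shi = ranges.sigma
    return bool(
        lo <= fit.theta_arcsec <= hi
        and slo <= fit.sigma <= shi
        and fit.p_dev > ranges.p_dev_min
    )
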