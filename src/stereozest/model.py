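"""Logistic psychometric function for forced-choice disparity detection.

The probability of a correct response at a (log) stimulus intensity ``x`` is

    Psi(x) = gamma + (1 - gamma - lambda) * L(x; alpha, beta)

where ``L`` is the logistic sigmoid ``1 / (1 + exp(-beta (x - alpha)))``,
``gamma`` is the guess rate fixed by the task (1/2 for 2AFC, 1/4 for 4AFC),
and ``lambda`` is the probability of an *incorrect* response caused by a
lapse of attention.  All intensities, thresholds and spreads are carried in
log10 arcsec of binocular disparity; linear arcsec appears only at I/O
boundaries.

Two equivalent width parameterizations are used throughout the field: the
slope ``beta`` (per log10 arcsec) and the spread ``sigma`` (log10 arcsec),
the stimulus interval over which the base sigmoid rises through its central
95% (from 0.025 to 0.975).  They are tied by ``beta * sigma = 2 ln 39``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPREAD_SLOPE_CONSTANT",
    "PROB_CLIP",
    "PsychometricModel",
    "SimulatedObserver",
    "TaskSpec",
    "base_logistic",
    "response_probability",
    "spread_to_slope",
    "slope_to_spread",
    "location_from_threshold",
    "threshold_from_location",
    "lapse_from_lapse_star",
    "lapse_star_from_lapse",
    "simulate_response",
]

#: beta * sigma for the central-95% spread definition: 2*ln(0.975/0.025).
SPREAD_SLOPE_CONSTANT = 2.0 * np.log(39.0)

#: probabilities are clipped to [PROB_CLIP, 1-PROB_CLIP] before logs.
PROB_CLIP = 1e-12


class InvalidParameterError(ValueError):
    """A psychometric-function parameter is out of its valid domain."""


class InfeasibleCriterionError(ValueError):
    """The requested criterion probability lies outside (gamma, 1-lambda)."""


def spread_to_slope(sigma):
    """Convert a spread (log10 arcsec) to a logistic slope (per log10 arcsec).

    The spread is the intensity interval over which the base logistic rises
    from 0.025 to 0.975, so ``beta = 2 ln(39) / sigma`` (approx. 7.327/sigma).
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise InvalidParameterError("spread must be finite and > 0")
    return SPREAD_SLOPE_CONSTANT / sigma


def slope_to_spread(beta):
    """Inverse of :func:`spread_to_slope`."""
    beta = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(beta)) or np.any(beta <= 0):
        raise InvalidParameterError("slope must be finite and > 0")
    return SPREAD_SLOPE_CONSTANT / beta


def lapse_from_lapse_star(lapse_star, gamma):
    """Convert the probability of lapsing at all (lambda*) to the lapse rate.

    A lapsed trial is answered at random, so the probability of an incorrect
    response due to a lapse is ``lambda = lambda* (1 - gamma)``; it grows with
    the number of response alternatives.
    """
    lapse_star = np.asarray(lapse_star, dtype=float)
    if np.any(lapse_star < 0) or np.any(lapse_star > 1):
        raise InvalidParameterError("lambda* must be in [0, 1]")
    if not 0 <= gamma < 1:
        raise InvalidParameterError("gamma must be in [0, 1)")
    return lapse_star * (1.0 - gamma)


def lapse_star_from_lapse(lapse, gamma):
    """Inverse of :func:`lapse_from_lapse_star`."""
    lapse = np.asarray(lapse, dtype=float)
    if np.any(lapse < 0):
        raise InvalidParameterError("lambda must be >= 0")
    if not 0 <= gamma < 1:
        raise InvalidParameterError("gamma must be in [0, 1)")
    return lapse / (1.0 - gamma)


def base_logistic(x, alpha, beta):
    """Unscaled logistic sigmoid ``1 / (1 + exp(-beta (x - alpha)))``."""
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or not np.isfinite(alpha):
        raise InvalidParameterError("x and alpha must be finite")
    if not (np.isfinite(beta) and beta > 0):
        raise InvalidParameterError("beta must be finite and > 0")
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-beta * (x - alpha)))
    return out if out.ndim else float(out)


def location_from_threshold(theta, beta, gamma, lapse, pi):
    """Location alpha of the logistic whose scaled curve passes pi at theta.

    Solves ``gamma + (1-gamma-lapse) L(theta; alpha, beta) = pi``:
    ``alpha = theta - ln(F/(1-F)) / beta`` with ``F = (pi-gamma)/(1-gamma-lapse)``.
    """
    theta = np.asarray(theta, dtype=float)
    if not (gamma < pi < 1.0 - lapse):
        raise InfeasibleCriterionError(
            f"criterion pi={pi} must lie strictly between gamma={gamma} "
            f"and 1-lambda={1 - lapse}"
        )
    frac = (pi - gamma) / (1.0 - gamma - lapse)
    alpha = theta - np.log(frac / (1.0 - frac)) / beta
    return alpha if alpha.ndim else float(alpha)


def threshold_from_location(alpha, beta, gamma, lapse, pi):
    """Inverse of :func:`location_from_threshold`."""
    alpha = np.asarray(alpha, dtype=float)
    if not (gamma < pi < 1.0 - lapse):
        raise InfeasibleCriterionError(
            f"criterion pi={pi} must lie strictly between gamma={gamma} "
            f"and 1-lambda={1 - lapse}"
        )
    frac = (pi - gamma) / (1.0 - gamma - lapse)
    theta = alpha + np.log(frac / (1.0 - frac)) / beta
    return theta if theta.ndim else float(theta)


@dataclass(frozen=True)
class TaskSpec:
    """An n-alternative forced-choice task; the guess rate is 1/n."""

    n_alternatives: int

    def __post_init__(self):
        if self.n_alternatives not in (2, 4):
            raise InvalidParameterError("n_alternatives must be 2 or 4")

    @property
    def guess(self) -> float:
        return 1.0 / self.n_alternatives

    @classmethod
    def from_name(cls, name: str) -> "TaskSpec":
        name = name.lower()
        if name in ("2afc", "2"):
            return cls(2)
        if name in ("4afc", "4"):
            return cls(4)
        raise InvalidParameterError(f"unknown task {name!r}")


TASK_2AFC = TaskSpec(2)
TASK_4AFC = TaskSpec(4)


@dataclass(frozen=True)
class PsychometricModel:
    """Scaled logistic psychometric function.

    Parameters
    ----------
    location : float
        Midpoint alpha of the base logistic, log10 arcsec.
    slope : float
        Slope beta, per log10 arcsec (equivalently spread = 2 ln 39 / beta).
    guess : float
        Lower asymptote gamma (1/n alternatives in forced choice).
    lapse : float
        Probability lambda of an incorrect response due to a lapse; the
        upper asymptote is 1 - lambda.
    """

    location: float
    slope: float
    guess: float = 0.5
    lapse: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.location)):
            raise InvalidParameterError("location must be finite")
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise InvalidParameterError("slope must be finite and > 0")
        if not 0 <= self.guess < 1:
            raise InvalidParameterError("guess must be in [0, 1)")
        if self.lapse < 0 or self.guess + self.lapse >= 1:
            raise InvalidParameterError("need 0 <= lapse and guess + lapse < 1")

    @property
    def spread(self) -> float:
        return float(slope_to_spread(self.slope))

    def probability(self, x):
        """Probability of a correct response at intensity ``x``."""
        return response_probability(x, self)

    def threshold(self, pi: float) -> float:
        """Intensity at which the function passes the criterion ``pi``."""
        return threshold_from_location(
            self.location, self.slope, self.guess, self.lapse, pi
        )

    @classmethod
    def from_threshold(
        cls,
        threshold: float,
        spread: float,
        guess: float,
        lapse: float,
        pi: float = 0.75,
    ) -> "PsychometricModel":
        """Build a model from (threshold at pi, spread, guess, lapse)."""
        beta = float(spread_to_slope(spread))
        alpha = location_from_threshold(threshold, beta, guess, lapse, pi)
        return cls(location=alpha, slope=beta, guess=guess, lapse=lapse)


def response_probability(x, model: PsychometricModel):
    """Probability of a correct response under ``model`` at intensity ``x``."""
    base = base_logistic(x, model.location, model.slope)
    return model.guess + (1.0 - model.guess - model.lapse) * base


@dataclass(frozen=True)
class SimulatedObserver:
    """A virtual observer: a psychometric function plus its nominal threshold.

    ``true_threshold`` is the intensity at which the observer's function
    passes the criterion ``pi`` (0.75 throughout); the identity
    ``model.probability(true_threshold) == pi`` is enforced at construction.
    """

    model: PsychometricModel
    true_threshold: float
    pi: float = 0.75
    identifier: str = ""

    def __post_init__(self):
        if not (self.model.guess < self.pi < 1.0 - self.model.lapse):
            raise InfeasibleCriterionError(
                "pi must lie strictly between guess and 1-lapse"
            )
        got = response_probability(self.true_threshold, self.model)
        if abs(got - self.pi) > 1e-9:
            raise InvalidParameterError(
                f"model probability at threshold is {got!r}, not pi={self.pi}"
            )

    @classmethod
    def standard(cls, task: TaskSpec, pi: float = 0.75) -> "SimulatedObserver":
        """The standard stereoacuity observer: theta=1.5, sigma=1, lapse
        0.02 (2AFC) / 0.03 (4AFC)."""
        lapse = lapse_from_lapse_star(0.04, task.guess)
        return cls.from_parameters(1.5, 1.0, float(lapse), task, pi, "standard")

    @classmethod
    def from_parameters(
        cls,
        threshold: float,
        spread: float,
        lapse: float,
        task: TaskSpec,
        pi: float = 0.75,
        identifier: str = "",
    ) -> "SimulatedObserver":
        model = PsychometricModel.from_threshold(
            threshold, spread, task.guess, lapse, pi
        )
        return cls(model=model, true_threshold=threshold, pi=pi,
                   identifier=identifier)


def simulate_response(model: PsychometricModel, x, rng: np.random.Generator):
    """Draw a Bernoulli correct/incorrect response at intensity ``x``.

    The success probability is read off the observer's psychometric
    function; identical generators yield identical response sequences.
    """
    p = response_probability(x, model)
    return bool(rng.random() < p)
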