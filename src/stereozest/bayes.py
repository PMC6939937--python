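"""Grid-based Bayesian adaptive procedures: ZEST, ZEST-2D, Psi, Psi-marginal.

All procedures share the same machinery: a discrete posterior over
psychometric-function parameters (threshold, optionally spread and lapse),
updated by Bayes' rule after every trial, with the next stimulus chosen
either at the posterior mean of the threshold (ZEST family) or at the
intensity minimizing the expected entropy of the posterior over the
parameters of interest (Psi family).

The parameter grid is indexed by the *threshold* (the intensity at which
the psychometric function passes the criterion probability ``pi``), not by
the logistic location, so every grid hypothesis satisfies
``Psi(theta) = pi`` by construction.

Seven procedure configurations are provided:

==================== ========= ============== =====================
name                 axes      placement      interest axes
==================== ========= ============== =====================
zest_fixed_sigma     theta     posterior mean --
zest2d_theta_sigma   theta,sig posterior mean --
zest2d_theta         theta,sig posterior mean --
psi_theta_sigma      theta,sig min entropy    theta, sigma
psi_marg_theta_sigma_L theta,sig,lapse min entropy theta, sigma
psi_marg_theta_SL    theta,sig,lapse min entropy theta
psi_marg_theta_S     theta,sig min entropy    theta
==================== ========= ============== =====================

The two ZEST-2D variants share one placement and posterior; they differ
only in whether the spread is reported as an estimate or treated purely as
a nuisance parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Optional, Sequence, Union

import numpy as np

from .model import (
    PROB_CLIP,
    PsychometricModel,
    SimulatedObserver,
    TaskSpec,
    lapse_from_lapse_star,
    location_from_threshold,
    response_probability,
    spread_to_slope,
)

__all__ = [
    "ParameterGrid",
    "GridModel",
    "Posterior",
    "MarginalPosterior",
    "GaussianPrior",
    "ProcedureConfig",
    "EstimateTrace",
    "PROCEDURES",
    "default_grid",
    "model_probability",
    "init_prior",
    "update_posterior",
    "marginal",
    "posterior_mean",
    "zest_place",
    "expected_posterior_entropy",
    "psi_place",
    "run_procedure",
    "run_zest_fixed_batch",
]


class InvalidRequestError(ValueError):
    pass


class DegeneratePosteriorError(RuntimeError):
    pass


def model_probability(x, theta, sigma, lapse, task: TaskSpec, pi: float = 0.75):
    """Probability of a correct response for a threshold-parameterized model.

    The logistic location is derived from the threshold so that the curve
    passes ``pi`` exactly at ``theta``.  All of ``x``, ``theta``, ``sigma``,
    ``lapse`` broadcast.
    """
    beta = spread_to_slope(sigma)
    gamma = task.guess
    frac = (pi - gamma) / (1.0 - gamma - lapse)
    if np.any(frac <= 0) or np.any(frac >= 1):
        from .model import InfeasibleCriterionError

        raise InfeasibleCriterionError(
            f"criterion pi={pi} infeasible for gamma={gamma} and given lapse"
        )
    alpha = np.asarray(theta, float) - np.log(frac / (1.0 - frac)) / beta
    with np.errstate(over="ignore"):
        base = 1.0 / (1.0 + np.exp(-beta * (np.asarray(x, float) - alpha)))
    return gamma + (1.0 - gamma - lapse) * base


# --------------------------------------------------------------------------
# grids

AXIS_NAMES = ("threshold", "spread", "lapse")


@dataclass(frozen=True)
class ParameterGrid:
    """Discrete axes for the posterior and the stimulus candidate set.

    The spread axis is absent for fixed-spread ZEST; the lapse axis is
    present only for the lapse-marginalizing Psi configurations.
    """

    threshold: np.ndarray
    stimuli: np.ndarray
    spread: Optional[np.ndarray] = None
    lapse: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in AXIS_NAMES + ("stimuli",):
            vals = getattr(self, name if name != "stimuli" else "stimuli")
            if vals is None:
                continue
            vals = np.asarray(vals, dtype=float)
            if vals.ndim != 1 or len(vals) < 1:
                raise InvalidRequestError(f"{name} axis must be 1-D, non-empty")
            if len(vals) > 1 and np.any(np.diff(vals) <= 0):
                raise InvalidRequestError(f"{name} axis must be strictly increasing")
            object.__setattr__(self, name, vals)
        tmin, tmax = self.threshold[0], self.threshold[-1]
        if self.stimuli[0] < tmin - 1e-12 or self.stimuli[-1] > tmax + 1e-12:
            raise InvalidRequestError(
                "stimulus candidates must lie within the threshold-axis range"
            )

    @property
    def axes(self) -> tuple[str, ...]:
        names = ["threshold"]
        if self.spread is not None:
            names.append("spread")
        if self.lapse is not None:
            names.append("lapse")
        return tuple(names)

    def axis_values(self, name: str) -> np.ndarray:
        if name not in self.axes:
            raise InvalidRequestError(f"grid has no axis {name!r}")
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(self.axis_values(a)) for a in self.axes)


def default_grid(
    with_spread: bool,
    with_lapse: bool,
    theta_range: tuple[float, float] = (0.0, 3.0),
    theta_step: float = 0.01,
    stimulus_step: Optional[float] = None,
    n_spread: int = 21,
    spread_range: tuple[float, float] = (0.03, 3.5),
    lapse_values: Sequence[float] = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
) -> ParameterGrid:
    """Default grid: threshold 0-3 log10 arcsec in steps of 0.01 (stimulus
    candidates identical unless ``stimulus_step`` is given), 21 log-spaced
    spreads over the empirically observed 0.03-3.5 range, lapse 0-0.06."""
    lo, hi = theta_range
    n = int(round((hi - lo) / theta_step)) + 1
    theta = np.linspace(lo, hi, n)
    if stimulus_step is None:
        stimuli = theta.copy()
    else:
        m = int(round((hi - lo) / stimulus_step)) + 1
        stimuli = np.linspace(lo, hi, m)
    spread = np.geomspace(*spread_range, n_spread) if with_spread else None
    lapse = np.asarray(lapse_values, float) if with_lapse else None
    return ParameterGrid(threshold=theta, stimuli=stimuli, spread=spread,
                         lapse=lapse)


# --------------------------------------------------------------------------
# grid model and posterior


@dataclass(frozen=True)
class GridModel:
    """A parameter grid bound to a task, criterion, and any fixed nuisance
    parameters; precomputes the per-stimulus likelihood tensor."""

    grid: ParameterGrid
    task: TaskSpec
    pi: float = 0.75
    sigma_m: Optional[float] = None   # fixed spread (no spread axis)
    lambda_m: Optional[float] = None  # fixed lapse (no lapse axis)

    def __post_init__(self):
        if (self.grid.spread is None) == (self.sigma_m is None):
            raise InvalidRequestError(
                "exactly one of a spread axis or a fixed sigma_m is required"
            )
        if (self.grid.lapse is None) == (self.lambda_m is None):
            raise InvalidRequestError(
                "exactly one of a lapse axis or a fixed lambda_m is required"
            )

    def _param_mesh(self):
        """Broadcastable (theta, sigma, lapse) arrays of the grid shape."""
        g = self.grid
        axes = g.axes
        nd = len(axes)

        def expand(vals, axis_name):
            if axis_name in axes:
                i = axes.index(axis_name)
                shape = [1] * nd
                shape[i] = len(vals)
                return np.asarray(vals, float).reshape(shape)
            return None

        theta = expand(g.threshold, "threshold")
        sigma = expand(g.spread, "spread") if g.spread is not None else self.sigma_m
        lapse = expand(g.lapse, "lapse") if g.lapse is not None else self.lambda_m
        return theta, sigma, lapse

    def prob_correct(self, x) -> np.ndarray:
        """P(correct at intensity x) for every grid hypothesis (grid-shaped)."""
        theta, sigma, lapse = self._param_mesh()
        p = model_probability(x, theta, sigma, lapse, self.task, self.pi)
        return np.clip(np.broadcast_to(p, self.grid.shape), PROB_CLIP,
                       1.0 - PROB_CLIP)

    @cached_property
    def likelihood_table(self) -> np.ndarray:
        """P(correct) for every (stimulus candidate, grid point); shape
        (n_stimuli, n_grid_points) with grid points flattened in C order."""
        theta, sigma, lapse = self._param_mesh()
        x = self.grid.stimuli.reshape((-1,) + (1,) * len(self.grid.shape))
        p = model_probability(x, theta, sigma, lapse, self.task, self.pi)
        p = np.broadcast_to(p, (len(self.grid.stimuli),) + self.grid.shape)
        return np.clip(p.reshape(len(self.grid.stimuli), -1), PROB_CLIP,
                       1.0 - PROB_CLIP)


@dataclass(frozen=True)
class GaussianPrior:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            from .model import InvalidParameterError

            raise InvalidParameterError("gaussian prior sd must be > 0")


SpreadPrior = Union[str, GaussianPrior]


@dataclass(frozen=True)
class Posterior:
    """Normalized probability mass over the grid of a :class:`GridModel`."""

    model: GridModel
    mass: np.ndarray

    def __post_init__(self):
        mass = np.asarray(self.mass, dtype=float)
        if mass.shape != self.model.grid.shape:
            raise InvalidRequestError("mass shape does not match grid")
        if np.any(~np.isfinite(mass)) or np.any(mass < 0):
            raise DegeneratePosteriorError("mass must be finite, non-negative")
        total = mass.sum()
        if not np.isfinite(total) or total <= 0:
            raise DegeneratePosteriorError("mass sums to zero")
        object.__setattr__(self, "mass", mass / total)

    @property
    def axes(self) -> tuple[str, ...]:
        return self.model.grid.axes


@dataclass(frozen=True)
class MarginalPosterior:
    """One-axis marginal: axis values and their (normalized) mass."""

    axis: str
    values: np.ndarray
    mass: np.ndarray

    def mean(self) -> float:
        return float(np.dot(self.values, self.mass))

    def mode(self) -> float:
        return float(self.values[int(np.argmax(self.mass))])

    def entropy_bits(self) -> float:
        return _entropy_bits(self.mass)


def _entropy_bits(mass: np.ndarray) -> float:
    m = mass[mass > 0]
    return float(-np.dot(m, np.log2(m)))


def init_prior(
    model: GridModel,
    threshold_prior: str = "uniform",
    spread_prior: SpreadPrior = "uniform",
) -> Posterior:
    """Initial posterior: uniform over the threshold axis, and either
    uniform or Gaussian (renormalized over the grid) over the spread axis;
    axes are independent under the prior."""
    if threshold_prior != "uniform":
        raise InvalidRequestError("only uniform threshold priors are supported")
    grid = model.grid
    mass = np.ones(grid.shape)
    if grid.spread is not None and isinstance(spread_prior, GaussianPrior):
        dens = np.exp(
            -0.5 * ((grid.spread - spread_prior.mean) / spread_prior.sd) ** 2
        )
        i = grid.axes.index("spread")
        shape = [1] * len(grid.shape)
        shape[i] = len(grid.spread)
        mass = mass * dens.reshape(shape)
    elif spread_prior != "uniform" and not isinstance(spread_prior, GaussianPrior):
        raise InvalidRequestError(f"unknown spread prior {spread_prior!r}")
    return Posterior(model=model, mass=mass)


def update_posterior(posterior: Posterior, x: float, response: bool) -> Posterior:
    """Bayes-rule update after observing ``response`` at intensity ``x``."""
    p = posterior.model.prob_correct(x)
    like = p if response else 1.0 - p
    return Posterior(model=posterior.model, mass=posterior.mass * like)


def marginal(posterior: Posterior, axis: str) -> MarginalPosterior:
    """Marginal over one axis, summing the mass over the nuisance axes."""
    axes = posterior.axes
    if axis not in axes:
        raise InvalidRequestError(f"posterior has no axis {axis!r}")
    nuisance = tuple(i for i, a in enumerate(axes) if a != axis)
    mass = posterior.mass.sum(axis=nuisance) if nuisance else posterior.mass
    return MarginalPosterior(
        axis=axis, values=posterior.model.grid.axis_values(axis), mass=mass
    )


def posterior_mean(posterior: Posterior, axis: str = "threshold") -> float:
    """Mass-weighted mean of the given axis."""
    return marginal(posterior, axis).mean()


def _snap_to_stimuli(stimuli: np.ndarray, value) -> np.ndarray:
    """Indices of the stimulus candidates nearest to ``value`` (ties toward
    the smaller intensity)."""
    value = np.asarray(value, float)
    idx = np.searchsorted(stimuli, value)
    idx = np.clip(idx, 1, len(stimuli) - 1)
    left = stimuli[idx - 1]
    right = stimuli[idx]
    choose_left = (value - left) <= (right - value)
    return np.where(choose_left, idx - 1, idx)


def zest_place(posterior: Posterior) -> float:
    """ZEST stimulus placement: the posterior mean of the threshold
    (marginalized over any nuisance axes), snapped to the nearest stimulus
    candidate."""
    mean = posterior_mean(posterior, "threshold")
    stimuli = posterior.model.grid.stimuli
    return float(stimuli[int(_snap_to_stimuli(stimuli, mean))])


def _interest_marginal_entropy(
    joint_flat: np.ndarray, grid: ParameterGrid, interest_axes: tuple[str, ...]
) -> float:
    """Entropy (bits) of the normalized marginal of a flat joint mass."""
    shaped = joint_flat.reshape(grid.shape)
    nuisance = tuple(
        i for i, a in enumerate(grid.axes) if a not in interest_axes
    )
    m = shaped.sum(axis=nuisance) if nuisance else shaped
    total = m.sum()
    if total <= 0:
        return 0.0
    return _entropy_bits((m / total).ravel())


def expected_posterior_entropy(
    posterior: Posterior, x: float, interest_axes: Sequence[str]
) -> float:
    """Expected entropy (bits), after a trial at ``x``, of the posterior
    marginal over ``interest_axes``; the expectation over the two possible
    responses uses the current posterior's predictive probability."""
    interest_axes = tuple(interest_axes)
    grid = posterior.model.grid
    p = posterior.model.prob_correct(x).ravel()
    m = posterior.mass.ravel()
    joint_c = m * p
    joint_i = m * (1.0 - p)
    pc = joint_c.sum()
    h_c = _interest_marginal_entropy(joint_c, grid, interest_axes)
    h_i = _interest_marginal_entropy(joint_i, grid, interest_axes)
    return float(pc * h_c + (1.0 - pc) * h_i)


def _psi_place_index(posterior: Posterior, interest_axes: tuple[str, ...]) -> int:
    """Vectorized argmin of expected posterior entropy over all candidates."""
    grid = posterior.model.grid
    L = posterior.model.likelihood_table            # (S, G)
    m = posterior.mass.ravel()                      # (G,)
    shape = grid.shape
    nuisance = tuple(
        i + 1 for i, a in enumerate(grid.axes) if a not in interest_axes
    )

    def branch_entropy(joint):                      # joint: (S, G)
        shaped = joint.reshape((len(L),) + shape)
        marg = shaped.sum(axis=nuisance) if nuisance else shaped
        marg = marg.reshape(len(L), -1)             # (S, K)
        tot = marg.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(tot > 0, marg / tot, 0.0)
            logq = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), 0.0)
        return -(q * logq).sum(axis=1), tot.ravel()

    h_c, pc = branch_entropy(L * m)
    h_i, p_i = branch_entropy((1.0 - L) * m)
    expected = pc * h_c + p_i * h_i
    return int(np.argmin(expected))  # first minimum = smallest intensity


def psi_place(posterior: Posterior, interest_axes: Sequence[str]) -> float:
    """Psi stimulus placement: the candidate minimizing the expected
    posterior entropy over the parameters of interest; ties break toward
    the smaller intensity."""
    idx = _psi_place_index(posterior, tuple(interest_axes))
    return float(posterior.model.grid.stimuli[idx])


# --------------------------------------------------------------------------
# procedures

_PROC = {
    # name: (has spread axis, has lapse axis, placement, interest axes,
    #        reports sigma)
    "zest_fixed_sigma": (False, False, "zest", (), False),
    "zest2d_theta_sigma": (True, False, "zest", (), True),
    "zest2d_theta": (True, False, "zest", (), False),
    "psi_theta_sigma": (True, False, "psi", ("threshold", "spread"), True),
    "psi_marg_theta_sigma_L": (True, True, "psi", ("threshold", "spread"), True),
    "psi_marg_theta_SL": (True, True, "psi", ("threshold",), False),
    "psi_marg_theta_S": (True, False, "psi", ("threshold",), False),
}

PROCEDURES = tuple(_PROC)


@dataclass(frozen=True)
class ProcedureConfig:
    """Configuration of one adaptive procedure run.

    ``sigma_m`` is required for (and only for) fixed-spread ZEST;
    ``lambda_m`` for every procedure without a lapse axis.  The spread
    prior (uniform or Gaussian) applies only when a spread axis exists.
    """

    procedure: str
    task: TaskSpec
    n_trials: int = 30
    pi: float = 0.75
    sigma_m: Optional[float] = None
    lambda_m: Optional[float] = None
    spread_prior: SpreadPrior = "uniform"
    grid: Optional[ParameterGrid] = None

    def __post_init__(self):
        if self.procedure not in _PROC:
            raise InvalidRequestError(f"unknown procedure {self.procedure!r}")
        has_spread, has_lapse, _, _, _ = _PROC[self.procedure]
        if has_spread and self.sigma_m is not None:
            raise InvalidRequestError(f"{self.procedure} does not take sigma_m")
        if not has_spread and self.sigma_m is None:
            raise InvalidRequestError(f"{self.procedure} requires sigma_m")
        if has_lapse and self.lambda_m is not None:
            raise InvalidRequestError(f"{self.procedure} does not take lambda_m")
        if not has_lapse and self.lambda_m is None:
            raise InvalidRequestError(f"{self.procedure} requires lambda_m")
        if self.n_trials < 1:
            raise InvalidRequestError("n_trials must be >= 1")

    @property
    def placement(self) -> str:
        return _PROC[self.procedure][2]

    @property
    def interest_axes(self) -> tuple[str, ...]:
        return _PROC[self.procedure][3]

    @property
    def reports_sigma(self) -> bool:
        return _PROC[self.procedure][4]

    def build_grid(self, **grid_kwargs) -> ParameterGrid:
        if self.grid is not None:
            return self.grid
        has_spread, has_lapse, _, _, _ = _PROC[self.procedure]
        return default_grid(has_spread, has_lapse, **grid_kwargs)

    def build_model(self) -> GridModel:
        return GridModel(
            grid=self.build_grid(),
            task=self.task,
            pi=self.pi,
            sigma_m=self.sigma_m,
            lambda_m=self.lambda_m,
        )


@dataclass
class EstimateTrace:
    """Per-trial record of one adaptive run."""

    stimulus: np.ndarray
    response: np.ndarray
    theta_hat: np.ndarray
    sigma_hat: Optional[np.ndarray] = None
    config: Optional[ProcedureConfig] = None

    def __len__(self):
        return len(self.stimulus)

    @property
    def final_theta(self) -> float:
        return float(self.theta_hat[-1])


def run_procedure(
    observer: SimulatedObserver,
    config: ProcedureConfig,
    rng: Optional[np.random.Generator] = None,
    uniform_draws: Optional[np.ndarray] = None,
    grid_model: Optional[GridModel] = None,
) -> EstimateTrace:
    """Drive one adaptive procedure against a simulated observer.

    Each trial: place a stimulus (ZEST or Psi rule), draw the observer's
    response, update the posterior, and record the posterior-mean threshold
    estimate (and spread estimate where the procedure reports one).

    ``uniform_draws`` (shape ``(n_trials,)``) substitutes pre-drawn uniforms
    for the response randomness, giving exactly reproducible trajectories
    shared with the batch runner.
    """
    if uniform_draws is None and rng is None:
        raise InvalidRequestError("provide an rng or pre-drawn uniforms")
    model = grid_model if grid_model is not None else config.build_model()
    post = init_prior(model, spread_prior=config.spread_prior)
    stimuli = model.grid.stimuli

    n = config.n_trials
    xs = np.empty(n)
    resp = np.empty(n, dtype=bool)
    th = np.empty(n)
    sh = np.empty(n) if config.reports_sigma else None

    for t in range(n):
        if config.placement == "zest":
            idx = int(_snap_to_stimuli(stimuli,
                                       posterior_mean(post, "threshold")))
        else:
            idx = _psi_place_index(post, config.interest_axes)
        x = float(stimuli[idx])
        p = response_probability(x, observer.model)
        u = uniform_draws[t] if uniform_draws is not None else rng.random()
        r = bool(u < p)
        like = model.likelihood_table[idx].reshape(model.grid.shape)
        if not r:
            like = 1.0 - like
        post = Posterior(model=model, mass=post.mass * like)
        xs[t] = x
        resp[t] = r
        th[t] = posterior_mean(post, "threshold")
        if sh is not None:
            sh[t] = posterior_mean(post, "spread")
    return EstimateTrace(stimulus=xs, response=resp, theta_hat=th,
                         sigma_hat=sh, config=config)


def run_zest_fixed_batch(
    observer: SimulatedObserver,
    config: ProcedureConfig,
    n_runs: int,
    rng: Optional[np.random.Generator] = None,
    uniform_draws: Optional[np.ndarray] = None,
    grid_model: Optional[GridModel] = None,
) -> np.ndarray:
    """Vectorized fixed-spread ZEST: ``n_runs`` independent staircases run
    in lock-step, posterior matrix of shape (n_runs, n_grid).

    Returns the per-trial posterior-mean threshold estimates, shape
    ``(n_runs, n_trials)``.  With the same per-run uniforms this reproduces
    :func:`run_procedure` exactly (asserted in the test suite).
    """
    if config.procedure != "zest_fixed_sigma":
        raise InvalidRequestError("batch runner supports zest_fixed_sigma only")
    if uniform_draws is None:
        if rng is None:
            raise InvalidRequestError("provide an rng or pre-drawn uniforms")
        uniform_draws = rng.random((n_runs, config.n_trials))
    model = grid_model if grid_model is not None else config.build_model()
    theta_axis = model.grid.threshold
    stimuli = model.grid.stimuli
    L = model.likelihood_table                     # (S, G)
    p_true = np.asarray(
        response_probability(stimuli, observer.model), float
    )

    post = np.full((n_runs, len(theta_axis)), 1.0 / len(theta_axis))
    out = np.empty((n_runs, config.n_trials))
    for t in range(config.n_trials):
        means = post @ theta_axis
        idx = _snap_to_stimuli(stimuli, means)
        resp = uniform_draws[:, t] < p_true[idx]
        rows = L[idx]                              # (n_runs, G)
        post = post * np.where(resp[:, None], rows, 1.0 - rows)
        tot = post.sum(axis=1, keepdims=True)
        if np.any(tot <= 0) or np.any(~np.isfinite(tot)):
            raise DegeneratePosteriorError("posterior mass vanished")
        post /= tot
        out[:, t] = post @ theta_axis
    return out
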