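"""Monte-Carlo evaluation of adaptive threshold procedures.

Three experiment families are covered:

* spread-mismatch surfaces — bias and SD of fixed-spread ZEST as a
  function of the assumed spread, for observers of known spread;
* the percentile sweep — candidate assumed spreads are the 5th–95th
  percentiles (step 5) of a population's spread distribution, each
  evaluated by simulating staircases for every observer; the optimal
  spread minimizes |mean bias x SD|;
* procedure comparison — bias and SD per procedure per trial count, for a
  single standard observer or a whole population, under uniform or
  Gaussian spread priors.

Threshold bias is the estimated minus the true threshold in log10 arcsec;
its antilog (the bias factor) is the multiplicative error on the linear
arcsec scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bayes import (
    GaussianPrior,
    GridModel,
    ProcedureConfig,
    SpreadPrior,
    default_grid,
    run_procedure,
    run_zest_fixed_batch,
)
from .model import SimulatedObserver, TaskSpec
from .population import observers_from_table

__all__ = [
    "BiasSummary",
    "SweepResult",
    "bias_factor",
    "bias_for_spread",
    "percentile_sweep",
    "procedure_estimates",
    "trace_bias_summary",
    "compare_procedures",
    "mismatch_surface",
    "standard_procedure_config",
    "RECOMMENDED_SIGMA_M",
    "FIXED_LAPSE_M",
]

#: recommended assumed spreads (log10 arcsec) for fixed-spread ZEST
RECOMMENDED_SIGMA_M = {2: 1.7, 4: 1.5}
#: fixed model lapse rates, both corresponding to lambda* = 0.04
FIXED_LAPSE_M = {2: 0.02, 4: 0.03}

SWEEP_PERCENTILES = tuple(range(5, 100, 5))  # 5..95 step 5 -> 19 values


def bias_factor(mean_bias: float) -> float:
    """Multiplicative threshold error: 10^(mean log10 bias)."""
    return float(10.0 ** np.asarray(mean_bias, float))


@dataclass
class BiasSummary:
    """Bias/precision of fixed-spread ZEST at one assumed spread."""

    sigma_m: float
    n_trials: int
    mean_bias: float            # mean over observers of per-observer means
    sd: float                   # SD of the pooled per-run bias distribution
    n_observers: int
    n_sims: int
    per_observer_bias: np.ndarray = field(repr=False, default=None)

    @property
    def n_staircases(self) -> int:
        return self.n_observers * self.n_sims

    @property
    def factor(self) -> float:
        return bias_factor(self.mean_bias)


def bias_for_spread(
    observers: Union[pd.DataFrame, Sequence[SimulatedObserver]],
    sigma_m: float,
    lapse_mode: Union[str, float],
    n_sims: int,
    n_trials: int,
    task: TaskSpec,
    rng: np.random.Generator,
    grid_kwargs: Optional[dict] = None,
) -> BiasSummary:
    """Mean bias and pooled SD of fixed-spread ZEST over a population.

    ``lapse_mode`` is either ``"subject"`` (the model lapse equals each
    observer's own) or a number (one fixed model lapse for all).  For each
    observer, ``n_sims`` staircases of ``n_trials`` trials are run and the
    bias of the final posterior-mean estimate recorded.
    """
    if isinstance(observers, pd.DataFrame):
        observers = observers_from_table(observers)
    grid_kwargs = grid_kwargs or {}
    grid = default_grid(False, False, **grid_kwargs)

    # one grid model per distinct lapse (shared cache in fixed-lapse mode)
    models: dict[float, GridModel] = {}

    def model_for(lam: float) -> GridModel:
        if lam not in models:
            models[lam] = GridModel(grid=grid, task=task, sigma_m=sigma_m,
                                    lambda_m=lam)
        return models[lam]

    per_obs_mean = np.empty(len(observers))
    pooled = np.empty((len(observers), n_sims))
    for i, obs in enumerate(observers):
        lam = obs.model.lapse if lapse_mode == "subject" else float(lapse_mode)
        config = ProcedureConfig(
            "zest_fixed_sigma", task=task, n_trials=n_trials,
            sigma_m=sigma_m, lambda_m=lam,
        )
        est = run_zest_fixed_batch(obs, config, n_sims, rng=rng,
                                   grid_model=model_for(lam))
        bias = est[:, -1] - obs.true_threshold
        per_obs_mean[i] = bias.mean()
        pooled[i] = bias
    return BiasSummary(
        sigma_m=float(sigma_m), n_trials=n_trials,
        mean_bias=float(per_obs_mean.mean()),
        sd=float(pooled.std(ddof=0)),
        n_observers=len(observers), n_sims=n_sims,
        per_observer_bias=per_obs_mean,
    )


@dataclass
class SweepResult:
    """Percentile sweep over candidate assumed spreads."""

    table: pd.DataFrame          # percentile, sigma_m, mean_bias, sd, product
    optimal_index: int
    n_staircases: int

    @property
    def optimal_percentile(self) -> int:
        return int(self.table["percentile"].iloc[self.optimal_index])

    @property
    def optimal_sigma_m(self) -> float:
        return float(self.table["sigma_m"].iloc[self.optimal_index])


def percentile_sweep(
    observers: Union[pd.DataFrame, Sequence[SimulatedObserver]],
    lapse_mode: Union[str, float],
    n_sims: int,
    n_trials: int,
    task: TaskSpec,
    rng: np.random.Generator,
    percentiles: Sequence[int] = SWEEP_PERCENTILES,
    grid_kwargs: Optional[dict] = None,
) -> SweepResult:
    """Evaluate candidate assumed spreads at the population's spread
    percentiles (linear interpolation between order statistics) and pick
    the one minimizing |mean bias x SD| (ties toward the smaller spread).
    """
    if isinstance(observers, pd.DataFrame):
        observers = observers_from_table(observers)
    if len(observers) < 2:
        raise ValueError("need at least two observers for a percentile sweep")
    spreads = np.array([o.model.spread for o in observers])
    candidates = np.percentile(spreads, percentiles)  # linear interpolation
    rows = []
    total = 0
    for pct, sigma_m in zip(percentiles, candidates):
        s = bias_for_spread(observers, float(sigma_m), lapse_mode, n_sims,
                            n_trials, task, rng, grid_kwargs)
        total += s.n_staircases
        rows.append({
            "percentile": pct, "sigma_m": s.sigma_m,
            "mean_bias": s.mean_bias, "sd": s.sd,
            "abs_bias_x_sd": abs(s.mean_bias * s.sd),
            "bias_factor": s.factor,
        })
    table = pd.DataFrame(rows)
    optimal = int(np.argmin(table["abs_bias_x_sd"].to_numpy()))
    return SweepResult(table=table, optimal_index=optimal, n_staircases=total)


def standard_procedure_config(
    procedure: str,
    task: TaskSpec,
    n_trials: int = 30,
    spread_prior: SpreadPrior = "uniform",
    grid_kwargs: Optional[dict] = None,
) -> ProcedureConfig:
    """Procedure config with the recommended defaults: assumed spread 1.7
    (2AFC) / 1.5 (4AFC) for fixed-spread ZEST and fixed model lapse 0.02 /
    0.03 (lambda* = 0.04) wherever the lapse is not marginalized."""
    n_alt = task.n_alternatives
    kwargs: dict = {"task": task, "n_trials": n_trials}
    if procedure == "zest_fixed_sigma":
        kwargs["sigma_m"] = RECOMMENDED_SIGMA_M[n_alt]
        kwargs["lambda_m"] = FIXED_LAPSE_M[n_alt]
    elif procedure in ("zest2d_theta_sigma", "zest2d_theta",
                       "psi_theta_sigma", "psi_marg_theta_S"):
        kwargs["lambda_m"] = FIXED_LAPSE_M[n_alt]
        kwargs["spread_prior"] = spread_prior
    elif procedure in ("psi_marg_theta_sigma_L", "psi_marg_theta_SL"):
        kwargs["spread_prior"] = spread_prior
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
    config = ProcedureConfig(procedure, **kwargs)
    if grid_kwargs:
        return ProcedureConfig(procedure, grid=config.build_grid(**grid_kwargs),
                               **kwargs)
    return config


def procedure_estimates(
    observer: SimulatedObserver,
    config: ProcedureConfig,
    n_sims: int,
    rng: np.random.Generator,
    grid_model: Optional[GridModel] = None,
) -> np.ndarray:
    """Per-trial threshold estimates over ``n_sims`` independent runs,
    shape (n_sims, n_trials); the fixed-spread ZEST path is vectorized."""
    if grid_model is None:
        grid_model = config.build_model()
    if config.procedure == "zest_fixed_sigma":
        return run_zest_fixed_batch(observer, config, n_sims, rng=rng,
                                    grid_model=grid_model)
    out = np.empty((n_sims, config.n_trials))
    for i in range(n_sims):
        trace = run_procedure(observer, config, rng=rng,
                              grid_model=grid_model)
        out[i] = trace.theta_hat
    return out


def trace_bias_summary(
    estimates: np.ndarray,
    true_threshold: float,
    trial_window: tuple[int, int] = (20, 30),
) -> dict:
    """Bias factor and estimate SD over a window of trial counts (1-based,
    inclusive): the per-trial bias factor 10^(mean estimate - true) is
    averaged over the window, and the SD of the estimates is reported at
    its maximum and minimum within the window."""
    lo, hi = trial_window
    window = estimates[:, lo - 1:hi]
    mean_est = window.mean(axis=0)
    sds = window.std(axis=0, ddof=0)
    factors = 10.0 ** (mean_est - true_threshold)
    return {
        "bias_factor": float(factors.mean()),
        "mean_bias": float((mean_est - true_threshold).mean()),
        "sd_max": float(sds.max()),
        "sd_min": float(sds.min()),
    }


def compare_procedures(
    observers: Union[str, pd.DataFrame, Sequence[SimulatedObserver]],
    procedures: Sequence[str],
    task: TaskSpec,
    spread_prior: SpreadPrior = "uniform",
    trial_counts: Sequence[int] = (10, 20, 30, 50),
    n_sims: int = 1000,
    rng: Optional[np.random.Generator] = None,
    grid_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Tidy bias/SD table over procedures x trial counts.

    ``observers`` may be ``"standard"`` (the theta=1.5, sigma=1 observer
    with the task's standard lapse), an observer table, or a sequence of
    observers.  Each run of ``max(trial_counts)`` trials yields estimates
    at every requested count.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(observers, str):
        if observers != "standard":
            raise ValueError("observer set must be 'standard', a table, "
                             "or a sequence")
        observers = [SimulatedObserver.standard(task)]
    elif isinstance(observers, pd.DataFrame):
        observers = observers_from_table(observers)
    trial_counts = sorted(trial_counts)
    n_max = trial_counts[-1]
    prior_name = (spread_prior if isinstance(spread_prior, str)
                  else f"gaussian({spread_prior.mean},{spread_prior.sd})")
    rows = []
    for proc in procedures:
        config = standard_procedure_config(proc, task, n_trials=n_max,
                                           spread_prior=spread_prior,
                                           grid_kwargs=grid_kwargs)
        grid_model = config.build_model()
        bias_runs = {t: [] for t in trial_counts}
        for obs in observers:
            est = procedure_estimates(obs, config, n_sims, rng, grid_model)
            for t in trial_counts:
                bias_runs[t].append(est[:, t - 1] - obs.true_threshold)
        for t in trial_counts:
            pooled = np.concatenate(bias_runs[t])
            per_obs = np.array([b.mean() for b in bias_runs[t]])
            rows.append({
                "procedure": proc, "prior": prior_name,
                "task": f"{task.n_alternatives}afc", "n_trials": t,
                "mean_bias": float(per_obs.mean()),
                "sd": float(pooled.std(ddof=0)),
                "bias_factor": bias_factor(per_obs.mean()),
                "n_sims": n_sims, "n_observers": len(observers),
            })
    return pd.DataFrame(rows)


def mismatch_surface(
    task: TaskSpec,
    sigma_s_values: Sequence[float] = (0.5, 1.5, 2.5),
    sigma_m_values: Sequence[float] = (0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    n_sims: int = 2000,
    n_trials: int = 30,
    theta_s: float = 1.5,
    rng: Optional[np.random.Generator] = None,
    grid_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Bias/SD of fixed-spread ZEST as a function of the assumed spread,
    for observers of fixed threshold and varying spread (the assumed and
    true lapse rates are equal, at the task's standard value)."""
    if rng is None:
        rng = np.random.default_rng()
    lam = FIXED_LAPSE_M[task.n_alternatives]
    rows = []
    for sigma_s in sigma_s_values:
        obs = SimulatedObserver.from_parameters(theta_s, sigma_s, lam, task)
        for sigma_m in sigma_m_values:
            s = bias_for_spread([obs], sigma_m, lam, n_sims, n_trials, task,
                                rng, grid_kwargs)
            rows.append({
                "task": f"{task.n_alternatives}afc",
                "sigma_s": sigma_s, "sigma_m": float(sigma_m),
                "mean_bias": s.mean_bias, "sd": s.sd,
            })
    return pd.DataFrame(rows)
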