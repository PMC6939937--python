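"""Weighted one-up/one-down staircase for disparity detection sessions.

The rule subtracts ``step_down`` (0.15 log10 arcsec) after a correct
response and adds ``step_up`` (0.45) after an incorrect one, so the level
converges on the intensity where the probability of a correct response is
``step_up / (step_up + step_down)`` = 0.75.  Sessions start with a cued
practice trial at 3.0 log10 arcsec (1000 arcsec).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import SimulatedObserver, TaskSpec, response_probability

__all__ = [
    "StaircaseConfig",
    "TrialRecord",
    "Session",
    "next_level",
    "equilibrium_probability",
    "run_updown",
]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StaircaseConfig:
    start_level: float = 3.0
    step_down: float = 0.15
    step_up: float = 0.45
    n_trials: int = 80
    practice_first_trial: bool = True
    level_bounds: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self):
        if self.step_down <= 0 or self.step_up <= 0:
            raise InvalidConfigError("steps must be positive")
        if self.n_trials < 1:
            raise InvalidConfigError("n_trials must be >= 1")
        if self.level_bounds[0] >= self.level_bounds[1]:
            raise InvalidConfigError("level_bounds must be ordered")


@dataclass(frozen=True)
class TrialRecord:
    index: int          # 1-based
    level: float        # log10 arcsec
    response: bool
    practice: bool = False


@dataclass
class Session:
    task: TaskSpec
    trials: list[TrialRecord] = field(default_factory=list)
    observer_id: str = ""

    def __len__(self):
        return len(self.trials)

    @property
    def levels(self) -> np.ndarray:
        return np.array([t.level for t in self.trials])

    @property
    def responses(self) -> np.ndarray:
        return np.array([t.response for t in self.trials], dtype=bool)


def next_level(level: float, response: bool, config: StaircaseConfig) -> float:
    """Level for the next trial given the response at the current one."""
    lo, hi = config.level_bounds
    nxt = level - config.step_down if response else level + config.step_up
    return float(min(max(nxt, lo), hi))


def equilibrium_probability(config: StaircaseConfig) -> float:
    """Correct-response probability at which the expected level change is 0.

    Solves ``p * step_down = (1 - p) * step_up``.
    """
    return config.step_up / (config.step_up + config.step_down)


def run_updown(
    observer: SimulatedObserver,
    config: StaircaseConfig = StaircaseConfig(),
    rng: Optional[np.random.Generator] = None,
    responses: Optional[Sequence[bool]] = None,
) -> Session:
    """Run a staircase session against a simulated observer.

    ``responses`` replays a fixed response sequence instead of drawing from
    the observer (deterministic trajectory reconstruction / testing).  On
    the cued practice trial the observer responds correctly with probability
    ``max(Psi(start), 0.95)``: the colour cue makes the first trial nearly
    trivially easy regardless of stereoacuity.
    """
    if responses is None and rng is None:
        raise InvalidConfigError("provide an rng or a replay response sequence")
    session = Session(task=TaskSpec(round(1.0 / observer.model.guess)),
                      observer_id=observer.identifier)
    level = float(config.start_level)
    for i in range(1, config.n_trials + 1):
        practice = config.practice_first_trial and i == 1
        if responses is not None:
            resp = bool(responses[i - 1])
        else:
            p = response_probability(level, observer.model)
            if practice:
                p = max(p, 0.95)
            resp = bool(rng.random() < p)
        session.trials.append(
            TrialRecord(index=i, level=level, response=resp, practice=practice)
        )
        level = next_level(level, resp, config)
    return session
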