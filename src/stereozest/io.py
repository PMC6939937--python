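"""File formats and run configuration.

Session logs, estimate traces, fit tables and Monte-Carlo summaries are
plain CSV (UTF-8, '.' decimal, header mandatory); run configurations are
YAML with strict key validation (unknown keys are errors, so a typo in a
procedure name cannot silently fall back to a default).  Stochastic
outputs embed the seed and a hash of the configuration that produced them,
so re-running a config reproduces the files exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .bayes import EstimateTrace
from .model import TaskSpec
from .staircase import Session, StaircaseConfig, TrialRecord

__all__ = [
    "SESSION_COLUMNS",
    "config_hash",
    "load_config",
    "write_session_csv",
    "read_session_csv",
    "write_trace_csv",
    "write_fit_table",
]

SESSION_COLUMNS = ["trial", "level_log10_arcsec", "correct", "practice"]


class ConfigError(ValueError):
    pass


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


_KNOWN_KEYS = {
    "command", "seed", "task", "procedure", "sigma_m", "lambda_m",
    "n_trials", "n_sims", "spread_prior", "prior_mean", "prior_sd",
    "profile", "n_observers", "lapse_mode", "percentiles", "trial_counts",
    "procedures", "theta_step", "stimulus_step", "n_spread", "output",
    "start_level", "step_down", "step_up", "practice_first_trial",
}


def load_config(path) -> dict:
    """Load a YAML run configuration; unknown keys are errors."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_session_csv(session: Session, path, seed: Optional[int] = None,
                      cfg_hash: Optional[str] = None) -> None:
    df = pd.DataFrame({
        "trial": [t.index for t in session.trials],
        "level_log10_arcsec": [t.level for t in session.trials],
        "correct": [int(t.response) for t in session.trials],
        "practice": [int(t.practice) for t in session.trials],
    })
    _write_with_provenance(df, path, session.task, seed, cfg_hash)


def _write_with_provenance(df: pd.DataFrame, path, task: Optional[TaskSpec],
                           seed, cfg_hash) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        meta = []
        if task is not None:
            meta.append(f"task={task.n_alternatives}afc")
        if seed is not None:
            meta.append(f"seed={seed}")
        if cfg_hash is not None:
            meta.append(f"config_hash={cfg_hash}")
        if meta:
            fh.write("# " + " ".join(meta) + "\n")
        df.to_csv(fh, index=False)


def read_session_csv(path, task: Optional[TaskSpec] = None) -> Session:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("task=") and task is None:
                    task = TaskSpec.from_name(tok.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"session file missing columns {sorted(missing)}")
    if task is None:
        raise ConfigError("task not recorded in file; pass task explicitly")
    session = Session(task=task, observer_id=path.stem)
    for row in df.itertuples(index=False):
        session.trials.append(TrialRecord(
            index=int(row.trial), level=float(row.level_log10_arcsec),
            response=bool(row.correct), practice=bool(row.practice),
        ))
    return session


def write_trace_csv(trace: EstimateTrace, path, seed: Optional[int] = None,
                    cfg_hash: Optional[str] = None) -> None:
    df = pd.DataFrame({
        "trial": range(1, len(trace) + 1),
        "stimulus": trace.stimulus,
        "response": trace.response.astype(int),
        "theta_hat": trace.theta_hat,
    })
    if trace.sigma_hat is not None:
        df["sigma_hat"] = trace.sigma_hat
    task = trace.config.task if trace.config is not None else None
    _write_with_provenance(df, path, task, seed, cfg_hash)


def write_fit_table(fits: pd.DataFrame, path, seed: Optional[int] = None,
                    cfg_hash: Optional[str] = None) -> None:
    _write_with_provenance(fits, path, None, seed, cfg_hash)


def staircase_config_from_dict(cfg: dict) -> StaircaseConfig:
    kwargs = {}
    for key in ("start_level", "step_down", "step_up", "n_trials",
                "practice_first_trial"):
        if key in cfg:
            kwargs[key] = cfg[key]
    return StaircaseConfig(**kwargs)
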