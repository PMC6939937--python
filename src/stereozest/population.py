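"""Virtual-observer populations for Monte-Carlo evaluation.

Each of the three stereoacuity experiments (2AFC global, 4AFC global, 4AFC
local) is summarized by the mean and SD of the fitted thresholds (log10
arcsec), spreads (log10 arcsec) and lapse-at-all probabilities (lambda*),
plus — for the 4AFC experiments, where threshold and spread correlate — a
linear regression of spread on threshold.  Populations are sampled from
truncated normals on these moments; for the 4AFC profiles the spread is
generated through the regression with a residual SD back-solved to
preserve the printed marginal spread SD.  Real per-subject tables (CSV or
XLSX) can be ingested instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .model import SimulatedObserver, TaskSpec, lapse_from_lapse_star
from .staircase import Session, StaircaseConfig, run_updown

__all__ = [
    "PopulationProfile",
    "PROFILE_NAMES",
    "builtin_profile",
    "sample_population",
    "observers_from_table",
    "load_subject_table",
    "save_subject_table",
    "sample_sessions",
]

PROFILE_NAMES = ("exp1_2AFC_g", "exp2_4AFC_g", "exp3_4AFC_l")

# validity ranges shared with the fit-inclusion screen
_THETA_RANGE_LOG10 = (0.0, float(np.log10(500.0)))
_SIGMA_RANGE = (0.01, 7.0)
_LAPSE_STAR_RANGE = (0.0, 0.08)


class InvalidProfileError(ValueError):
    pass


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationProfile:
    """Moments and truncation ranges describing one experiment's sample."""

    name: str
    n: int
    theta_mean: float
    theta_sd: float
    sigma_mean: float
    sigma_sd: float
    lapse_star_mean: float
    lapse_star_sd: float
    task: TaskSpec
    sigma_on_theta: Optional[tuple[float, float]] = None  # (intercept, slope)
    theta_range: tuple[float, float] = _THETA_RANGE_LOG10
    sigma_range: tuple[float, float] = _SIGMA_RANGE
    lapse_star_range: tuple[float, float] = _LAPSE_STAR_RANGE

    def __post_init__(self):
        for sd in (self.theta_sd, self.sigma_sd, self.lapse_star_sd):
            if sd < 0:
                raise InvalidProfileError("SDs must be >= 0")
        for mean, rng in (
            (self.theta_mean, self.theta_range),
            (self.sigma_mean, self.sigma_range),
            (self.lapse_star_mean, self.lapse_star_range),
        ):
            if not rng[0] <= mean <= rng[1]:
                raise InvalidProfileError(
                    f"mean {mean} outside truncation range {rng}"
                )


_PROFILES = {
    "exp1_2AFC_g": PopulationProfile(
        name="exp1_2AFC_g", n=71,
        theta_mean=1.528, theta_sd=0.300,
        sigma_mean=1.005, sigma_sd=0.776,
        lapse_star_mean=0.0207, lapse_star_sd=0.042,
        task=TaskSpec(2), sigma_on_theta=None,
    ),
    "exp2_4AFC_g": PopulationProfile(
        name="exp2_4AFC_g", n=68,
        theta_mean=1.540, theta_sd=0.203,
        sigma_mean=1.186, sigma_sd=0.740,
        lapse_star_mean=0.0308, lapse_star_sd=0.0361,
        task=TaskSpec(4), sigma_on_theta=(-0.823, 1.305),
    ),
    "exp3_4AFC_l": PopulationProfile(
        name="exp3_4AFC_l", n=76,
        theta_mean=1.568, theta_sd=0.230,
        sigma_mean=1.306, sigma_sd=0.632,
        lapse_star_mean=0.0276, lapse_star_sd=0.036,
        task=TaskSpec(4), sigma_on_theta=(-0.159, 0.934),
    ),
}


def builtin_profile(name: str) -> PopulationProfile:
    """Profile of one of the three experiments by name."""
    try:
        return _PROFILES[name]
    except KeyError:
        raise InvalidProfileError(
            f"unknown profile {name!r}; choose from {PROFILE_NAMES}"
        ) from None


@lru_cache(maxsize=None)
def _matched_truncnorm_params(mean: float, sd: float, lo: float,
                              hi: float) -> tuple[float, float]:
    """Underlying (loc, scale) whose truncation to [lo, hi] has the target
    mean and SD.

    Naively truncating N(mean, sd) shifts the moments (for a heavily
    left-truncated spread distribution, by a sizeable fraction of the SD),
    so the parameters are solved for instead.  The mean residual is
    weighted heavily: when the target SD is unreachable within the interval
    (possible for the strongly non-normal lapse distribution), the mean is
    matched exactly and the SD saturates at the family's maximum.
    """

    def resid(params):
        loc, log_scale = params
        s = np.exp(log_scale)
        a, b = (lo - loc) / s, (hi - loc) / s
        m, v = truncnorm.stats(a, b, loc=loc, scale=s, moments="mv")
        return [10.0 * (float(m) - mean) / sd,
                (float(np.sqrt(v)) - sd) / sd]

    res = least_squares(
        resid, x0=[mean, np.log(sd)],
        bounds=([lo - 10 * sd, np.log(sd) - 4],
                [hi + 10 * sd, np.log(sd) + 4]),
    )
    loc, log_scale = res.x
    return float(loc), float(np.exp(log_scale))


def _truncated_normal(mean, sd, bounds, size, rng) -> np.ndarray:
    lo, hi = bounds
    if sd == 0:
        return np.full(size, mean)
    loc, scale = _matched_truncnorm_params(float(mean), float(sd),
                                           float(lo), float(hi))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size,
                         random_state=rng)


def sample_population(
    profile: PopulationProfile,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Sample n virtual observers from a profile.

    Columns: id, theta_log10, sigma, lambda (lapse rate), lambda_star,
    task.  Thresholds and lambda* come from truncated normals on the
    profile moments; spreads come from the spread-on-threshold regression
    (where the profile has one) with residual SD solved from
    ``sd_sigma^2 = b^2 sd_theta^2 + sd_eps^2``, else independently.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n is None:
        n = profile.n
    if n < 1:
        raise InvalidProfileError("n must be >= 1")
    theta = _truncated_normal(profile.theta_mean, profile.theta_sd,
                              profile.theta_range, n, rng)
    if profile.sigma_on_theta is not None:
        a, b = profile.sigma_on_theta
        resid_var = profile.sigma_sd**2 - (b * profile.theta_sd) ** 2
        if resid_var < 0:
            raise InvalidProfileError(
                "regression slope implies more spread variance than marginal SD"
            )
        mu = a + b * theta
        eps = rng.normal(0.0, np.sqrt(resid_var), size=n)
        sigma = np.clip(mu + eps, *profile.sigma_range)
    else:
        sigma = _truncated_normal(profile.sigma_mean, profile.sigma_sd,
                                  profile.sigma_range, n, rng)
    lapse_star = _truncated_normal(
        profile.lapse_star_mean, profile.lapse_star_sd,
        profile.lapse_star_range, n, rng,
    )
    lam = lapse_from_lapse_star(lapse_star, profile.task.guess)
    return pd.DataFrame({
        "id": [f"{profile.name}_{i:04d}" for i in range(n)],
        "theta_log10": theta,
        "sigma": sigma,
        "lambda": lam,
        "lambda_star": lapse_star,
        "task": f"{profile.task.n_alternatives}afc",
    })


def observers_from_table(table: pd.DataFrame, pi: float = 0.75
                         ) -> list[SimulatedObserver]:
    """Instantiate simulated observers from an observer table."""
    out = []
    for _, row in table.iterrows():
        task = TaskSpec.from_name(str(row["task"]))
        out.append(SimulatedObserver.from_parameters(
            float(row["theta_log10"]), float(row["sigma"]),
            float(row["lambda"]), task, pi, str(row["id"])))
    return out


_COLUMN_ALIASES = {
    "theta_log10": ("theta_log10", "theta", "threshold", "threshold_log10"),
    "sigma": ("sigma", "spread"),
    "lambda": ("lambda", "lapse", "lambda_rate"),
    "id": ("id", "subject", "participant", "subject_id"),
    "task": ("task", "afc", "n_alternatives"),
}


def load_subject_table(path, task: Optional[str] = None,
                       theta_unit: str = "log10") -> pd.DataFrame:
    """Load a per-subject parameter table from CSV or XLSX.

    Column names are matched case-insensitively against common aliases
    (theta/threshold, sigma/spread, lambda/lapse...).  ``theta_unit`` may
    be "log10" or "arcsec".  Rows with parameters outside the validity
    ranges (theta in [1, 500] arcsec, sigma in [0.01, 7]) are dropped; the
    dropped count is stored in ``df.attrs['n_dropped']``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path} contains no rows")
    lower = {c.lower().strip(): c for c in df.columns}

    def find(target, required=True):
        for alias in _COLUMN_ALIASES[target]:
            if alias in lower:
                return lower[alias]
        if required:
            raise FormatError(f"no column for {target!r} in {list(df.columns)}")
        return None

    out = pd.DataFrame()
    theta_col = find("theta_log10")
    theta = pd.to_numeric(df[theta_col], errors="coerce")
    if theta_unit == "arcsec":
        theta = np.log10(theta)
    elif theta_unit != "log10":
        raise FormatError("theta_unit must be 'log10' or 'arcsec'")
    out["theta_log10"] = theta
    out["sigma"] = pd.to_numeric(df[find("sigma")], errors="coerce")
    out["lambda"] = pd.to_numeric(df[find("lambda")], errors="coerce")
    id_col = find("id", required=False)
    out["id"] = (df[id_col].astype(str) if id_col
                 else [f"subject_{i:04d}" for i in range(len(df))])
    task_col = find("task", required=False)
    if task_col:
        out["task"] = df[task_col].astype(str).str.lower()
    elif task is not None:
        out["task"] = task.lower()
    else:
        raise FormatError("no task column; pass task='2afc' or '4afc'")

    valid = (
        out["theta_log10"].between(*_THETA_RANGE_LOG10)
        & out["sigma"].between(*_SIGMA_RANGE)
        & out["lambda"].ge(0)
        & out["theta_log10"].notna()
    )
    dropped = int((~valid).sum())
    out = out[valid].reset_index(drop=True)
    out = out[["id", "theta_log10", "sigma", "lambda", "task"]]
    out.attrs["n_dropped"] = dropped
    return out


def save_subject_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in ("id", "theta_log10", "sigma", "lambda", "task")
            if c in table.columns]
    table[cols].to_csv(path, index=False)


def sample_sessions(
    observer: SimulatedObserver,
    config: StaircaseConfig,
    n_sessions: int,
    rng: np.random.Generator,
) -> list[Session]:
    """Independent seeded staircase sessions against one observer."""
    return [run_updown(observer, config, rng) for _ in range(n_sessions)]
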