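"""Maximum-likelihood fitting, deviance, and inclusion screening."""

import numpy as np
import pytest

from stereozest import (
    AggregatedData,
    FitResult,
    TASK_4AFC,
    aggregate,
    deviance,
    fit_ml,
    model_probability,
    negative_log_likelihood,
    p_deviance,
    passes_inclusion,
)
from stereozest.fit import EmptyDataError, NonIdentifiableError
from stereozest.staircase import Session, TrialRecord
from stereozest.model import TaskSpec


def make_session(levels, responses, practice_first=False):
    s = Session(task=TASK_4AFC)
    for i, (lv, r) in enumerate(zip(levels, responses), start=1):
        s.trials.append(TrialRecord(index=i, level=lv, response=r,
                                    practice=practice_first and i == 1))
    return s


def test_aggregate_counts():
    s = make_session([2.0, 2.0, 2.0], [True, True, False])
    d = aggregate(s)
    assert d.level.tolist() == [2.0]
    assert d.n.tolist() == [3] and d.k.tolist() == [2]


def test_aggregate_excludes_practice():
    s = make_session([3.0, 2.0, 2.0], [True, True, False],
                     practice_first=True)
    d = aggregate(s, exclude_practice=True)
    assert 3.0 not in d.level
    assert d.total_trials == 2
    d_all = aggregate(s, exclude_practice=False)
    assert d_all.total_trials == 3


def test_aggregate_conserves_counts(short_session):
    assert aggregate(short_session, exclude_practice=False).total_trials == 80
    assert aggregate(short_session, exclude_practice=True).total_trials == 79


def test_aggregate_empty_raises():
    with pytest.raises(EmptyDataError):
        aggregate(Session(task=TASK_4AFC))


def test_nll_hand_value():
    """Single level, n=10, k=7 at Psi=0.7: -[7 ln .7 + 3 ln .3] = 6.1086."""
    # choose theta so that Psi(level)=0.7 exactly: put level at threshold
    # with pi=0.7
    d = AggregatedData(np.array([1.5]), np.array([10]), np.array([7]))
    val = negative_log_likelihood(1.5, 1.0, 0.03, d, guess=0.25, pi=0.7)
    assert val == pytest.approx(6.1086, abs=1e-4)


def test_nll_penalizes_constraint_violations():
    d = AggregatedData(np.array([1.0, 1.5, 2.0]), np.array([5, 5, 5]),
                       np.array([2, 4, 5]))
    assert negative_log_likelihood(1.5, -1.0, 0.03, d, 0.25) >= 1e12
    assert negative_log_likelihood(1.5, 1.0, 0.07, d, 0.25) >= 1e12
    assert np.isfinite(negative_log_likelihood(1.5, 1.0, 0.03, d, 0.25))


def test_nll_minimum_near_truth():
    """On data at the exact model probabilities, the truth beats nearby
    parameter perturbations."""
    levels = np.arange(0.5, 2.6, 0.25)
    truth = (1.5, 1.0, 0.03)
    p = model_probability(levels, *truth, TASK_4AFC, 0.75)
    n = np.full(len(levels), 1000)
    k = np.round(n * p).astype(int)
    d = AggregatedData(levels, n, k)
    base = negative_log_likelihood(*truth, d, 0.25)
    for delta in [(0.1, 0, 0), (-0.1, 0, 0), (0, 0.3, 0), (0, -0.3, 0),
                  (0, 0, 0.02)]:
        perturbed = tuple(t + dd for t, dd in zip(truth, delta))
        assert negative_log_likelihood(*perturbed, d, 0.25) > base


def test_deviance_hand_values():
    d = AggregatedData(np.array([1.5]), np.array([10]), np.array([7]))
    fit = FitResult(theta=1.5, sigma=1.0, lapse=0.03, guess=0.25, pi=0.7,
                    nll=0.0, dev=0.0)
    # fitted probability at the level is exactly pi = 0.7 -> Dev vs k/n
    got = deviance(d, fit)
    want = 2 * (7 * np.log(0.7 / 0.7) + 3 * np.log(0.3 / 0.3))
    assert got == pytest.approx(want, abs=1e-12)
    # p_hat = 0.5: 2[7 ln 1.4 + 3 ln 0.6] = 1.646
    k, n, p = 7.0, 10.0, 0.5
    dev = 2 * (k * np.log(k / (n * p)) + (n - k) * np.log((n - k) /
                                                         (n * (1 - p))))
    assert dev == pytest.approx(1.646, abs=1e-3)


def test_deviance_identity_with_likelihood(short_session):
    """Dev = 2 (loglik_saturated - loglik_fitted) on real session data."""
    d = aggregate(short_session)
    fit = fit_ml(d, guess=0.25)
    ll_fit = -negative_log_likelihood(fit.theta, fit.sigma, fit.lapse, d,
                                      0.25)
    phat = d.k / d.n
    ll_sat = 0.0
    for ki, ni, pi_ in zip(d.k, d.n, phat):
        if ki > 0:
            ll_sat += ki * np.log(pi_)
        if ni - ki > 0:
            ll_sat += (ni - ki) * np.log(1 - pi_)
    assert fit.dev == pytest.approx(2 * (ll_sat - ll_fit), abs=1e-8)


def test_fit_recovers_single_dataset():
    """A large synthetic dataset is recovered close to the truth and the
    fitted threshold satisfies Psi(theta_hat) = 0.75."""
    levels = np.arange(0.3, 2.81, 0.25)
    truth = (1.5, 1.0, 0.03)
    p = model_probability(levels, *truth, TASK_4AFC, 0.75)
    rng = np.random.default_rng(8)
    n = np.full(len(levels), 400)
    d = AggregatedData(levels, n, rng.binomial(n, p))
    fit = fit_ml(d, guess=0.25)
    assert fit.theta == pytest.approx(1.5, abs=0.06)
    assert fit.sigma == pytest.approx(1.0, abs=0.3)
    assert fit.lapse == pytest.approx(0.03, abs=0.02)
    # threshold definition: fitted curve passes the criterion at theta_hat
    assert model_probability(fit.theta, fit.theta, fit.sigma, fit.lapse,
                             TASK_4AFC, 0.75) == pytest.approx(0.75)


def test_fit_lapse_boundary_with_lapse_free_data():
    levels = np.arange(0.5, 2.6, 0.25)
    p = model_probability(levels, 1.5, 1.0, 0.0, TASK_4AFC, 0.75)
    rng = np.random.default_rng(9)
    n = np.full(len(levels), 300)
    d = AggregatedData(levels, n, rng.binomial(n, p))
    fit = fit_ml(d, guess=0.25)
    assert fit.lapse < 0.01


def test_fit_degenerate_data_raises():
    d = AggregatedData(np.array([1.0, 2.0, 3.0]), np.array([5, 5, 5]),
                       np.array([5, 5, 5]))
    with pytest.raises(NonIdentifiableError):
        fit_ml(d, guess=0.25)


def test_p_deviance_perfect_fit_and_determinism(short_session):
    d = aggregate(short_session)
    fit = fit_ml(d, guess=0.25)
    zero_dev = FitResult(theta=fit.theta, sigma=fit.sigma, lapse=fit.lapse,
                         guess=0.25, pi=0.75, nll=fit.nll, dev=0.0)
    assert p_deviance(d, zero_dev, B=200, rng=np.random.default_rng(1),
                      refit=False) == 1.0
    p1 = p_deviance(d, fit, B=200, rng=np.random.default_rng(2))
    p2 = p_deviance(d, fit, B=200, rng=np.random.default_rng(2))
    assert p1 == p2
    # the conservative no-refit variant never gives a smaller p-value
    p_fast = p_deviance(d, fit, B=200, rng=np.random.default_rng(2),
                        refit=False)
    assert p_fast >= p1
    with pytest.raises(ValueError):
        p_deviance(d, fit, B=50, rng=np.random.default_rng(1))


@pytest.mark.parametrize("theta_arcsec, sigma, p, included", [
    (600.0, 1.0, 0.2, False),
    (33.7, 0.005, 0.2, False),
    (33.7, 1.0, 0.2, True),
    (33.7, 1.0, 0.03, False),
])
def test_passes_inclusion(theta_arcsec, sigma, p, included):
    fit = FitResult(theta=float(np.log10(theta_arcsec)), sigma=sigma,
                    lapse=0.02, guess=0.25, pi=0.75, nll=0.0, dev=1.0,
                    p_dev=p)
    assert passes_inclusion(fit) is included


def test_staircase_fit_bias_shrinks_with_trials(standard_4afc):
    """Threshold recovery from staircase-collected data improves from 80 to
    2000 trials (concatenated sessions)."""
    from stereozest import StaircaseConfig, run_updown

    rng = np.random.default_rng(77)

    def fitted_theta(n_sessions):
        s = Session(task=TASK_4AFC)
        idx = 1
        for _ in range(n_sessions):
            sess = run_updown(standard_4afc, StaircaseConfig(n_trials=80),
                              rng)
            for t in sess.trials:
                if not t.practice:
                    s.trials.append(TrialRecord(idx, t.level, t.response))
                    idx += 1
        return fit_ml(aggregate(s, exclude_practice=False), guess=0.25).theta

    short_err = np.mean([abs(fitted_theta(1) - 1.5) for _ in range(12)])
    long_err = np.mean([abs(fitted_theta(25) - 1.5) for _ in range(3)])
    assert long_err < short_err
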