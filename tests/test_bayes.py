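"""Posterior machinery and adaptive placement rules.

The expected-entropy and MLE checks use independent brute-force oracles
written here, separate from the vectorized implementation paths.
"""

import numpy as np
import pytest

from stereozest import (
    GaussianPrior,
    GridModel,
    ParameterGrid,
    Posterior,
    ProcedureConfig,
    SimulatedObserver,
    TASK_2AFC,
    TASK_4AFC,
    default_grid,
    expected_posterior_entropy,
    init_prior,
    marginal,
    model_probability,
    posterior_mean,
    psi_place,
    run_procedure,
    run_zest_fixed_batch,
    update_posterior,
    zest_place,
)
from stereozest.bayes import InvalidRequestError, _psi_place_index
from stereozest.model import InfeasibleCriterionError


def small_model(n_theta=5, n_sigma=3, n_lapse=None, task=TASK_4AFC,
                sigma_m=None, lambda_m=0.03):
    grid = ParameterGrid(
        threshold=np.linspace(0.5, 2.5, n_theta),
        stimuli=np.linspace(0.5, 2.5, n_theta),
        spread=np.geomspace(0.3, 2.5, n_sigma) if n_sigma else None,
        lapse=np.linspace(0, 0.06, n_lapse) if n_lapse else None,
    )
    return GridModel(grid=grid, task=task,
                     sigma_m=sigma_m if n_sigma is None else None,
                     lambda_m=None if n_lapse else lambda_m)


def test_model_probability_passes_pi_at_threshold():
    assert model_probability(1.5, 1.5, 1.0, 0.02, TASK_2AFC, 0.75) == \
        pytest.approx(0.75)
    assert model_probability(-40.0, 1.5, 1.0, 0.02, TASK_2AFC, 0.75) == \
        pytest.approx(0.5, abs=1e-9)


def test_model_probability_infeasible_pi():
    with pytest.raises(InfeasibleCriterionError):
        model_probability(1.0, 1.5, 1.0, 0.02, TASK_2AFC, 0.4)


def test_grid_validation():
    with pytest.raises(InvalidRequestError):
        ParameterGrid(threshold=np.array([1.0, 0.5]),
                      stimuli=np.array([0.7]))
    with pytest.raises(InvalidRequestError):
        ParameterGrid(threshold=np.array([1.0, 2.0]),
                      stimuli=np.array([0.5]))  # outside threshold range


def test_uniform_prior_mass():
    model = small_model()
    post = init_prior(model)
    assert np.allclose(post.mass, 1.0 / post.mass.size)
    assert post.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_gaussian_spread_prior_symmetric():
    grid = ParameterGrid(
        threshold=np.linspace(0, 3, 4),
        stimuli=np.linspace(0, 3, 4),
        spread=np.array([0.205, 0.605, 1.005, 1.405, 1.805]),
    )
    model = GridModel(grid=grid, task=TASK_2AFC, lambda_m=0.02)
    post = init_prior(model, spread_prior=GaussianPrior(1.005, 0.776))
    m = marginal(post, "spread").mass
    assert np.allclose(m, m[::-1])
    assert post.mass.sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(Exception):
        GaussianPrior(1.0, 0.0)


def test_update_two_point_hand_bayes():
    """Uniform prior on two hypotheses with Psi = 0.6 / 0.9 and a correct
    response gives posterior (0.4, 0.6)."""

    class TwoPoint(GridModel):
        def prob_correct(self, x):
            return np.array([0.6, 0.9])

    grid = ParameterGrid(threshold=np.array([1.0, 2.0]),
                         stimuli=np.array([1.0, 2.0]))
    model = TwoPoint(grid=grid, task=TASK_2AFC, sigma_m=1.0, lambda_m=0.02)
    post = init_prior(model)
    post = update_posterior(post, 1.5, True)
    assert np.allclose(post.mass, [0.4, 0.6])
    assert posterior_mean(post) == pytest.approx(1.6)


def test_update_order_invariance(rng):
    model = small_model(n_theta=7, n_sigma=3)
    trials = [(float(x), bool(r)) for x, r in
              zip(rng.choice(model.grid.stimuli, 12), rng.random(12) < 0.7)]
    a = init_prior(model)
    for x, r in trials:
        a = update_posterior(a, x, r)
    b = init_prior(model)
    for x, r in reversed(trials):
        b = update_posterior(b, x, r)
    assert np.allclose(a.mass, b.mass, atol=1e-12)
    assert a.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_marginal_matches_brute_force_sums(rng):
    model = small_model(n_theta=6, n_sigma=4)
    mass = rng.random((6, 4))
    post = Posterior(model=model, mass=mass)
    assert np.allclose(marginal(post, "threshold").mass,
                       post.mass.sum(axis=1))
    assert np.allclose(marginal(post, "spread").mass, post.mass.sum(axis=0))
    with pytest.raises(InvalidRequestError):
        marginal(post, "lapse")


def test_marginal_separable_mass():
    model = small_model(n_theta=4, n_sigma=3)
    p = np.array([0.1, 0.2, 0.3, 0.4])
    q = np.array([0.2, 0.5, 0.3])
    post = Posterior(model=model, mass=np.outer(p, q))
    assert np.allclose(marginal(post, "threshold").mass, p)


def test_posterior_mean_and_zest_place():
    model = small_model(n_theta=5, n_sigma=None, sigma_m=1.0)
    post = init_prior(model)
    assert posterior_mean(post) == pytest.approx(1.5)  # uniform midpoint
    mass = np.zeros(5)
    mass[3] = 1.0  # point mass at 2.0
    post = Posterior(model=model, mass=mass)
    assert posterior_mean(post) == pytest.approx(2.0)
    assert zest_place(post) == pytest.approx(2.0)
    # weighted two-point mean snaps to the nearest stimulus candidate
    mass = np.array([0.0, 0.4, 0.0, 0.6, 0.0])  # mean = 0.4*1+0.6*2 = 1.6
    post = Posterior(model=model, mass=mass)
    assert posterior_mean(post) == pytest.approx(1.6)
    assert zest_place(post) == pytest.approx(1.5)  # candidates step 0.5


# --------------------------------------------------------------------------
# entropy oracle


def entropy_bits_oracle(mass):
    m = mass[mass > 0]
    return float(-(m * np.log2(m)).sum())


def expected_entropy_oracle(post, x, interest_axes):
    """Brute-force enumeration of both responses via update_posterior."""
    p = (post.model.prob_correct(x) * post.mass).sum()
    out = 0.0
    for r, pr in ((True, p), (False, 1 - p)):
        upd = update_posterior(post, x, r)
        nuisance = tuple(i for i, a in enumerate(upd.axes)
                         if a not in interest_axes)
        m = upd.mass.sum(axis=nuisance) if nuisance else upd.mass
        out += pr * entropy_bits_oracle(m.ravel())
    return out


def test_expected_entropy_point_mass_is_zero():
    model = small_model(n_theta=5, n_sigma=None, sigma_m=1.0)
    mass = np.zeros(5)
    mass[2] = 1.0
    post = Posterior(model=model, mass=mass)
    for x in model.grid.stimuli:
        assert expected_posterior_entropy(post, float(x), ("threshold",)) == \
            pytest.approx(0.0, abs=1e-12)


def test_expected_entropy_matches_oracle(rng):
    for n_lapse in (None, 5):
        model = small_model(n_theta=8, n_sigma=4, n_lapse=n_lapse)
        mass = rng.random(model.grid.shape)
        post = Posterior(model=model, mass=mass)
        for axes in (("threshold",), ("threshold", "spread")):
            for x in (0.5, 1.5, 2.5):
                got = expected_posterior_entropy(post, x, axes)
                want = expected_entropy_oracle(post, x, axes)
                assert got == pytest.approx(want, abs=1e-10)


def test_psi_place_matches_brute_force_argmin(rng):
    """psi_place equals an exhaustive entropy scan on grids up to 10x10x5."""
    for shape in ((10, 10, 5), (6, 4, None), (10, 3, 2)):
        n_theta, n_sigma, n_lapse = shape
        model = small_model(n_theta=n_theta, n_sigma=n_sigma,
                            n_lapse=n_lapse)
        for _ in range(3):
            post = Posterior(model=model, mass=rng.random(model.grid.shape))
            for axes in (("threshold",), ("threshold", "spread")):
                ents = [expected_entropy_oracle(post, float(x), axes)
                        for x in model.grid.stimuli]
                want = model.grid.stimuli[int(np.argmin(ents))]
                assert psi_place(post, axes) == pytest.approx(float(want))


def test_psi_place_single_candidate_and_ties():
    grid = ParameterGrid(threshold=np.linspace(0.5, 2.5, 5),
                         stimuli=np.array([1.5]),
                         spread=np.geomspace(0.3, 2.5, 3))
    model = GridModel(grid=grid, task=TASK_4AFC, lambda_m=0.03)
    post = init_prior(model)
    assert psi_place(post, ("threshold",)) == pytest.approx(1.5)
    # point-mass posterior: all candidates tie at zero entropy -> smallest
    model = small_model(n_theta=5, n_sigma=None, sigma_m=1.0)
    mass = np.zeros(5)
    mass[4] = 1.0
    post = Posterior(model=model, mass=mass)
    assert psi_place(post, ("threshold",)) == pytest.approx(0.5)


# --------------------------------------------------------------------------
# full procedure runs


def grid_mle_oracle(model, xs, responses):
    """Exhaustive per-hypothesis log-likelihood scan (threshold axis)."""
    loglik = np.zeros(model.grid.shape)
    for x, r in zip(xs, responses):
        p = model.prob_correct(float(x))
        loglik += np.log(p if r else 1 - p)
    return model.grid.threshold[int(np.argmax(loglik))]


def test_zest_mode_equals_exhaustive_mle(standard_4afc):
    """With a uniform prior, the posterior mode reproduces the grid MLE on
    every simulated session (ZEST/ML equivalence)."""
    config = ProcedureConfig("zest_fixed_sigma", task=TASK_4AFC, n_trials=40,
                             sigma_m=1.5, lambda_m=0.03)
    model = config.build_model()
    for seed in range(5):
        trace = run_procedure(standard_4afc, config,
                              rng=np.random.default_rng(seed),
                              grid_model=model)
        post = init_prior(model)
        for x, r in zip(trace.stimulus, trace.response):
            post = update_posterior(post, float(x), bool(r))
        mode = marginal(post, "threshold").mode()
        assert mode == pytest.approx(
            grid_mle_oracle(model, trace.stimulus, trace.response))


def test_batch_runner_matches_scalar_path(standard_4afc):
    """The vectorized fixed-spread ZEST reproduces run_procedure exactly
    when both consume the same pre-drawn uniforms."""
    config = ProcedureConfig("zest_fixed_sigma", task=TASK_4AFC, n_trials=25,
                             sigma_m=1.5, lambda_m=0.03)
    model = config.build_model()
    U = np.random.default_rng(31).random((8, 25))
    batch = run_zest_fixed_batch(standard_4afc, config, 8, uniform_draws=U,
                                 grid_model=model)
    for i in range(8):
        trace = run_procedure(standard_4afc, config, uniform_draws=U[i],
                              grid_model=model)
        assert np.allclose(batch[i], trace.theta_hat, atol=1e-12)


def test_posterior_concentrates_with_informative_trials():
    """Estimate spread across runs shrinks as trials accumulate."""
    obs = SimulatedObserver.from_parameters(1.5, 1.0, 0.0, TASK_4AFC)
    config = ProcedureConfig("zest_fixed_sigma", task=TASK_4AFC, n_trials=60,
                             sigma_m=1.0, lambda_m=0.0)
    est = run_zest_fixed_batch(obs, config, 300,
                               rng=np.random.default_rng(17))
    assert est[:, 59].std() < est[:, 9].std()


def test_procedure_config_validation():
    with pytest.raises(InvalidRequestError):
        ProcedureConfig("zest_fixed_sigma", task=TASK_4AFC, lambda_m=0.03)
    with pytest.raises(InvalidRequestError):
        ProcedureConfig("psi_theta_sigma", task=TASK_4AFC, sigma_m=1.0,
                        lambda_m=0.03)
    with pytest.raises(InvalidRequestError):
        ProcedureConfig("psi_marg_theta_SL", task=TASK_4AFC, lambda_m=0.03)
    with pytest.raises(InvalidRequestError):
        ProcedureConfig("nonsense", task=TASK_4AFC)


def test_run_procedure_seeded_reproducibility(standard_4afc):
    config = ProcedureConfig("zest2d_theta_sigma", task=TASK_4AFC,
                             n_trials=10, lambda_m=0.03,
                             grid=default_grid(True, False, theta_step=0.05,
                                               stimulus_step=0.1))
    a = run_procedure(standard_4afc, config, rng=np.random.default_rng(4))
    b = run_procedure(standard_4afc, config, rng=np.random.default_rng(4))
    assert np.array_equal(a.stimulus, b.stimulus)
    assert np.array_equal(a.theta_hat, b.theta_hat)
    assert a.sigma_hat is not None
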