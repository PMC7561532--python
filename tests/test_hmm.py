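"""Movement HMM: emission densities, recursions vs exhaustive
enumeration, fitting, decoding, and the three-criterion selection."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from carnmove import hmm
from carnmove.hmm import (
    Decoding,
    MovementModel,
    aic,
    fit_hmm,
    forward_loglik,
    gamma_logpdf,
    multistart_fit,
    predictive_power,
    select_model,
    state_posteriors,
    viterbi,
    wrapped_cauchy_logpdf,
)


def _steps(lengths, angles):
    return pd.DataFrame({"length": lengths, "turn_angle": angles})


def _toy_model(n):
    mus = np.array([10.0, 200.0, 1500.0, 4000.0])[:n]
    ss = np.array([8.0, 150.0, 900.0, 2000.0])[:n]
    ms = np.zeros(n)
    rhos = np.linspace(0.1, 0.7, n)
    if n == 1:
        gam = np.array([[1.0]])
    else:
        gam = np.full((n, n), 0.2 / (n - 1))
        np.fill_diagonal(gam, 0.8)
    delta = np.full(n, 1.0 / n)
    return MovementModel(mus, ss, ms, rhos, gam, delta)


# ---------------------------------------------------------------------------
# emission densities


def test_gamma_exponential_limit_at_zero():
    # mu == s is the exponential case: density at 0 is 1/mu
    assert gamma_logpdf(0.0, 198.0, 198.0) == pytest.approx(np.log(1 / 198.0))


def test_gamma_integrates_to_one():
    for mu, s in [(7.0, 7.0), (198.0, 150.0), (1426.0, 800.0)]:
        val, _ = integrate.quad(lambda x: np.exp(gamma_logpdf(x, mu, s)), 0, np.inf)
        assert abs(val - 1.0) < 1e-6


def test_gamma_sampling_mean_matches_parametrization():
    rng = np.random.default_rng(0)
    mu, s = 198.0, 150.0
    draws = rng.gamma((mu / s) ** 2, s**2 / mu, size=100_000)
    se = s / np.sqrt(len(draws))
    assert abs(draws.mean() - mu) < 3 * se


def test_gamma_invalid_params():
    with pytest.raises(ValueError):
        gamma_logpdf(1.0, -5.0, 2.0)


def test_wrapped_cauchy_uniform_limit():
    for theta in (-3.0, 0.0, 1.5, np.pi):
        assert np.exp(wrapped_cauchy_logpdf(theta, 0.0, 0.0)) == pytest.approx(1 / (2 * np.pi))


def test_wrapped_cauchy_integrates_to_one():
    for m, rho in [(0.0, 0.5), (1.2, 0.9), (-2.0, 0.2)]:
        val, _ = integrate.quad(lambda t: np.exp(wrapped_cauchy_logpdf(t, m, rho)), -np.pi, np.pi)
        assert abs(val - 1.0) < 1e-6


def test_wrapped_cauchy_mode_at_location():
    grid = np.linspace(-np.pi, np.pi, 1001)
    dens = wrapped_cauchy_logpdf(grid, 0.8, 0.8)
    assert abs(grid[np.argmax(dens)] - 0.8) < 0.01


def test_wrapped_cauchy_domain_error():
    with pytest.raises(ValueError):
        wrapped_cauchy_logpdf(0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# recursions vs exhaustive enumeration


def _enumerate_loglik(model, lengths, angles):
    """Brute-force sum over all state paths."""
    T, N = len(lengths), model.n_states
    logb = hmm._emission_logs((model.mu, model.s, model.m, model.rho), np.asarray(lengths), np.asarray(angles))
    total = -np.inf
    for path in product(range(N), repeat=T):
        lp = np.log(model.delta[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.gamma[path[t - 1], path[t]]) + logb[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def _enumerate_best_path(model, lengths, angles):
    T, N = len(lengths), model.n_states
    logb = hmm._emission_logs((model.mu, model.s, model.m, model.rho), np.asarray(lengths), np.asarray(angles))
    best, best_lp = None, -np.inf
    for path in product(range(N), repeat=T):
        lp = np.log(model.delta[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.gamma[path[t - 1], path[t]]) + logb[t, path[t]]
        if lp > best_lp:
            best, best_lp = path, lp
    return np.asarray(best) + 1


def _enumerate_marginals(model, lengths, angles):
    T, N = len(lengths), model.n_states
    logb = hmm._emission_logs((model.mu, model.s, model.m, model.rho), np.asarray(lengths), np.asarray(angles))
    marg = np.zeros((T, N))
    for path in product(range(N), repeat=T):
        lp = np.log(model.delta[path[0]]) + logb[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.gamma[path[t - 1], path[t]]) + logb[t, path[t]]
        w = np.exp(lp)
        for t, s in enumerate(path):
            marg[t, s] += w
    return marg / marg.sum(axis=1, keepdims=True)


_TOY_LENGTHS = [5.0, 12.0, 300.0, 1200.0, 2500.0, 180.0]
_TOY_ANGLES = [np.nan, 0.3, -2.8, 0.1, np.nan, 1.0]


@pytest.mark.parametrize("n_states", [2, 3])
def test_forward_matches_exhaustive_enumeration(n_states):
    model = _toy_model(n_states)
    steps = _steps(_TOY_LENGTHS, _TOY_ANGLES)
    assert forward_loglik(model, steps) == pytest.approx(
        _enumerate_loglik(model, _TOY_LENGTHS, _TOY_ANGLES), abs=1e-8
    )


def test_single_state_forward_is_emission_sum():
    model = _toy_model(1)
    steps = _steps(_TOY_LENGTHS, _TOY_ANGLES)
    logb = hmm._emission_logs(
        (model.mu, model.s, model.m, model.rho),
        np.asarray(_TOY_LENGTHS),
        np.asarray(_TOY_ANGLES),
    )
    assert forward_loglik(model, steps) == pytest.approx(float(logb.sum()), abs=1e-8)


def test_viterbi_matches_exhaustive_enumeration():
    model = _toy_model(3)
    lengths = _TOY_LENGTHS + [40.0]
    angles = _TOY_ANGLES + [0.0]
    got = viterbi(model, _steps(lengths, angles))
    assert np.array_equal(got, _enumerate_best_path(model, lengths, angles))


def test_single_state_viterbi_and_posteriors():
    model = _toy_model(1)
    steps = _steps(_TOY_LENGTHS, _TOY_ANGLES)
    assert np.array_equal(viterbi(model, steps), np.ones(6, dtype=int))
    dec = state_posteriors(model, steps)
    assert np.allclose(dec.posteriors, 1.0)
    assert predictive_power(dec) == 1.0


def test_posteriors_match_exhaustive_marginals():
    model = _toy_model(2)
    lengths = _TOY_LENGTHS[:5]
    angles = _TOY_ANGLES[:5]
    dec = state_posteriors(model, _steps(lengths, angles))
    oracle = _enumerate_marginals(model, lengths, angles)
    assert np.allclose(dec.posteriors, oracle, atol=1e-8)
    assert np.allclose(dec.posteriors.sum(axis=1), 1.0, atol=1e-10)


def test_multi_burst_loglik_sums():
    model = _toy_model(2)
    s1 = _steps(_TOY_LENGTHS[:3], _TOY_ANGLES[:3])
    s2 = _steps(_TOY_LENGTHS[3:], _TOY_ANGLES[3:])
    joint = pd.concat([s1.assign(burst_id=0), s2.assign(burst_id=1)], ignore_index=True)
    assert forward_loglik(model, joint) == pytest.approx(
        forward_loglik(model, s1) + forward_loglik(model, s2), abs=1e-10
    )


def test_loglik_invariant_to_state_relabeling():
    model = _toy_model(3)
    perm = [2, 0, 1]
    shuffled = MovementModel(
        model.mu[perm],
        model.s[perm],
        model.m[perm],
        model.rho[perm],
        model.gamma[np.ix_(perm, perm)],
        model.delta[perm],
    )
    steps = _steps(_TOY_LENGTHS, _TOY_ANGLES)
    assert forward_loglik(model, steps) == pytest.approx(
        forward_loglik(shuffled, steps), abs=1e-10
    )
    assert np.all(np.diff(shuffled.canonical().mu) > 0)


# ---------------------------------------------------------------------------
# fitting


@pytest.fixture(scope="module")
def two_state_sim():
    rng = np.random.default_rng(4)
    T = 3000
    gam = np.array([[0.9, 0.1], [0.15, 0.85]])
    mus, ss, rhos = np.array([10.0, 1000.0]), np.array([10.0, 700.0]), np.array([0.2, 0.7])
    states = [0]
    for _ in range(T - 1):
        states.append(rng.choice(2, p=gam[states[-1]]))
    states = np.array(states)
    lengths = rng.gamma((mus / ss)[states] ** 2 * 1.0, (ss**2 / mus)[states])
    u = rng.uniform(0, 1, T)
    angles = 2 * np.arctan(((1 - rhos[states]) / (1 + rhos[states])) * np.tan(np.pi * (u - 0.5)))
    truth = MovementModel(mus, ss, np.zeros(2), rhos, gam, np.array([0.5, 0.5]))
    return _steps(lengths, angles), states, truth


def test_two_state_parameter_recovery(two_state_sim):
    steps, states, truth = two_state_sim
    model = multistart_fit(steps, 2)
    assert np.all(np.abs(model.mu - truth.mu) / truth.mu < 0.10)
    assert np.all(np.abs(model.gamma - truth.gamma) < 0.05)


def test_fit_is_fixed_point_of_itself(two_state_sim):
    steps, _, _ = two_state_sim
    model = multistart_fit(steps, 2)
    refit = fit_hmm(steps, 2, start=model)
    assert np.allclose(refit.mu, model.mu, rtol=1e-4)
    assert refit.loglik >= model.loglik - 1e-6


def test_likelihood_at_fit_beats_truth(two_state_sim):
    steps, _, truth = two_state_sim
    model = multistart_fit(steps, 2)
    assert model.loglik >= forward_loglik(truth, steps) - 1e-6


def test_multistart_single_start_equals_fit(two_state_sim):
    steps, _, _ = two_state_sim
    theta0 = hmm._start_vector(np.array([20.0, 800.0]), np.array([20.0, 600.0]), 0.4, 2)
    direct = fit_hmm(steps, 2, start=theta0.copy())
    grid = multistart_fit(steps, 2, start_grid=[theta0.copy()])
    assert grid.loglik == pytest.approx(direct.loglik, abs=1e-8)


def test_multistart_winner_beats_bad_start(two_state_sim):
    steps, _, _ = two_state_sim
    bad = hmm._start_vector(np.array([3000.0, 9000.0]), np.array([100.0, 100.0]), 0.7, 2)
    good = hmm._start_vector(np.array([20.0, 800.0]), np.array([20.0, 600.0]), 0.4, 2)
    winner = multistart_fit(steps, 2, start_grid=[bad.copy(), good.copy()])
    for theta0 in (bad, good):
        assert winner.loglik >= fit_hmm(steps, 2, start=theta0.copy()).loglik - 1e-6


def test_multistart_deterministic_under_reordering(two_state_sim):
    steps, _, _ = two_state_sim
    g1 = hmm.default_start_grid(2)
    g2 = list(reversed(g1))
    m1 = multistart_fit(steps, 2, start_grid=g1)
    m2 = multistart_fit(steps, 2, start_grid=g2)
    assert np.allclose(m1.mu, m2.mu, rtol=1e-5)


def test_viterbi_accuracy_on_separated_states(sim3):
    steps, states = sim3
    model = multistart_fit(steps, 3)
    path = viterbi(model, steps)
    truth = states[1 : 1 + len(path)]
    assert (path == truth).mean() >= 0.90


def test_posterior_argmax_agrees_with_viterbi(sim3):
    steps, _ = sim3
    model = multistart_fit(steps, 3)
    dec = state_posteriors(model, steps)
    agree = (dec.posteriors.argmax(axis=1) + 1 == dec.path).mean()
    assert agree >= 0.95
    assert predictive_power(dec) > 0.85


# ---------------------------------------------------------------------------
# AIC and selection


def test_aic_formula_and_parameter_count():
    model = _toy_model(3)
    model.loglik = -100.0
    assert model.k == 20  # 12 emission + 6 transition + 2 initial
    assert aic(model) == pytest.approx(-2 * -100.0 + 2 * 20)
    model2 = _toy_model(2)
    model2.loglik = -100.0
    assert model2.k == 11  # 8 emission + 2 transition + 1 initial
    assert aic(model2) == pytest.approx(222.0)


def _fake_decoding(power, T=10, n=2):
    post = np.full((T, n), (1 - power) / (n - 1))
    post[:, 0] = power
    return Decoding(path=np.ones(T, dtype=int), posteriors=post)


def test_uniform_posterior_power_is_half():
    assert predictive_power(_fake_decoding(0.5, n=2)) == pytest.approx(0.5)


def test_selection_sequential_logic():
    def fake_model(mus, loglik):
        n = len(mus)
        gam = np.full((n, n), 0.1 / max(n - 1, 1))
        np.fill_diagonal(gam, 0.9)
        m = MovementModel(np.array(mus), np.array(mus) * 0.8, np.zeros(n),
                          np.full(n, 0.3), gam, np.full(n, 1 / n), loglik=loglik)
        return m

    # only the 3-state candidate passes both filters -> chosen despite AIC
    candidates = {
        2: fake_model([10.0, 20.0], -50.0),  # ratio 2 < 3: implausible
        3: fake_model([7.0, 198.0, 1426.0], -100.0),
        4: fake_model([7.0, 14.0, 198.0, 1426.0], -40.0),  # ratio 2 < 3
    }
    decodings = {2: _fake_decoding(0.99), 3: _fake_decoding(0.9, n=3), 4: _fake_decoding(0.99, n=4)}
    chosen, report = select_model(candidates, decodings)
    assert chosen.n_states == 3
    assert report[3]["selected"]

    # all pass -> minimum AIC wins
    candidates = {
        2: fake_model([10.0, 1000.0], -5.0),
        3: fake_model([7.0, 198.0, 1426.0], -4.0),
        4: fake_model([1.0, 10.0, 198.0, 1426.0], -6.0),
    }
    decodings = {n: _fake_decoding(0.95, n=n) for n in (2, 3, 4)}
    chosen, report = select_model(candidates, decodings)
    assert chosen.n_states == min((2, 3, 4), key=lambda n: report[n]["aic"])

    # nothing passes -> error carrying the report
    decodings = {n: _fake_decoding(0.5, n=n) for n in (2, 3, 4)}
    with pytest.raises(RuntimeError) as exc:
        select_model(candidates, decodings)
    assert hasattr(exc.value, "report")


def test_model_json_roundtrip():
    model = _toy_model(3)
    model.loglik = -123.456
    restored = MovementModel.from_json(model.to_json())
    assert np.allclose(restored.mu, model.mu)
    assert np.allclose(restored.gamma, model.gamma)
    assert restored.loglik == model.loglik
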