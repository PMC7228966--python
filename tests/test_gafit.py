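"""Genetic-algorithm fitting machinery."""

import numpy as np
import pytest

from chamberlink import gafit


def make_bounds():
    return gafit.ParameterBounds(lower={"A": 0.1, "tau": 1.0},
                                 upper={"A": 10.0, "tau": 100.0},
                                 scale={"A": "log", "tau": "log"})


def test_bounds_validation():
    with pytest.raises(ValueError):
        gafit.ParameterBounds(lower={"a": 0.0}, upper={"b": 1.0})
    with pytest.raises(ValueError):
        gafit.ParameterBounds(lower={"a": 2.0}, upper={"a": 1.0})
    with pytest.raises(ValueError):
        gafit.ParameterBounds(lower={"a": -1.0}, upper={"a": 1.0},
                              scale={"a": "log"})


def test_samples_respect_bounds():
    b = make_bounds()
    rng = np.random.default_rng(0)
    for _ in range(200):
        s = b.sample(rng)
        assert 0.1 <= s["A"] <= 10.0
        assert 1.0 <= s["tau"] <= 100.0


def test_log_scale_averaging_is_geometric_mean():
    b = make_bounds()
    child = b.average({"A": 1.0, "tau": 4.0}, {"A": 4.0, "tau": 16.0})
    assert child["A"] == pytest.approx(2.0)
    assert child["tau"] == pytest.approx(8.0)
    lin = gafit.ParameterBounds(lower={"x": 0.0}, upper={"x": 10.0})
    assert lin.average({"x": 2.0}, {"x": 6.0})["x"] == pytest.approx(4.0)


def test_objective_is_euclidean_residual_norm():
    assert gafit.objective_l2(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
    assert gafit.objective_l2(np.array([3.0, 0.0]),
                              np.array([0.0, 4.0])) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        gafit.objective_l2(np.zeros(3), np.zeros(4))


def test_generation_composition_elite_averaged_fresh():
    b = make_bounds()
    rng = np.random.default_rng(1)
    pop = [b.sample(rng) for _ in range(gafit.POPULATION_SIZE)]
    objs = np.arange(gafit.POPULATION_SIZE, dtype=float)
    nxt, carried = gafit.ga_generation(pop, objs, b, rng)
    assert len(nxt) == 100
    assert carried.sum() == 10 and np.all(carried[:10])
    # elite carried unchanged, in objective order
    for i in range(10):
        assert nxt[i] == pop[i]
    # the 9 averaged children combine the best with ranks 2-10
    for j, partner in enumerate(pop[1:10]):
        assert nxt[10 + j] == b.average(pop[0], partner)


def test_generation_requires_full_population():
    b = make_bounds()
    with pytest.raises(ValueError):
        gafit.ga_generation([b.sample(np.random.default_rng(0))], [1.0], b,
                            np.random.default_rng(0))


def test_fit_recovers_two_parameter_exponential():
    t = np.linspace(0.0, 100.0, 51)
    obs = 3.0 * np.exp(-t / 25.0)
    prob = gafit.FitProblem(lambda p: p["A"] * np.exp(-t / p["tau"]),
                            obs, make_bounds())
    res = gafit.fit(prob, rng_seed=12345)
    assert abs(res.best_parameters["A"] - 3.0) / 3.0 < 0.05
    assert abs(res.best_parameters["tau"] - 25.0) / 25.0 < 0.05
    assert res.converged


def test_fit_is_deterministic_given_seed():
    t = np.linspace(0.0, 50.0, 26)
    obs = 2.0 * np.exp(-t / 10.0)
    prob = gafit.FitProblem(lambda p: p["A"] * np.exp(-t / p["tau"]),
                            obs, make_bounds())
    r1 = gafit.fit(prob, rng_seed=7, max_generations=15)
    r2 = gafit.fit(prob, rng_seed=7, max_generations=15)
    assert r1.best_parameters == r2.best_parameters
    assert r1.objective_trace == r2.objective_trace


def test_objective_trace_is_monotone_non_increasing():
    t = np.linspace(0.0, 50.0, 26)
    obs = 2.0 * np.exp(-t / 10.0)
    prob = gafit.FitProblem(lambda p: p["A"] * np.exp(-t / p["tau"]),
                            obs, make_bounds())
    res = gafit.fit(prob, rng_seed=11, max_generations=25)
    trace = np.array(res.objective_trace)
    assert np.all(np.diff(trace) <= 1e-12)


def test_simulator_failures_are_counted_not_fatal():
    t = np.linspace(0.0, 50.0, 26)
    obs = 2.0 * np.exp(-t / 10.0)

    def flaky(p):
        if p["A"] > 5.0:
            raise RuntimeError("simulated integrator failure")
        return p["A"] * np.exp(-t / p["tau"])

    res = gafit.fit(gafit.FitProblem(flaky, obs, make_bounds()),
                    rng_seed=3, max_generations=15)
    assert res.n_simulator_failures > 0
    assert np.isfinite(res.best_objective)
    assert res.best_parameters["A"] <= 5.0


def test_structure_gene_recovers_true_chain_length():
    # structure-only identification on an Erlang-shaped target
    from scipy import stats
    t = np.linspace(0.0, 60.0, 121)
    obs = stats.gamma.pdf(t, 5, scale=2.0)

    def sim(p, N):
        return stats.gamma.pdf(t, N, scale=1.0 / p["a"])

    b = gafit.ParameterBounds(lower={"a": 0.05}, upper={"a": 5.0},
                              scale={"a": "log"})
    res = gafit.fit(gafit.FitProblem(sim, obs, b, structure_search=(1, 10)),
                    rng_seed=42, max_generations=40)
    assert res.best_structure == 5
    assert abs(res.best_parameters["a"] - 0.5) / 0.5 < 0.05
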