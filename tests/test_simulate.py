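"""Microstep simulator: choice sets, probabilities, dynamics and limits."""

import numpy as np
import pytest

from netcoevolve.effects import ModelSpec
from netcoevolve.experiments import (outdegree_birth_death_stationary,
                                     outdegree_stationary_experiment)
from netcoevolve.simulate import (RateSet, SimulationError, SystemState,
                                  choice_probabilities, network_choice_set,
                                  simulate_panel, simulate_period)


def _state(n, density=0.2, seed=0):
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj[adj.sum(axis=1) > 10] = 0
    return SystemState(adj, rng.integers(1, 5, n).astype(float),
                       rng.integers(1, 4, n).astype(float),
                       rng.integers(1, 4, n).astype(float)).validate()


class TestChoiceProbabilities:
    def test_uniform_for_equal_values(self):
        np.testing.assert_allclose(choice_probabilities([3.0, 3.0, 3.0]), 1 / 3)

    def test_closed_form(self):
        np.testing.assert_allclose(choice_probabilities([np.log(2), 0.0]),
                                   [2 / 3, 1 / 3])

    def test_shift_invariance(self):
        v = np.array([0.1, -2.0, 5.0])
        np.testing.assert_allclose(choice_probabilities(v),
                                   choice_probabilities(v + 123.4))

    def test_extreme_values_are_stable(self):
        p = choice_probabilities([1e4, 0.0])
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)

    def test_nan_rejected(self):
        with pytest.raises(SimulationError):
            choice_probabilities([np.nan, 1.0])


class TestNetworkChoiceSet:
    def test_isolate_counts(self):
        st = _state(4, density=0.0)
        assert len(network_choice_set(0, st)) == 4   # 3 additions + no change

    def test_minimal_network(self):
        st = _state(2, density=0.0)
        assert len(network_choice_set(0, st)) == 2

    def test_cap_blocks_additions(self):
        n = 13
        adj = np.zeros((n, n), dtype=np.int8)
        adj[0, 1:11] = 1                              # at the cap of 10
        st = SystemState(adj, np.ones(n), np.ones(n), np.ones(n))
        cands = network_choice_set(0, st)
        assert len(cands) == 11                       # 10 deletions + no change
        for c in cands:
            assert c.adjacency[0].sum() <= 10


class TestSimulatePeriod:
    @pytest.fixture
    def setup(self):
        spec = ModelSpec.build(1)
        theta = spec.theta_template()
        theta[spec["outdegree"].index] = -1.5
        n = 12
        return spec, theta, _state(n, 0.15, seed=5), np.zeros(n), np.zeros(n)

    def test_deterministic_given_seed(self, setup):
        spec, theta, st, g, f = setup
        a, _ = simulate_period(st, theta, RateSet(4, 1, 1, 1), spec, g, f, seed=99)
        b, _ = simulate_period(st, theta, RateSet(4, 1, 1, 1), spec, g, f, seed=99)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.array_equal(a.alcohol, b.alcohol)

    def test_null_dynamics_at_vanishing_rates(self, setup):
        spec, theta, st, g, f = setup
        end, nsteps = simulate_period(st, theta, RateSet(1e-12, 1e-12, 1e-12, 1e-12),
                                      spec, g, f, seed=1)
        assert nsteps == 0
        assert np.array_equal(end.adjacency, st.adjacency)

    def test_negative_rate_rejected(self, setup):
        spec, theta, st, g, f = setup
        with pytest.raises(SimulationError):
            simulate_period(st, theta, RateSet(-1, 1, 1, 1), spec, g, f, seed=1)

    def test_state_validity_preserved(self, setup):
        spec, theta, st, g, f = setup
        end, _ = simulate_period(st, theta, RateSet(8, 2, 2, 2), spec, g, f, seed=3)
        end.validate()

    def test_expected_microstep_count(self, setup):
        spec, theta, st, g, f = setup
        # total rate = n * sum(rates) = 12 * 5 = 60 per unit time
        counts = [simulate_period(st, theta, RateSet(2, 1, 1, 1), spec, g, f,
                                  seed=s, horizon=4.0)[1] for s in range(40)]
        expected = 12 * 5 * 4.0
        assert np.mean(counts) == pytest.approx(expected, rel=0.1)


class TestSimulatePanel:
    def test_wave_count_and_first_wave_identity(self):
        spec = ModelSpec.build(1)
        theta = spec.theta_template()
        st = _state(10, 0.2, seed=2)
        g = np.zeros(10)
        panel = simulate_panel(st, theta, [RateSet(3, 1, 1, 1)], spec, g, g, seed=4)
        assert panel.n_waves == 2
        assert np.array_equal(panel.waves[0].adjacency, st.adjacency)

    def test_identical_seeds_identical_panels(self):
        spec = ModelSpec.build(2)
        theta = spec.theta_template()
        st = _state(10, 0.2, seed=2)
        g = np.zeros(10)
        rates = [RateSet(3, 1, 1, 1)] * 2
        p1 = simulate_panel(st, theta, rates, spec, g, g, seed=8)
        p2 = simulate_panel(st, theta, rates, spec, g, g, seed=8)
        for w1, w2 in zip(p1.waves, p2.waves):
            assert np.array_equal(w1.adjacency, w2.adjacency)
            np.testing.assert_array_equal(w1.alcohol, w2.alcohol)

    def test_influence_raises_drinking_assortativity(self):
        """Strong total-similarity influence makes friends' drinking align."""
        spec = ModelSpec.build(1, dimensions=("network", "alcohol"))
        base = spec.theta_template()
        base[spec["outdegree"].index] = -1.8
        with_inf = base.copy()
        with_inf[spec["alc_totsim"].index] = 2.0

        def assort(theta, seed):
            st = _state(30, 0.12, seed=seed)
            g = np.zeros(30)
            end, _ = simulate_period(st, theta, RateSet(4, 3, 0, 0), spec, g, g,
                                     seed=seed, horizon=3.0)
            i, j = np.nonzero(end.adjacency)
            return float(np.mean(np.abs(end.alcohol[i] - end.alcohol[j])))

        null = np.mean([assort(base, s) for s in range(12)])
        inf = np.mean([assort(with_inf, s) for s in range(12)])
        assert inf < null


def test_null_model_microsteps_are_equiprobable():
    """With all evaluation parameters zero every candidate toggle is equally
    likely: the first changed dyad over many short runs is uniform (chi-square)."""
    from scipy import stats as sps

    spec = ModelSpec.build(1, single_sex=True, dimensions=("network",))
    theta = spec.theta_template()
    n = 5
    adj = np.zeros((n, n), dtype=np.int8)
    start = SystemState(adj, np.ones(n), np.ones(n), np.ones(n))
    g = np.zeros(n)
    counts = {}
    n_events = 0
    for s in range(4000):
        end, nsteps = simulate_period(start, theta, RateSet(5.0, 0, 0, 0),
                                      spec, g, g, seed=s, horizon=0.05)
        if nsteps != 1:
            continue
        diff = np.argwhere(end.adjacency != start.adjacency)
        if len(diff) == 1:
            counts[tuple(diff[0])] = counts.get(tuple(diff[0]), 0) + 1
            n_events += 1
    # 20 ordered dyads; no-change consumes part of the events
    observed = np.array([counts.get((i, j), 0)
                         for i in range(n) for j in range(n) if i != j])
    chi2 = float(((observed - observed.mean()) ** 2 / observed.mean()).sum())
    p = float(sps.chi2.sf(chi2, df=len(observed) - 1))
    assert p > 0.001


class TestStationaryLaws:
    def test_binary_choice_density_is_logistic(self):
        """With one possible tie per actor the stationary law is exactly logistic."""
        r = outdegree_stationary_experiment(-1.0, n_periods=2500, seed=7)
        assert abs(r["density"] - r["expected"]) < 3 * r["mc_se"]

    def test_multi_alter_density_matches_birth_death_oracle(self):
        """For n > 2 the exact stationary law comes from the outdegree birth-death chain."""
        r = outdegree_stationary_experiment(-2.0, n=10, n_periods=1500, seed=9)
        exact = outdegree_birth_death_stationary(-2.0, 10)
        assert abs(r["density"] - exact) < max(3 * r["mc_se"], 0.01)
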