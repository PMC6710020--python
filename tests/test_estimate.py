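"""Method-of-moments machinery: diagnostics, derivatives and small fits."""

import numpy as np
import pytest

from netcoevolve.effects import ModelSpec
from netcoevolve.estimate import (EstimationError, EstimationOptions, FitResult,
                                  TargetSimulator, convergence_diagnostics,
                                  derivative_matrix, estimate_school)
from netcoevolve.simulate import RateSet, SystemState, simulate_panel


def small_network_spec(n_periods=1):
    return ModelSpec.build(
        n_periods, single_sex=True, dimensions=("network",),
        exclude=("in_pop_sqrt", "fsm_sim", "trans_trip",
                 "alc_alter", "alc_ego", "alc_sim", "con_alter", "con_ego",
                 "con_sim", "con_ego_x_alc_sim", "sec_alter", "sec_ego",
                 "sec_sim"))


def small_panel(n=20, seed=0, theta_out=-1.5, theta_rec=1.0):
    spec = small_network_spec()
    theta = spec.theta_template()
    theta[spec["outdegree"].index] = theta_out
    theta[spec["reciprocity"].index] = theta_rec
    theta[spec["rate_net_p1"].index] = 4.0
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < 0.15).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj[adj.sum(axis=1) > 10] = 0
    state = SystemState(adj, np.ones(n), np.ones(n), np.ones(n))
    panel = simulate_panel(state, theta, [RateSet(4.0, 0, 0, 0)], spec,
                           np.zeros(n), np.zeros(n), seed=seed + 7,
                           school_type="boys")
    return panel, spec, theta


class TestConvergenceDiagnostics:
    def test_perfect_match(self):
        sims = np.tile([1.0, 2.0, 3.0], (20, 1)) + np.random.default_rng(0).normal(
            0, 1e-9, (20, 3))
        obs = sims.mean(axis=0)
        t, overall = convergence_diagnostics(sims, obs)
        np.testing.assert_allclose(t, 0.0, atol=1e-3)
        assert overall < 1e-3

    def test_one_sd_offset_gives_unit_t_ratio(self):
        rng = np.random.default_rng(1)
        sims = rng.normal(0, 1, size=(4000, 2))
        obs = np.array([-1.0, 0.0])
        t, _ = convergence_diagnostics(sims, obs)
        assert t[0] == pytest.approx(1.0, abs=4 / np.sqrt(4000))
        assert t[1] == pytest.approx(0.0, abs=4 / np.sqrt(4000))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        sims = rng.normal(size=(50, 4))
        obs = rng.normal(size=4)
        t1, o1 = convergence_diagnostics(sims, obs)
        perm = [3, 1, 0, 2]
        t2, o2 = convergence_diagnostics(sims[:, perm], obs[perm])
        np.testing.assert_allclose(t2, t1[perm])
        assert o1 == pytest.approx(o2)

    def test_zero_variance_statistic(self):
        sims = np.column_stack([np.full(30, 5.0), np.random.default_rng(3).normal(size=30)])
        t, _ = convergence_diagnostics(sims, np.array([5.0, 0.0]))
        assert t[0] == 0.0
        t, _ = convergence_diagnostics(sims, np.array([4.0, 0.0]))
        assert np.isinf(t[0])

    def test_too_few_rows_rejected(self):
        with pytest.raises(EstimationError):
            convergence_diagnostics(np.zeros((4, 3)), np.zeros(3))

    def test_thresholds_define_convergence_flag(self, ):
        """max|t| < .1 and overall < .25 is the convergence rule."""
        panel, spec, theta = small_panel(n=12, seed=5)
        fit = estimate_school(panel, spec,
                              EstimationOptions(n1=6, newton_iters=3, n_dev=5,
                                                final_iters=5, n_avg=2, n3=20,
                                                max_restarts=0), seed=3)
        assert fit.converged == bool(np.max(np.abs(fit.t_ratios)) < 0.1
                                     and fit.overall_ratio < 0.25)


class TestDerivativeMatrix:
    def test_forward_difference_matches_central_oracle(self):
        """Independent central-difference run on the outdegree column."""
        panel, spec, theta = small_panel(n=14, seed=11)
        sim = TargetSimulator(panel, spec)
        idx = spec.free_names.index("outdegree")
        D = derivative_matrix(theta, spec, panel, n1=60, delta=0.3, seed=5)
        # central difference with its own seeds
        d = 0.3
        up, dn = theta.copy(), theta.copy()
        up[spec["outdegree"].index] += d
        dn[spec["outdegree"].index] -= d
        seeds = range(900, 990)
        col = np.mean([sim.simulate(up, s) for s in seeds], axis=0)
        col -= np.mean([sim.simulate(dn, s) for s in seeds], axis=0)
        central = col[idx] / (2 * d)
        assert D[idx, idx] == pytest.approx(central, rel=0.10)

    def test_flat_rate_column_near_zero(self):
        """A vanishing rate never fires, so its derivative column is ~0."""
        panel, spec, theta = small_panel(n=12, seed=3)
        spec2 = ModelSpec.build(1, single_sex=True, dimensions=("network", "alcohol"),
                                exclude=("in_pop_sqrt", "fsm_sim", "trans_trip",
                                         "alc_alter", "alc_ego", "alc_sim",
                                         "con_alter", "con_ego", "con_sim",
                                         "con_ego_x_alc_sim", "sec_alter",
                                         "sec_ego", "sec_sim", "alc_totsim",
                                         "alc_con_x_totsim", "alc_sec_x_totsim",
                                         "alc_quad"))
        theta2 = spec2.theta_template()
        theta2[spec2["outdegree"].index] = -1.5
        theta2[spec2["rate_net_p1"].index] = 4.0
        theta2[spec2["rate_alc_p1"].index] = 1e-6
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                D = derivative_matrix(theta2, spec2, panel, n1=20, delta=0.3, seed=1)
        k = spec2.free_names.index("alc_linear")
        assert np.abs(D[:, k]).max() < 1e-6

    def test_variance_shrinks_with_more_replications(self):
        """Column Monte-Carlo sd scales like 1/sqrt(n1)."""
        panel, spec, theta = small_panel(n=12, seed=2)
        idx = spec.free_names.index("outdegree")

        def column_draws(n1, n_draws=12):
            return [derivative_matrix(theta, spec, panel, n1=n1, delta=0.3,
                                      seed=1000 + 17 * d)[idx, idx]
                    for d in range(n_draws)]

        sd_small = np.std(column_draws(5), ddof=1)
        sd_big = np.std(column_draws(20), ddof=1)
        assert sd_big < sd_small


class TestEstimateSchool:
    def test_fixed_effect_stays_fixed_with_nan_se(self):
        panel, spec, _ = small_panel(n=16, seed=21)
        fit = estimate_school(panel, spec,
                              EstimationOptions(n1=8, newton_iters=4, n_dev=8,
                                                final_iters=10, n_avg=2, n3=30,
                                                max_restarts=0), seed=5)
        e = spec["trans_trip"]
        assert e.fixed
        assert fit.theta[e.index] == 0.0
        assert np.isnan(fit.se[e.index])

    def test_recovers_outdegree_roughly(self):
        """A cheap two-parameter fit should land near the generating values."""
        panel, spec, theta = small_panel(n=25, seed=31, theta_out=-2.0, theta_rec=1.2)
        fit = estimate_school(panel, spec,
                              EstimationOptions(n1=10, newton_iters=6, n_dev=15,
                                                final_iters=25, n_avg=3, n3=100,
                                                max_restarts=0), seed=13)
        est, se = fit.get("outdegree", spec)
        assert abs(est - (-2.0)) < max(3 * se, 0.8)

    def test_reproducible_from_seed(self):
        panel, spec, _ = small_panel(n=14, seed=41)
        opts = EstimationOptions(n1=6, newton_iters=3, n_dev=6, final_iters=8,
                                 n_avg=2, n3=25, max_restarts=0)
        f1 = estimate_school(panel, spec, opts, seed=77)
        f2 = estimate_school(panel, spec, opts, seed=77)
        np.testing.assert_array_equal(f1.theta, f2.theta)
        assert f1.overall_ratio == f2.overall_ratio

    def test_json_roundtrip(self):
        panel, spec, _ = small_panel(n=12, seed=51)
        opts = EstimationOptions(n1=6, newton_iters=2, n_dev=5, final_iters=5,
                                 n_avg=2, n3=20, max_restarts=0)
        fit = estimate_school(panel, spec, opts, seed=1)
        back = FitResult.from_json(fit.to_json())
        np.testing.assert_array_equal(back.theta, fit.theta)
        np.testing.assert_array_equal(back.covariance, fit.covariance)
        assert back.converged == fit.converged
        assert back.free_names == fit.free_names
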