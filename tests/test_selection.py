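"""Ego-alter selection tables: construction, pooling and asymmetry contrasts."""

import numpy as np
import pytest

from netcoevolve.effects import ModelSpec
from netcoevolve.estimate import FitResult
from netcoevolve.selection import (SelectionTableError, asymmetry_contrast,
                                   pool_selection_tables,
                                   school_asymmetry_contrast,
                                   school_log_odds_table)


def make_fit(spec, betas: dict, cov_diag: float = 0.01, cov: np.ndarray | None = None):
    """Synthetic FitResult with the given effect values and covariance."""
    theta = spec.theta_template()
    for name, value in betas.items():
        theta[spec[name].index] = value
    p = spec.n_free
    covariance = np.eye(p) * cov_diag if cov is None else cov
    se = np.full(spec.n_params, np.nan)
    se[spec.free_indices] = np.sqrt(np.diag(covariance))
    return FitResult(theta=theta, se=se, covariance=covariance,
                     rates=spec.pack(theta)[4], t_ratios=np.zeros(p),
                     overall_ratio=0.0, converged=True, n_phase3=0, seed=0,
                     free_names=spec.free_names, free_indices=spec.free_indices,
                     school_id="synthetic")


@pytest.fixture
def spec():
    return ModelSpec.build(1)


class TestSchoolTable:
    def test_reference_cell_is_exactly_zero(self, spec):
        fit = make_fit(spec, {"alc_ego": 0.2, "alc_alter": -0.1, "alc_sim": 0.5})
        L, V = school_log_odds_table(fit, spec, "alcohol", school_mean=2.0)
        # the 2.0 category coincides with the school mean here
        assert L[1, 1] == pytest.approx(0.0, abs=1e-14)
        assert V[1, 1] == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_when_ego_equals_alter(self, spec):
        fit = make_fit(spec, {"alc_ego": 0.07, "alc_alter": 0.07, "alc_sim": 0.4})
        L, _ = school_log_odds_table(fit, spec, "alcohol")
        np.testing.assert_allclose(L, L.T, atol=1e-14)

    def test_worked_frequent_frequent_cell(self, spec):
        """Pooled-style inputs ego .01, alter .03, sim .35 at mean 2.0:
        cell (4,4) has cancelling similarity terms and log-odds .08."""
        fit = make_fit(spec, {"alc_ego": 0.01, "alc_alter": 0.03, "alc_sim": 0.35})
        L, _ = school_log_odds_table(fit, spec, "alcohol", school_mean=2.0)
        assert L[3, 3] == pytest.approx(0.08, abs=1e-12)
        assert np.exp(L[3, 3]) == pytest.approx(np.exp(0.08), abs=1e-12)

    def test_fixed_effect_rejected(self, spec):
        fixed_spec = ModelSpec.build(1, exclude=("con_sim",))
        fit = make_fit(fixed_spec, {"con_ego": 0.1, "con_alter": 0.1})
        with pytest.raises(SelectionTableError):
            school_log_odds_table(fit, fixed_spec, "control")

    def test_similarity_lowers_dissimilar_cells_only(self, spec):
        """Against the mean-mean reference the similarity terms cancel on the
        diagonal (sim = 1 there, as in the reference dyad); a larger
        similarity preference strictly lowers dissimilar-pair cells."""
        lo = make_fit(spec, {"alc_ego": 0.02, "alc_alter": 0.02, "alc_sim": 0.2})
        hi = make_fit(spec, {"alc_ego": 0.02, "alc_alter": 0.02, "alc_sim": 0.6})
        L_lo, _ = school_log_odds_table(lo, spec, "alcohol", school_mean=2.0)
        L_hi, _ = school_log_odds_table(hi, spec, "alcohol", school_mean=2.0)
        np.testing.assert_allclose(np.diag(L_hi), np.diag(L_lo), atol=1e-12)
        for e in range(4):
            for a in range(4):
                if e != a:
                    assert L_hi[e, a] < L_lo[e, a]


class TestPooling:
    def test_idempotent_on_identical_tables(self, spec):
        fit = make_fit(spec, {"sec_ego": 0.1, "sec_alter": -0.2, "sec_sim": 0.3})
        pair = school_log_odds_table(fit, spec, "secrecy")
        table = pool_selection_tables([pair, pair], "secrecy")
        np.testing.assert_allclose(table.log_odds, pair[0], atol=1e-9)

    def test_two_school_inverse_variance_oracle(self):
        """Close estimates force tau2 = 0: cells must equal the closed form."""
        K = 3
        L1 = np.full((K, K), 0.30)
        L2 = np.full((K, K), 0.32)
        V1 = np.full((K, K), 0.01)
        V2 = np.full((K, K), 0.04)
        table = pool_selection_tables([(L1, V1), (L2, V2)], "control")
        w1, w2 = 1 / 0.01, 1 / 0.04
        expected = (w1 * 0.30 + w2 * 0.32) / (w1 + w2)
        np.testing.assert_allclose(table.log_odds, expected, atol=1e-10)
        np.testing.assert_allclose(table.or_matrix, np.exp(expected), atol=1e-10)

    def test_flag_iff_or_ci_excludes_one(self):
        rng = np.random.default_rng(0)
        tables = [(rng.normal(0.2, 0.05, (3, 3)), np.full((3, 3), 0.002))
                  for _ in range(4)]
        table = pool_selection_tables(tables, "secrecy")
        np.testing.assert_array_equal(
            table.flagged, (table.ci_low > 1.0) | (table.ci_high < 1.0))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(SelectionTableError):
            pool_selection_tables([(np.zeros((3, 3)), np.zeros((3, 3)))], "alcohol")


class TestAsymmetry:
    def test_symmetric_table_zero_contrasts(self, spec):
        fit = make_fit(spec, {"con_ego": 0.15, "con_alter": 0.15, "con_sim": 0.3})
        pair = school_log_odds_table(fit, spec, "control")
        table = pool_selection_tables([pair, pair], "control")
        est, _, _ = asymmetry_contrast(table, 0, 2)
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetry(self, spec):
        fit = make_fit(spec, {"con_ego": 0.3, "con_alter": -0.1, "con_sim": 0.2})
        pair = school_log_odds_table(fit, spec, "control")
        table = pool_selection_tables([pair, pair], "control")
        a, _, _ = asymmetry_contrast(table, 0, 2)
        b, _, _ = asymmetry_contrast(table, 2, 0)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_same_category_rejected(self, spec):
        fit = make_fit(spec, {"con_ego": 0.3, "con_alter": -0.1, "con_sim": 0.2})
        table = pool_selection_tables(
            [school_log_odds_table(fit, spec, "control")] * 2, "control")
        with pytest.raises(SelectionTableError):
            asymmetry_contrast(table, 1, 1)

    def test_exact_school_contrast_formula(self, spec):
        fit = make_fit(spec, {"con_ego": 0.3, "con_alter": -0.1, "con_sim": 0.2})
        est, se = school_asymmetry_contrast(fit, spec, "control", 1.0, 3.0)
        assert est == pytest.approx((0.3 - (-0.1)) * (1.0 - 3.0), abs=1e-12)
        assert se > 0


def test_asymmetry_contrast_recovers_generating_direction():
    """Schools generated with unequal control ego/alter selection: the exact
    per-school low-vs-high contrast matches the generating sign in >= 90%
    of replicates."""
    import warnings

    from netcoevolve.estimate import EstimationOptions, estimate_school
    from netcoevolve.simulate import RateSet, simulate_panel
    from netcoevolve.synth import SynthConfig, _wave1_state

    gen_spec = ModelSpec.build(
        1, single_sex=False, dimensions=("network",),
        exclude=("in_pop_sqrt", "fsm_sim", "trans_trip", "alc_alter", "alc_ego",
                 "alc_sim", "con_ego_x_alc_sim", "sec_alter", "sec_ego", "sec_sim"))
    theta = gen_spec.theta_template()
    for nm, v in {"outdegree": -2.0, "reciprocity": 1.2, "same_gender": 0.4,
                  "con_ego": 0.30, "con_alter": -0.10, "con_sim": 0.15,
                  "rate_net_p1": 5.0}.items():
        theta[gen_spec[nm].index] = v
    truth_sign = np.sign((0.30 - (-0.10)) * (1.0 - 3.0))
    opts = EstimationOptions(n1=10, newton_iters=7, refresh_every=2, n_dev=15,
                             final_iters=30, final_gain=0.15, n_avg=3, n3=60,
                             max_restarts=0)
    cfg = SynthConfig()
    hits = 0
    n_reps = 50
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            rng = np.random.default_rng(4000 + rep)
            state, g, f = _wave1_state(cfg, 35, "coed", rng)
            panel = simulate_panel(state, theta, [RateSet(5.0, 0, 0, 0)],
                                   gen_spec, g, f, int(rng.integers(2**31)))
            fit = estimate_school(panel, gen_spec, opts,
                                  seed=int(rng.integers(2**31)))
            est, _ = school_asymmetry_contrast(fit, gen_spec, "control", 1.0, 3.0)
            hits += int(np.sign(est) == truth_sign)
    assert hits / n_reps >= 0.9


def test_table_frame_has_category_labels(spec):
    fit = make_fit(spec, {"alc_ego": 0.05, "alc_alter": 0.02, "alc_sim": 0.3})
    table = pool_selection_tables(
        [school_log_odds_table(fit, spec, "alcohol")] * 2, "alcohol")
    frame = table.to_frame()
    assert set(frame["ego_category"]) == {"never", "rarely", "monthly", "frequently"}
    assert len(frame) == 16
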