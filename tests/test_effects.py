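"""Effect statistics against brute-force enumeration, and target vectors."""

import numpy as np
import pytest

from netcoevolve.effects import (EffectError, ModelSpec, behavior_evaluation,
                                 dyadic_similarity, network_evaluation,
                                 network_statistics, target_statistics)
from netcoevolve.experiments import (brute_behavior_stats, brute_network_stats,
                                     effects_oracle_check, random_state)
from netcoevolve.panels import impute_panel

CONSTS = np.array([1.9, 2.1, 1.95, 0.55, 0.6, 0.62, 0.68, 3.0, 2.0, 2.0])


@pytest.mark.parametrize("vi,vj,rng,expected", [
    (3, 3, 3, 1.0),
    (1, 4, 3, 0.0),
    (2, 3, 3, 2 / 3),
])
def test_dyadic_similarity(vi, vj, rng, expected):
    assert dyadic_similarity(vi, vj, rng) == pytest.approx(expected)


def test_dyadic_similarity_bad_range():
    with pytest.raises(EffectError):
        dyadic_similarity(1, 2, 0.0)


def test_transitive_triplet_orientation_hand_case():
    """Ties 0->1, 1->2, 0->2: one triplet from actor 0, none from 1 or 2."""
    adj = np.zeros((3, 3), dtype=np.int8)
    adj[0, 1] = adj[1, 2] = adj[0, 2] = 1
    ones = np.ones(3)
    zeros = np.zeros(3)
    tt = [brute_network_stats(i, adj, ones, ones, ones, zeros, zeros, CONSTS)[2]
          for i in range(3)]
    assert tt == [1.0, 0.0, 0.0]
    beh = np.vstack([ones, ones, ones])
    ref = [network_statistics(i, adj, beh, zeros, zeros, CONSTS)[2] for i in range(3)]
    assert ref == tt


def test_statistics_match_brute_force_oracle():
    """Kernel, reference and enumeration agree on random small fixtures."""
    res = effects_oracle_check(n_fixtures=30, seed=123)
    assert res["max_abs_diff"] < 1e-10
    assert res["max_triad_diff"] == 0


def test_empty_network_zero_statistics():
    st = random_state(5, np.random.default_rng(0), density=0.0)
    beh = np.vstack([st["alc"], st["con"], st["sec"]])
    for i in range(5):
        s = network_statistics(i, st["adj"], beh, st["gender"], st["fsm"], CONSTS)
        assert np.all(s == 0.0)


def test_objective_is_linear_in_theta(tiny_panel, tiny_spec):
    imp = impute_panel(tiny_panel)
    beh = imp.behaviors[0]
    t1 = np.random.default_rng(1).normal(size=tiny_spec.n_params)
    t2 = np.random.default_rng(2).normal(size=tiny_spec.n_params)
    args = (imp.adjacency[0], beh, imp.gender, imp.fsm)
    f = network_evaluation
    assert f(0, *args, t1 + t2, tiny_spec) == pytest.approx(
        f(0, *args, t1, tiny_spec) + f(0, *args, t2, tiny_spec), abs=1e-10)
    g = behavior_evaluation
    assert g(1, "alcohol", 3.0, *args, t1 + t2, tiny_spec) == pytest.approx(
        g(1, "alcohol", 3.0, *args, t1, tiny_spec)
        + g(1, "alcohol", 3.0, *args, t2, tiny_spec), abs=1e-10)


def test_pure_outdegree_objective_scales_with_ties():
    adj = np.zeros((6, 6), dtype=np.int8)
    adj[0, 1:5] = 1
    spec = ModelSpec.build(1)
    theta = spec.theta_template()
    theta[spec["outdegree"].index] = -2.0
    beh = np.ones((3, 6)) * 2
    val = network_evaluation(0, adj, beh, np.zeros(6), np.zeros(6), theta, spec)
    # four ties at weight -2 each, all other effect parameters zero ...
    # except centered alter/ego/similarity statistics, which are zero here
    # only because every other theta component is zero
    assert val == pytest.approx(-8.0 + 0.0)


def test_isolate_average_terms_are_zero():
    st = random_state(4, np.random.default_rng(3), density=0.0)
    out = brute_behavior_stats(0, "secrecy", 2.0, st["adj"], st["alc"], st["con"],
                               st["sec"], st["gender"], st["fsm"], CONSTS)
    assert out[2] == 0.0 and out[3] == 0.0


def test_total_similarity_with_identical_friends():
    """Two friends at ego's own drinking level: statistic = 2 (1 - sbar)."""
    adj = np.zeros((3, 3), dtype=np.int8)
    adj[0, 1] = adj[0, 2] = 1
    alc = np.array([3.0, 3.0, 3.0])
    out = brute_behavior_stats(0, "alcohol", 3.0, adj, alc, alc.copy(), alc.copy(),
                               np.zeros(3), np.zeros(3), CONSTS)
    assert out[2] == pytest.approx(2 * (1 - CONSTS[3]))


def test_permutation_equivariance_of_summed_targets(tiny_panel):
    """Relabeling actors leaves the summed target vector unchanged."""
    spec = ModelSpec.from_panel(tiny_panel)
    base = target_statistics(tiny_panel, spec)
    perm = np.array([2, 0, 3, 1])
    p = tiny_panel.copy()
    p.actor_ids = [tiny_panel.actor_ids[k] for k in perm]
    p.gender = tiny_panel.gender[perm]
    p.fsm = tiny_panel.fsm[perm]
    for w, w0 in zip(p.waves, tiny_panel.waves):
        w.adjacency = w0.adjacency[np.ix_(perm, perm)].copy()
        w.present = w0.present[perm].copy()
        for attr in ("alcohol", "control", "secrecy"):
            setattr(w, attr, getattr(w0, attr)[perm].copy())
    spec_p = ModelSpec.from_panel(p)
    np.testing.assert_allclose(target_statistics(p, spec_p), base, atol=1e-9)


def test_fsm_similarity_closed_form():
    """For a binary covariate: statistic = same-category ties - sbar * outdegree."""
    rng = np.random.default_rng(9)
    st = random_state(6, rng, density=0.5)
    beh = np.vstack([st["alc"], st["con"], st["sec"]])
    for i in range(6):
        s = network_statistics(i, st["adj"], beh, st["gender"], st["fsm"], CONSTS)
        row = st["adj"][i]
        same = sum(row[j] for j in range(6) if st["fsm"][j] == st["fsm"][i])
        assert s[5] == pytest.approx(same - CONSTS[6] * row.sum(), abs=1e-12)


class TestTargetStatistics:
    def test_identical_waves_have_zero_rate_targets(self, tiny_panel):
        p = tiny_panel.copy()
        p.waves[1] = p.waves[0]
        spec = ModelSpec.from_panel(p)
        targets = target_statistics(p, spec)
        rate_pos = [k for k, e in enumerate([spec[n] for n in spec.free_names])
                    if e.kind == "rate"]
        assert all(targets[k] == 0.0 for k in rate_pos)

    def test_single_toggle_gives_unit_network_rate(self, tiny_panel):
        spec = ModelSpec.from_panel(tiny_panel)
        # tiny_panel differs by one tie (3->0) and some behaviour changes
        pos = spec.free_names.index("rate_net_p1")
        assert target_statistics(tiny_panel, spec)[pos] == 1.0

    def test_cross_lagged_eval_targets_match_enumeration(self, tiny_panel):
        """Network stats: wave-2 ties with wave-1 behaviours; behaviours reversed."""
        spec = ModelSpec.from_panel(tiny_panel)
        imp = impute_panel(tiny_panel)
        adj0, adj1 = imp.adjacency
        beh0, beh1 = imp.behaviors
        c = spec.consts
        g, f = imp.gender, imp.fsm
        n = 4
        net = sum(brute_network_stats(i, adj1, beh0[0], beh0[1], beh0[2], g, f, c)
                  for i in range(n))
        alc = sum(brute_behavior_stats(i, "alcohol", beh1[0][i], adj0,
                                       beh1[0], beh0[1], beh0[2], g, f, c)
                  for i in range(n))
        con = sum(brute_behavior_stats(i, "control", beh1[1][i], adj0,
                                       beh0[0], beh1[1], beh0[2], g, f, c)
                  for i in range(n))
        sec = sum(brute_behavior_stats(i, "secrecy", beh1[2][i], adj0,
                                       beh0[0], beh0[1], beh1[2], g, f, c)
                  for i in range(n))
        expected_full = np.concatenate([net, alc, con, sec])
        got = target_statistics(tiny_panel, spec)
        free = spec.free_indices
        eval_mask = free < 34
        np.testing.assert_allclose(got[eval_mask], expected_full[free[eval_mask]],
                                   atol=1e-10)


def test_modelspec_serialization_roundtrip(tiny_spec):
    back = ModelSpec.from_dict(tiny_spec.to_dict())
    assert back.free_names == tiny_spec.free_names
    np.testing.assert_array_equal(back.consts, tiny_spec.consts)
    assert back.n_periods == tiny_spec.n_periods


def test_single_sex_school_fixes_gender_effects(tiny_panel):
    p = tiny_panel.copy()
    p.gender = np.ones(4)
    p.school_type = "girls"
    spec = ModelSpec.from_panel(p)
    for name in ("same_gender", "alc_gender", "con_gender", "sec_gender"):
        assert spec[name].fixed and spec[name].fixed_value == 0.0
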