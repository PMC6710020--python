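"""Validation experiments: oracles, analytic limits, recovery and calibration.

These are the package's own correctness experiments, shared by the test
suite and by ``scripts/acceptance.py``.  Each function regenerates its
inputs from a seed, runs the relevant pipeline stage and returns the
measured quantities.  The brute-force statistic enumerations here are
deliberately written from the definitions (python loops over actors,
dyads and triples) and share no code with the compiled kernels they
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kernels
from .effects import ModelSpec, behavior_statistics, network_statistics
from .estimate import EstimationOptions, estimate_school
from .gof import auxiliary_vector, gof_test, triad_census
from .meta import encode_moderators, meta_regression
from .simulate import RateSet, SystemState, simulate_panel, simulate_period
from .synth import SynthConfig, true_theta, _wave1_state

# ---------------------------------------------------------------------------
# Brute-force oracles (definition-level enumeration)
# ---------------------------------------------------------------------------

def brute_network_stats(i, adj, alc, con, sec, gender, fsm, consts):
    """Actor i's 16 network statistics by direct summation over dyads/triples."""
    n = adj.shape[0]
    zb = consts[0:3]
    sb = consts[3:6]
    sbf = consts[6]
    rng = consts[7:10]
    beh = [alc, con, sec]
    s = [0.0] * 16
    for j in range(n):
        if not adj[i][j]:
            continue
        s[0] += 1
        s[1] += 1 if adj[j][i] else 0
        for h in range(n):
            if adj[j][h] and adj[i][h]:
                s[2] += 1
        indeg_j = sum(int(adj[k][j]) for k in range(n))
        s[3] += float(np.sqrt(float(indeg_j)))
        s[4] += 1 if gender[i] == gender[j] else 0
        s[5] += (1 - abs(fsm[i] - fsm[j])) - sbf
        for b in range(3):
            v = beh[b]
            s[6 + 3 * b] += v[j] - zb[b]
            s[7 + 3 * b] += v[i] - zb[b]
            s[8 + 3 * b] += (1 - abs(v[i] - v[j]) / rng[b]) - sb[b]
        s[15] += (con[i] - zb[1]) * ((1 - abs(alc[i] - alc[j]) / rng[0]) - sb[0])
    return np.array(s)


def brute_behavior_stats(i, behavior, z, adj, alc, con, sec, gender, fsm, consts):
    """Actor i's behaviour statistics at candidate level z, by enumeration."""
    n = adj.shape[0]
    zb = consts[0:3]
    sb = consts[3:6]
    rng = consts[7:10]
    friends = [j for j in range(n) if adj[i][j]]
    if behavior == "alcohol":
        c = z - zb[0]
        tot = sum((1 - abs(z - alc[j]) / rng[0]) - sb[0] for j in friends)
        return np.array([c, c * c, tot, (con[i] - zb[1]) * tot,
                         (sec[i] - zb[2]) * tot, c * gender[i], c * fsm[i]])
    if behavior == "control":
        c = z - zb[1]
        return np.array([c, c * c, c * (alc[i] - zb[0]),
                         c * gender[i], c * fsm[i]])
    c = z - zb[2]
    d = max(1, len(friends))
    avs = sum((1 - abs(z - sec[j]) / rng[2]) - sb[2] for j in friends) / d
    avd = sum(alc[j] - zb[0] for j in friends) / d
    return np.array([c, c * c, avs, c * avd, c * gender[i], c * fsm[i]])


def brute_triad_census(adj):
    """Per-triple triad classification via isomorphism over vertex orders."""
    from itertools import combinations, permutations

    from .gof import _CLASS_TABLE, _EDGES
    n = adj.shape[0]
    counts = np.zeros(16, dtype=int)
    for i, j, k in combinations(range(n), 3):
        sub = [[0, adj[i][j], adj[i][k]],
               [adj[j][i], 0, adj[j][k]],
               [adj[k][i], adj[k][j], 0]]
        best = None
        for p in permutations(range(3)):
            code = sum((1 << b) for b, (a, c) in enumerate(_EDGES)
                       if sub[p[a]][p[c]])
            if best is None or code < best:
                best = code
        counts[_CLASS_TABLE[best]] += 1
    return counts


def random_state(n: int, rng: np.random.Generator, density: float = 0.3) -> dict:
    adj = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return {
        "adj": adj,
        "alc": rng.integers(1, 5, n).astype(float),
        "con": rng.integers(1, 4, n).astype(float),
        "sec": rng.integers(1, 4, n).astype(float),
        "gender": rng.integers(0, 2, n).astype(float),
        "fsm": rng.integers(0, 2, n).astype(float),
    }


def effects_oracle_check(n_fixtures: int = 100, seed: int = 0) -> dict:
    """Max |kernel - brute force| over random 4-6 actor states, all statistics."""
    rng = np.random.default_rng(seed)
    consts = np.array([1.9, 2.1, 1.95, 0.55, 0.6, 0.62, 0.68, 3.0, 2.0, 2.0])
    worst = 0.0
    worst_triad = 0
    for _ in range(n_fixtures):
        n = int(rng.integers(4, 7))
        st = random_state(n, rng, density=float(rng.uniform(0.15, 0.6)))
        adj, alc, con, sec = st["adj"], st["alc"], st["con"], st["sec"]
        g, f = st["gender"], st["fsm"]
        net_kernel = kernels.network_stats_total(adj, alc, con, sec, g, f, consts)
        beh_kernel = kernels.behavior_stats_total(adj, alc, con, sec, g, f, consts)
        net_brute = np.zeros(16)
        beh_brute = np.zeros(18)
        beh = np.vstack([alc, con, sec])
        for i in range(n):
            bn = brute_network_stats(i, adj, alc, con, sec, g, f, consts)
            net_brute += bn
            # the readable reference implementation must agree too
            ref = network_statistics(i, adj, beh, g, f, consts)
            worst = max(worst, float(np.max(np.abs(ref - bn))))
            for b, (name, z) in enumerate((("alcohol", alc[i]), ("control", con[i]),
                                           ("secrecy", sec[i]))):
                bb = brute_behavior_stats(i, name, z, adj, alc, con, sec, g, f, consts)
                refb = behavior_statistics(i, name, z, adj, beh, g, f, consts)
                worst = max(worst, float(np.max(np.abs(refb - bb))))
                off = (0, 7, 12)[b]
                beh_brute[off:off + len(bb)] += bb
        worst = max(worst, float(np.max(np.abs(net_kernel - net_brute))))
        worst = max(worst, float(np.max(np.abs(beh_kernel - beh_brute))))
        census = triad_census(adj)
        worst_triad = max(worst_triad,
                          int(np.max(np.abs(census - brute_triad_census(adj)))))
    return {"max_abs_diff": worst, "max_triad_diff": worst_triad,
            "n_fixtures": n_fixtures}


# ---------------------------------------------------------------------------
# Analytic simulator limits
# ---------------------------------------------------------------------------

def outdegree_stationary_experiment(theta_out: float, n: int = 2,
                                    n_periods: int = 4000, burn_in: int = 200,
                                    seed: int = 0) -> dict:
    """Tie density of the pure-outdegree model against logistic(theta_out).

    The logistic stationary law is exact when each actor's choice set is
    binary (toggle the one possible tie, or keep it): the tie then follows
    a two-state chain with flip odds exp(theta), hence P(tie) =
    logistic(theta).  With more alters the softmax normalisation is
    state-dependent, the chain is no longer reversible with respect to
    exp(theta * #ties), and the stationary density genuinely deviates from
    the logistic value (see :func:`outdegree_birth_death_stationary` for
    the exact law) — so the analytic benchmark is run at n = 2.  Density
    is sampled at period ends after burn-in; the Monte-Carlo se uses batch
    means over periods.
    """
    spec = ModelSpec.build(1, single_sex=True, dimensions=("network",))
    theta = spec.theta_template()
    theta[spec["outdegree"].index] = theta_out
    for e in spec.effects:
        if e.kind == "rate" and not e.fixed:
            theta[e.index] = 0.0
    gender = np.zeros(n)
    fsm = np.zeros(n)
    rng = np.random.default_rng(seed)
    adj0 = (rng.random((n, n)) < 0.2).astype(np.int8)
    np.fill_diagonal(adj0, 0)
    state = SystemState(adj0, np.ones(n), np.ones(n), np.ones(n))
    # several opportunities per dyad between recorded samples
    rates = RateSet(8.0, 0.0, 0.0, 0.0)
    dens = []
    seeds = np.random.SeedSequence(seed).generate_state(n_periods) >> 1
    for m in range(n_periods):
        state, _ = simulate_period(state, theta, rates, spec, gender, fsm,
                                   int(seeds[m]))
        if m >= burn_in:
            dens.append(state.adjacency.mean() * n / (n - 1))
    dens = np.asarray(dens)
    batches = dens[:len(dens) // 10 * 10].reshape(10, -1).mean(axis=1)
    mc_se = float(batches.std(ddof=1) / np.sqrt(len(batches)))
    expected = 1.0 / (1.0 + np.exp(-theta_out))
    return {"density": float(dens.mean()), "expected": float(expected),
            "mc_se": mc_se, "n_periods": n_periods}


def outdegree_birth_death_stationary(theta_out: float, n: int) -> float:
    """Exact stationary density of the pure-outdegree model for any n.

    Under the outdegree-only objective an actor's outdegree k is a
    birth-death chain: relative choice weights are exp(theta) for each of
    the (n-1-k) additions, exp(-theta) for each of the k deletions and 1
    for no change.  Detailed balance of the k-chain gives the stationary
    law in closed form; the mean density follows.
    """
    m = n - 1
    eth = np.exp(theta_out)

    def z(k):
        return 1.0 + k / eth + (m - k) * eth

    pi = np.zeros(m + 1)
    pi[0] = 1.0
    for k in range(m):
        up = (m - k) * eth / z(k)
        down = (k + 1) / eth / z(k + 1)
        pi[k + 1] = pi[k] * up / down
    pi /= pi.sum()
    return float((pi * np.arange(m + 1)).sum() / m)


def behavior_chain_experiment(theta_lin: float = 0.4, theta_quad: float = -0.3,
                              n_periods: int = 30000, seed: int = 0) -> dict:
    """Single-actor alcohol chain vs the brute-force stationary distribution.

    The embedded microstep chain on {1,2,3,4} has explicit transition
    probabilities given by the multinomial logit over {z-1, z, z+1}; its
    stationary vector is computed by eigen-decomposition and compared with
    the empirical occupancy of the simulated chain in total variation.
    """
    spec = ModelSpec.build(1, single_sex=True, dimensions=("alcohol",))
    theta = spec.theta_template()
    theta[spec["alc_linear"].index] = theta_lin
    theta[spec["alc_quad"].index] = theta_quad
    zbar = spec.consts[0]

    def objective(z):
        c = z - zbar
        return theta_lin * c + theta_quad * c * c

    P = np.zeros((4, 4))
    for z in range(1, 5):
        cands = [zz for zz in (z - 1, z, z + 1) if 1 <= zz <= 4]
        w = np.exp([objective(zz) for zz in cands])
        w = w / w.sum()
        for zz, pk in zip(cands, w):
            P[z - 1, zz - 1] += pk
    evals, evecs = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, k])
    pi = pi / pi.sum()

    state = SystemState(np.zeros((1, 1), dtype=np.int8), np.array([1.0]),
                        np.array([1.0]), np.array([1.0]))
    gender = np.zeros(1)
    fsm = np.zeros(1)
    # sample the state every ~8 microsteps; with uniform holding times the
    # time-average occupancy equals the embedded-chain stationary law
    n_chunks = max(200, n_periods // 8)
    burn = 100
    seeds = np.random.SeedSequence(seed).generate_state(n_chunks) >> 1
    chunk_rates = RateSet(0.0, 8.0, 0.0, 0.0)
    counts = np.zeros(4)
    for c in range(n_chunks):
        state, _ = simulate_period(state, theta, chunk_rates, spec, gender,
                                   fsm, int(seeds[c]))
        if c >= burn:
            counts[int(state.alcohol[0]) - 1] += 1
    occ = counts / counts.sum()
    tv = 0.5 * float(np.abs(occ - pi).sum())
    return {"tv_distance": tv, "stationary": pi.tolist(),
            "empirical": occ.tolist()}


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def reduced_fit_options() -> EstimationOptions:
    """Estimation controls sized for replicate studies on one desktop CPU."""
    return EstimationOptions(n1=12, newton_iters=14, refresh_every=3, n_dev=20,
                             final_iters=50, final_gain=0.15, n_avg=3,
                             n3=400, max_restarts=0)


def parameter_recovery_experiment(n_fits: int = 100, n: int = 40,
                                  waves: int = 3, seed: int = 0,
                                  options: EstimationOptions | None = None) -> pd.DataFrame:
    """Fit replicate synthetic schools simulated at the default true theta.

    Each replicate draws a fresh wave-1 state (coeducational school of
    size ``n``), simulates ``waves - 1`` periods at the generator's default
    parameter vector, fully observed, and refits the full model.  Returns a
    per-parameter frame with truth, mean and sd of the estimates, the
    Monte-Carlo standard error of the mean, and 95%-CI coverage.
    """
    cfg = SynthConfig()
    spec = ModelSpec.build(waves - 1, single_sex=False)
    theta_star = true_theta(cfg, spec, "coed")
    rates = [RateSet(*row) for row in spec.pack(theta_star)[4]]
    options = options or reduced_fit_options()
    free = spec.free_indices
    root = np.random.SeedSequence(seed).generate_state(2 * n_fits) >> 1
    ests, covered = [], []
    for r in range(n_fits):
        rng = np.random.default_rng(int(root[2 * r]))
        state, gender, fsm = _wave1_state(cfg, n, "coed", rng)
        panel = simulate_panel(state, theta_star, rates, spec, gender, fsm,
                               int(rng.integers(2**31)))
        fit = estimate_school(panel, spec, options, seed=int(root[2 * r + 1]))
        ests.append(fit.theta[free])
        lo = fit.theta[free] - 1.96 * fit.se[free]
        hi = fit.theta[free] + 1.96 * fit.se[free]
        covered.append((lo <= theta_star[free]) & (theta_star[free] <= hi))
    E = np.asarray(ests)
    C = np.asarray(covered)
    mcse = E.std(axis=0, ddof=1) / np.sqrt(n_fits)
    return pd.DataFrame({
        "parameter": spec.free_names,
        "truth": theta_star[free],
        "mean": E.mean(axis=0),
        "sd": E.std(axis=0, ddof=1),
        "mc_se": mcse,
        "bias": E.mean(axis=0) - theta_star[free],
        "coverage": C.mean(axis=0),
    })


# ---------------------------------------------------------------------------
# School-context moderator recovery
# ---------------------------------------------------------------------------

def _moderator_spec(waves: int, single_sex: bool) -> ModelSpec:
    """Reduced network + secrecy co-evolution model for the moderator study."""
    return ModelSpec.build(
        waves - 1, single_sex=single_sex, dimensions=("network", "secrecy"),
        exclude=("in_pop_sqrt", "fsm_sim",
                 "alc_alter", "alc_ego", "alc_sim",
                 "con_alter", "con_ego", "con_sim", "con_ego_x_alc_sim",
                 "sec_avsim", "sec_alt_avg_alc", "sec_quad", "sec_fsm"))


def moderator_recovery_experiment(n_reps: int = 50, seed: int = 0,
                                  boys_offset: float = 0.4,
                                  n_schools: tuple[int, int, int] = (9, 8, 5),
                                  size_range: tuple[int, int] = (30, 40),
                                  waves: int = 2,
                                  options: EstimationOptions | None = None) -> dict:
    """22-school studies with a boys-school shift on secrecy-alter selection.

    Each replicate generates 9 coeducational, 8 girls and 5 boys schools
    at reduced scale, with the secrecy-alter tie effect offset by
    ``boys_offset`` in boys schools, fits every school, and runs the
    school-context meta-regression (intercept, boys, girls, centred
    prevalence).  Reports the distribution of the boys coefficient.
    """
    cfg = SynthConfig()
    base_theta = {"outdegree": -2.2, "reciprocity": 1.5, "trans_trip": 0.3,
                  "same_gender": 0.5, "sec_linear": 0.1}
    rates = {"rate_net_p": 5.0, "rate_sec_p": 0.8}
    # Reduced-scale fits: every school with finite standard errors enters
    # the meta-regression.  The strict per-fit convergence flag is designed
    # for production phase-3 sizes; at this scale it would drop schools on
    # Monte-Carlo noise and unbalance the school-type design.
    options = options or EstimationOptions(
        n1=10, newton_iters=8, refresh_every=2, n_dev=15,
        final_iters=40, final_gain=0.12, n_avg=3, n3=300, max_restarts=0)
    types = ["coed"] * n_schools[0] + ["girls"] * n_schools[1] + ["boys"] * n_schools[2]
    root = np.random.SeedSequence(seed).generate_state(n_reps) >> 1
    boys_coefs, intercepts, n_used = [], [], []
    for rep in range(n_reps):
        rng = np.random.default_rng(int(root[rep]))
        ests, ses, meta_rows = [], [], []
        for st_type in types:
            single = st_type in ("girls", "boys")
            spec = _moderator_spec(waves, single)
            theta = spec.theta_template()
            for nm, v in base_theta.items():
                if not spec[nm].fixed:
                    theta[spec[nm].index] = v
            if st_type == "boys":
                theta[spec["sec_alter"].index] += boys_offset
            for m in range(1, waves):
                theta[spec[f"rate_net_p{m}"].index] = rates["rate_net_p"]
                theta[spec[f"rate_sec_p{m}"].index] = rates["rate_sec_p"]
            n = int(rng.integers(size_range[0], size_range[1] + 1))
            state, gender, fsm = _wave1_state(cfg, n, st_type, rng)
            rate_sets = [RateSet(*row) for row in spec.pack(theta)[4]]
            panel = simulate_panel(state, theta, rate_sets, spec, gender, fsm,
                                   int(rng.integers(2**31)), school_type=st_type)
            fit = estimate_school(panel, spec, options,
                                  seed=int(rng.integers(2**31)))
            est, se = fit.get("sec_alter", spec)
            if np.isfinite(se) and se > 0:
                ests.append(est)
                ses.append(se)
                meta_rows.append({"school_id": "x", "school_type": st_type,
                                  "year3_weekly_prevalence": float(rng.uniform(0.1, 0.4))})
        sub = pd.DataFrame(meta_rows)
        if sub.empty or (sub["school_type"] == "boys").sum() < 2:
            continue
        X, names = encode_moderators(sub)
        reg = meta_regression(np.array(ests), np.array(ses), X, names)
        boys_coefs.append(float(reg.coef[names.index("boys")]))
        intercepts.append(float(reg.coef[0]))
        n_used.append(len(ests))
    boys_coefs = np.asarray(boys_coefs)
    return {
        "boys_coefs": boys_coefs,
        "mean": float(boys_coefs.mean()),
        "mc_se": float(boys_coefs.std(ddof=1) / np.sqrt(len(boys_coefs))),
        "sign_correct": float(np.mean(np.sign(boys_coefs) == np.sign(boys_offset))),
        "truth": boys_offset,
        "n_reps_used": len(boys_coefs),
        "mean_schools_used": float(np.mean(n_used)),
    }


# ---------------------------------------------------------------------------
# GOF calibration
# ---------------------------------------------------------------------------

def gof_calibration_experiment(n_reps: int = 50, n: int = 30, seed: int = 0,
                               n_gof: int = 100,
                               options: EstimationOptions | None = None) -> dict:
    """p-value calibration of the auxiliary-statistic GOF under a true model.

    Replicates: simulate a 2-wave structural-only network panel at theta*,
    refit, simulate the reference cloud at theta-hat, and compute the
    Monte-Carlo GOF p-value of the observed wave-2 auxiliaries (degree
    distributions + triad census).  Under a correctly specified model the
    p-values should be roughly uniform; returns the Kolmogorov-Smirnov
    statistic against the uniform distribution.
    """
    cfg = SynthConfig()
    spec = ModelSpec.build(1, single_sex=True, dimensions=("network",),
                           exclude=("in_pop_sqrt", "fsm_sim", "alc_alter",
                                    "alc_ego", "alc_sim", "con_alter", "con_ego",
                                    "con_sim", "con_ego_x_alc_sim",
                                    "sec_alter", "sec_ego", "sec_sim"))
    theta_star = spec.theta_template()
    theta_star[spec["outdegree"].index] = -2.2
    theta_star[spec["reciprocity"].index] = 1.5
    theta_star[spec["trans_trip"].index] = 0.3
    theta_star[spec["rate_net_p1"].index] = 5.0
    options = options or EstimationOptions(
        n1=10, newton_iters=8, refresh_every=2, n_dev=15,
        final_iters=25, final_gain=0.15, n_avg=3, n3=150, max_restarts=0)
    root = np.random.SeedSequence(seed).generate_state(n_reps) >> 1
    pvals = []
    from .panels import impute_panel
    from .simulate import dyad_class_tables
    for rep in range(n_reps):
        rng = np.random.default_rng(int(root[rep]))
        state, gender, fsm = _wave1_state(cfg, n, "boys", rng)
        rate_sets = [RateSet(*row) for row in spec.pack(theta_star)[4]]
        panel = simulate_panel(state, theta_star, rate_sets, spec, gender, fsm,
                               int(rng.integers(2**31)), school_type="boys")
        fit = estimate_school(panel, spec, options, seed=int(rng.integers(2**31)))
        imp = impute_panel(panel)
        obs_aux = auxiliary_vector(imp.adjacency[1], indegree_cap=10)
        tn = np.ascontiguousarray(fit.theta[:16])
        ta, tc, ts = (np.ascontiguousarray(fit.theta[16:23]),
                      np.ascontiguousarray(fit.theta[23:28]),
                      np.ascontiguousarray(fit.theta[28:34]))
        edy, inv_edy = dyad_class_tables(tn, spec.consts)
        rates_hat = np.ascontiguousarray(fit.theta[34:38])
        sims = []
        for g in range(n_gof):
            adj = imp.adjacency[0].copy()
            beh = imp.behaviors[0].copy()
            kernels.simulate_period_inplace(
                adj, beh[0], beh[1], beh[2], imp.gender, imp.fsm,
                tn, ta, tc, ts, rates_hat, spec.consts, 1.0,
                int(rng.integers(2**31)), edy, inv_edy)
            sims.append(auxiliary_vector(adj, indegree_cap=10))
        _, p = gof_test(obs_aux, np.asarray(sims))
        pvals.append(p)
    pvals = np.sort(np.asarray(pvals))
    grid = (np.arange(1, len(pvals) + 1)) / len(pvals)
    ks = float(np.max(np.abs(pvals - grid)))
    return {"p_values": pvals, "ks_statistic": ks, "n_reps": n_reps}
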