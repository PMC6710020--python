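"""Compiled inner loops for the actor-oriented microstep chain.

Everything here operates on plain arrays so numba can compile it once and
the estimator can run the hundreds of thousands of microsteps a single
method-of-moments fit needs.  The readable reference implementations of the
same statistics live in :mod:`netcoevolve.effects`; the two are pinned
against each other (and against brute-force enumeration) in the test suite.

Parameter packing
-----------------
``tn`` (16,)  network evaluation parameters::

    0 outdegree            1 reciprocity        2 transitive triplets
    3 indegree popularity (sqrt)                4 same gender
    5 fsm similarity
    6 alcohol alter        7 alcohol ego        8 alcohol similarity
    9 control alter       10 control ego       11 control similarity
   12 secrecy alter       13 secrecy ego       14 secrecy similarity
   15 control-ego x alcohol-similarity interaction

``ta`` (7,)  alcohol behaviour: linear, quadratic, total similarity,
control x total-similarity, secrecy x total-similarity, gender, fsm.

``tc`` (5,)  control behaviour: linear, quadratic, effect-from-alcohol,
gender, fsm.

``ts`` (6,)  secrecy behaviour: linear, quadratic, average similarity,
alter-average-drinking, gender, fsm.

``consts`` (10,) centering constants: zbar_alc, zbar_con, zbar_sec,
sbar_alc, sbar_con, sbar_sec, sbar_fsm, range_alc, range_con, range_sec.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CAP = 10          # nomination limit: best friend + up to nine others
N_NET = 16
N_ALC = 7
N_CON = 5
N_SEC = 6
BEH_MAX = (4.0, 3.0, 3.0)   # alcohol 1-4, control/secrecy tertiles 1-3


@njit(cache=True)
def _build_degrees(adj):
    n = adj.shape[0]
    outdeg = np.zeros(n, dtype=np.int64)
    indeg = np.zeros(n, dtype=np.int64)
    outlist = np.zeros((n, CAP), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if adj[i, j] == 1:
                outlist[i, outdeg[i]] = j
                outdeg[i] += 1
                indeg[j] += 1
    return outdeg, indeg, outlist


@njit(cache=True, inline="always")
def _dyad_value(alc, con, sec, gender, fsm, tn, consts, i, j):
    """Non-structural part of the objective gain from the tie i->j.

    Depends only on the two actors' covariates and behaviours, not on the
    network, so it can be cached per ordered dyad and refreshed only when a
    behaviour changes.
    """
    zbar_a, zbar_c, zbar_s = consts[0], consts[1], consts[2]
    sbar_a, sbar_c, sbar_s, sbar_f = consts[3], consts[4], consts[5], consts[6]
    ra, rc, rs = consts[7], consts[8], consts[9]
    d = 0.0
    if gender[i] == gender[j]:
        d += tn[4]
    d += tn[5] * (1.0 - abs(fsm[i] - fsm[j]) - sbar_f)
    sim_a = 1.0 - abs(alc[i] - alc[j]) / ra
    d += tn[6] * (alc[j] - zbar_a)
    d += tn[7] * (alc[i] - zbar_a)
    d += tn[8] * (sim_a - sbar_a)
    d += tn[9] * (con[j] - zbar_c)
    d += tn[10] * (con[i] - zbar_c)
    d += tn[11] * (1.0 - abs(con[i] - con[j]) / rc - sbar_c)
    d += tn[12] * (sec[j] - zbar_s)
    d += tn[13] * (sec[i] - zbar_s)
    d += tn[14] * (1.0 - abs(sec[i] - sec[j]) / rs - sbar_s)
    d += tn[15] * (con[i] - zbar_c) * (sim_a - sbar_a)
    return d


_DY_CLAMP = 50.0   # |dyadic objective| beyond this is astronomically decisive anyway

#: attribute classes: (alcohol 1-4) x (control 1-3) x (secrecy 1-3) x
#: gender x fsm -> 144 combinations
N_CLASSES = 144


@njit(cache=True, inline="always")
def _class_of(alc_i, con_i, sec_i, g_i, f_i):
    return ((((int(alc_i) - 1) * 3 + (int(con_i) - 1)) * 3
             + (int(sec_i) - 1)) * 4 + int(g_i) * 2 + int(f_i))


@njit(cache=True)
def class_tables(tn, consts):
    """exp(dyadic objective) for every ordered pair of attribute classes.

    The non-structural tie value depends on the two actors only through
    their attribute classes, so a 144 x 144 table replaces per-dyad
    caching; it is built once per parameter vector and shared across all
    simulations at that theta.
    """
    alc_c = np.empty(N_CLASSES)
    con_c = np.empty(N_CLASSES)
    sec_c = np.empty(N_CLASSES)
    g_c = np.empty(N_CLASSES)
    f_c = np.empty(N_CLASSES)
    for a in range(4):
        for c in range(3):
            for s in range(3):
                for g in range(2):
                    for f in range(2):
                        k = (((a * 3 + c) * 3 + s) * 4 + g * 2 + f)
                        alc_c[k] = a + 1.0
                        con_c[k] = c + 1.0
                        sec_c[k] = s + 1.0
                        g_c[k] = g
                        f_c[k] = f
    edy = np.empty((N_CLASSES, N_CLASSES))
    inv_edy = np.empty((N_CLASSES, N_CLASSES))
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            v = _dyad_value(alc_c, con_c, sec_c, g_c, f_c, tn, consts, i, j)
            if v > _DY_CLAMP:
                v = _DY_CLAMP
            elif v < -_DY_CLAMP:
                v = -_DY_CLAMP
            w = np.exp(v)
            edy[i, j] = w
            inv_edy[i, j] = 1.0 / w
    return edy, inv_edy


@njit(cache=True)
def _alc_objective(adj, alc, con, sec, gender, fsm, ta, consts,
                   outdeg, outlist, i, z):
    zbar_a, zbar_c, zbar_s = consts[0], consts[1], consts[2]
    sbar_a, ra = consts[3], consts[7]
    c = z - zbar_a
    v = ta[0] * c + ta[1] * c * c
    coef = ta[2] + ta[3] * (con[i] - zbar_c) + ta[4] * (sec[i] - zbar_s)
    if coef != 0.0:
        tot = 0.0
        for q in range(outdeg[i]):
            j = outlist[i, q]
            tot += (1.0 - abs(z - alc[j]) / ra) - sbar_a
        v += coef * tot
    v += ta[5] * c * gender[i] + ta[6] * c * fsm[i]
    return v


@njit(cache=True)
def _con_objective(alc, gender, fsm, tc, consts, i, z):
    zbar_a, zbar_c = consts[0], consts[1]
    c = z - zbar_c
    return (tc[0] * c + tc[1] * c * c + tc[2] * c * (alc[i] - zbar_a)
            + tc[3] * c * gender[i] + tc[4] * c * fsm[i])


@njit(cache=True)
def _sec_objective(adj, alc, sec, gender, fsm, ts, consts,
                   outdeg, outlist, i, z):
    zbar_a, zbar_s = consts[0], consts[2]
    sbar_s, rs = consts[5], consts[9]
    c = z - zbar_s
    v = ts[0] * c + ts[1] * c * c
    od = outdeg[i]
    if od > 0 and (ts[2] != 0.0 or ts[3] != 0.0):
        ssum = 0.0
        asum = 0.0
        for q in range(od):
            j = outlist[i, q]
            ssum += (1.0 - abs(z - sec[j]) / rs) - sbar_s
            asum += alc[j] - zbar_a
        v += ts[2] * ssum / od + ts[3] * c * asum / od
    v += ts[4] * c * gender[i] + ts[5] * c * fsm[i]
    return v


@njit(cache=True)
def _choose(values, k):
    """Multinomial-logit draw over values[:k] with log-sum-exp stabilisation."""
    vmax = -1.0e300
    for q in range(k):
        if values[q] > vmax:
            vmax = values[q]
    total = 0.0
    for q in range(k):
        values[q] = np.exp(values[q] - vmax)
        total += values[q]
    u = np.random.random() * total
    acc = 0.0
    for q in range(k):
        acc += values[q]
        if u <= acc:
            return q
    return k - 1


@njit(cache=True)
def simulate_period_inplace(adj, alc, con, sec, gender, fsm,
                            tn, ta, tc, ts, rates, consts,
                            horizon, seed, edy, inv_edy):
    """Run the continuous-time microstep chain for one period, in place.

    rates = (network, alcohol, control, secrecy) per-actor change rates;
    (edy, inv_edy) are the class tables from :func:`class_tables` for the
    same (tn, consts).  Returns the number of microsteps taken.
    """
    np.random.seed(seed)
    n = adj.shape[0]
    rate_sum = rates[0] + rates[1] + rates[2] + rates[3]
    total_rate = n * rate_sum
    if total_rate <= 0.0:
        return 0
    outdeg, indeg, outlist = _build_degrees(adj)
    ci = np.empty(n, dtype=np.int64)
    for q in range(n):
        ci[q] = _class_of(alc[q], con[q], sec[q], gender[q], fsm[q])
    # lookup tables for the structural exponentials: no exp() in the loop
    sq = np.sqrt(np.arange(n + 2).astype(np.float64))
    e_out = np.exp(tn[0])
    e_rec_add = np.exp(tn[1])
    e_rec_del = 1.0 / e_rec_add
    inv_e_out = 1.0 / e_out
    ett_add = np.exp(tn[2] * np.arange(2 * CAP + 1).astype(np.float64))
    ett_del = 1.0 / ett_add
    epop_add = np.exp(tn[3] * sq)      # indexed by new indegree
    epop_del = 1.0 / epop_add          # indexed by current indegree
    values = np.empty(max(n + 1, 3))  # behaviour steps need 3 candidate slots
    t = 0.0
    nsteps = 0
    while True:
        t += np.random.exponential(1.0 / total_rate)
        if t >= horizon:
            break
        i = np.random.randint(0, n)
        u = np.random.random() * rate_sum
        if u < rates[0]:
            # network microstep: toggle one tie or keep the status quo.
            # Multinomial-logit weights are products of cached exponentials.
            at_cap = outdeg[i] >= CAP
            use_tt = tn[2] != 0.0
            total = 1.0                      # the no-change option
            for j in range(n):
                if j == i or (adj[i, j] == 0 and at_cap):
                    values[j] = 0.0
                    continue
                a = 0
                if use_tt:
                    for q in range(outdeg[j]):
                        if adj[i, outlist[j, q]] == 1:
                            a += 1
                    for q in range(outdeg[i]):
                        if adj[outlist[i, q], j] == 1:
                            a += 1
                if adj[i, j] == 0:
                    w = e_out * edy[ci[i], ci[j]] * ett_add[a] * epop_add[indeg[j] + 1]
                    if adj[j, i] == 1:
                        w *= e_rec_add
                else:
                    w = inv_e_out * inv_edy[ci[i], ci[j]] * ett_del[a] * epop_del[indeg[j]]
                    if adj[j, i] == 1:
                        w *= e_rec_del
                values[j] = w
                total += w
            r = np.random.random() * total
            k = n                            # default: keep the status quo
            acc = 0.0
            for j in range(n):
                acc += values[j]
                if r <= acc:
                    k = j
                    break
            if k < n:
                if adj[i, k] == 0:
                    adj[i, k] = 1
                    outlist[i, outdeg[i]] = k
                    outdeg[i] += 1
                    indeg[k] += 1
                else:
                    adj[i, k] = 0
                    indeg[k] -= 1
                    for q in range(outdeg[i]):
                        if outlist[i, q] == k:
                            outlist[i, q] = outlist[i, outdeg[i] - 1]
                            break
                    outdeg[i] -= 1
        else:
            if u < rates[0] + rates[1]:
                b, cur, hi = 0, alc[i], BEH_MAX[0]
            elif u < rates[0] + rates[1] + rates[2]:
                b, cur, hi = 1, con[i], BEH_MAX[1]
            else:
                b, cur, hi = 2, sec[i], BEH_MAX[2]
            k = 0
            cand0 = cur - 1.0
            for step in range(3):
                z = cand0 + step
                if z < 1.0 or z > hi:
                    continue
                if b == 0:
                    values[k] = _alc_objective(adj, alc, con, sec, gender, fsm,
                                               ta, consts, outdeg, outlist, i, z)
                elif b == 1:
                    values[k] = _con_objective(alc, gender, fsm, tc, consts, i, z)
                else:
                    values[k] = _sec_objective(adj, alc, sec, gender, fsm,
                                               ts, consts, outdeg, outlist, i, z)
                k += 1
            chosen = _choose(values, k)
            z = cand0
            cnt = 0
            for step in range(3):
                zz = cand0 + step
                if zz < 1.0 or zz > hi:
                    continue
                if cnt == chosen:
                    z = zz
                    break
                cnt += 1
            if z != cur:
                if b == 0:
                    alc[i] = z
                elif b == 1:
                    con[i] = z
                else:
                    sec[i] = z
                ci[i] = _class_of(alc[i], con[i], sec[i], gender[i], fsm[i])
        nsteps += 1
    return nsteps


@njit(cache=True)
def network_stats_total(adj, alc, con, sec, gender, fsm, consts):
    """The 16 network evaluation statistics summed over all actors."""
    n = adj.shape[0]
    zbar_a, zbar_c, zbar_s = consts[0], consts[1], consts[2]
    sbar_a, sbar_c, sbar_s, sbar_f = consts[3], consts[4], consts[5], consts[6]
    ra, rc, rs = consts[7], consts[8], consts[9]
    outdeg, indeg, outlist = _build_degrees(adj)
    s = np.zeros(N_NET)
    for i in range(n):
        for q in range(outdeg[i]):
            j = outlist[i, q]
            s[0] += 1.0
            s[1] += adj[j, i]
            tt = 0.0
            for r in range(outdeg[j]):
                if adj[i, outlist[j, r]] == 1:
                    tt += 1.0
            s[2] += tt
            s[3] += np.sqrt(float(indeg[j]))
            if gender[i] == gender[j]:
                s[4] += 1.0
            s[5] += 1.0 - abs(fsm[i] - fsm[j]) - sbar_f
            sim_a = 1.0 - abs(alc[i] - alc[j]) / ra
            s[6] += alc[j] - zbar_a
            s[7] += alc[i] - zbar_a
            s[8] += sim_a - sbar_a
            s[9] += con[j] - zbar_c
            s[10] += con[i] - zbar_c
            s[11] += 1.0 - abs(con[i] - con[j]) / rc - sbar_c
            s[12] += sec[j] - zbar_s
            s[13] += sec[i] - zbar_s
            s[14] += 1.0 - abs(sec[i] - sec[j]) / rs - sbar_s
            s[15] += (con[i] - zbar_c) * (sim_a - sbar_a)
    return s


@njit(cache=True)
def behavior_stats_total(adj, alc, con, sec, gender, fsm, consts):
    """Alcohol (7), control (5) and secrecy (6) statistics summed over actors."""
    n = adj.shape[0]
    zbar_a, zbar_c, zbar_s = consts[0], consts[1], consts[2]
    sbar_a, sbar_s = consts[3], consts[5]
    ra, rs = consts[7], consts[9]
    outdeg, _, outlist = _build_degrees(adj)
    out = np.zeros(N_ALC + N_CON + N_SEC)
    for i in range(n):
        ca = alc[i] - zbar_a
        tot = 0.0
        for q in range(outdeg[i]):
            j = outlist[i, q]
            tot += (1.0 - abs(alc[i] - alc[j]) / ra) - sbar_a
        out[0] += ca
        out[1] += ca * ca
        out[2] += tot
        out[3] += (con[i] - zbar_c) * tot
        out[4] += (sec[i] - zbar_s) * tot
        out[5] += ca * gender[i]
        out[6] += ca * fsm[i]

        cc = con[i] - zbar_c
        out[7] += cc
        out[8] += cc * cc
        out[9] += cc * ca
        out[10] += cc * gender[i]
        out[11] += cc * fsm[i]

        cs = sec[i] - zbar_s
        out[12] += cs
        out[13] += cs * cs
        if outdeg[i] > 0:
            ssum = 0.0
            asum = 0.0
            for q in range(outdeg[i]):
                j = outlist[i, q]
                ssum += (1.0 - abs(sec[i] - sec[j]) / rs) - sbar_s
                asum += alc[j] - zbar_a
            out[14] += ssum / outdeg[i]
            out[15] += cs * asum / outdeg[i]
        out[16] += cs * gender[i]
        out[17] += cs * fsm[i]
    return out


@njit(cache=True)
def triad_census_kernel(adj, table):
    """Count unordered triples in each of the 16 directed-triad classes.

    ``table`` maps the 6-bit edge code of a triple to its class index.
    """
    n = adj.shape[0]
    census = np.zeros(16, dtype=np.int64)
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                code = (adj[i, j] + 2 * adj[j, i] + 4 * adj[i, k]
                        + 8 * adj[k, i] + 16 * adj[j, k] + 32 * adj[k, j])
                census[table[code]] += 1
    return census
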