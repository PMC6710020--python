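"""Effect definitions, objective functions and target statistics.

The model couples one directed friendship network with three ordinal
behaviours (drinking frequency 1-4, parental-control and secrecy tertiles
1-3).  Every actor carries an objective function per dependent variable; a
microstep changes the state toward options with higher objective value via
a multinomial logit.  This module owns the declarative description of the
effect set (:class:`ModelSpec`), the centering constants shared by all
similarity effects, readable per-actor statistic implementations, and the
observed method-of-moments targets.

The canonical parameter vector is laid out as::

    [16 network effects][7 alcohol][5 control][6 secrecy][4 rates x period]

matching the packing documented in :mod:`netcoevolve.kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import kernels
from .panels import ImputedPanel, SchoolPanel, impute_panel

DIMENSIONS = ("network", "alcohol", "control", "secrecy")
BEHAVIORS = ("alcohol", "control", "secrecy")
BEH_RANGES = {"alcohol": 3.0, "control": 2.0, "secrecy": 2.0}
BEH_BOUNDS = {"alcohol": (1.0, 4.0), "control": (1.0, 3.0), "secrecy": (1.0, 3.0)}

NETWORK_EFFECTS = (
    "outdegree", "reciprocity", "trans_trip", "in_pop_sqrt",
    "same_gender", "fsm_sim",
    "alc_alter", "alc_ego", "alc_sim",
    "con_alter", "con_ego", "con_sim",
    "sec_alter", "sec_ego", "sec_sim",
    "con_ego_x_alc_sim",
)
ALCOHOL_EFFECTS = (
    "alc_linear", "alc_quad", "alc_totsim",
    "alc_con_x_totsim", "alc_sec_x_totsim", "alc_gender", "alc_fsm",
)
CONTROL_EFFECTS = ("con_linear", "con_quad", "con_from_alc", "con_gender", "con_fsm")
SECRECY_EFFECTS = (
    "sec_linear", "sec_quad", "sec_avsim", "sec_alt_avg_alc",
    "sec_gender", "sec_fsm",
)
N_EVAL = 16 + 7 + 5 + 6   # evaluation-effect slots before the rate block

_KINDS = {
    "outdegree": "structural", "reciprocity": "structural",
    "trans_trip": "structural", "in_pop_sqrt": "structural",
    "same_gender": "covariate", "fsm_sim": "covariate",
    "con_ego_x_alc_sim": "interaction",
    "alc_con_x_totsim": "interaction", "alc_sec_x_totsim": "interaction",
    "con_from_alc": "behavior_linked", "sec_alt_avg_alc": "behavior_linked",
}


class EffectError(ValueError):
    """Raised for inconsistent effect specifications."""


@dataclass(frozen=True)
class EffectSpec:
    """One effect: a named statistic with a parameter slot."""

    name: str
    dependent: str                      # network | alcohol | control | secrecy | one of them for rates
    kind: str                           # structural | covariate | behavior_linked | interaction | shape | rate
    index: int                          # slot in the full parameter vector
    refs: tuple[str, ...] = ()
    fixed: bool = False
    fixed_value: float = 0.0
    period: int | None = None           # 1-based, rate effects only


def _base_effects(n_periods: int) -> list[EffectSpec]:
    effects: list[EffectSpec] = []
    idx = 0
    for name in NETWORK_EFFECTS:
        kind = _KINDS.get(name, "behavior_linked" if name[:3] in ("alc", "con", "sec") else "structural")
        effects.append(EffectSpec(name, "network", kind, idx))
        idx += 1
    for group, dep in ((ALCOHOL_EFFECTS, "alcohol"), (CONTROL_EFFECTS, "control"),
                       (SECRECY_EFFECTS, "secrecy")):
        for name in group:
            kind = _KINDS.get(name, "shape" if name.endswith(("linear", "quad")) else "behavior_linked")
            effects.append(EffectSpec(name, dep, kind, idx))
            idx += 1
    for m in range(1, n_periods + 1):
        for dim in DIMENSIONS:
            effects.append(EffectSpec(f"rate_{dim[:3]}_p{m}", dim, "rate", idx, period=m))
            idx += 1
    return effects


@dataclass
class ModelSpec:
    """Ordered effect list plus the centering constants they reference.

    ``consts`` packs (zbar_alc, zbar_con, zbar_sec, sbar_alc, sbar_con,
    sbar_sec, sbar_fsm, range_alc, range_con, range_sec): behaviour means
    and mean similarities are computed per school over all observed
    actor-waves, ranges are theoretical.
    """

    effects: list[EffectSpec]
    consts: np.ndarray
    n_periods: int

    def __post_init__(self) -> None:
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise EffectError("duplicate effect names")
        self._by_name = {e.name: e for e in self.effects}

    # -- lookup ------------------------------------------------------------
    def __getitem__(self, name: str) -> EffectSpec:
        return self._by_name[name]

    @property
    def n_params(self) -> int:
        return len(self.effects)

    @property
    def free_indices(self) -> np.ndarray:
        return np.array([e.index for e in self.effects if not e.fixed], dtype=int)

    @property
    def free_names(self) -> list[str]:
        return [e.name for e in self.effects if not e.fixed]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def theta_template(self) -> np.ndarray:
        """Full-length parameter vector holding every fixed value."""
        theta = np.zeros(self.n_params)
        for e in self.effects:
            if e.fixed:
                theta[e.index] = e.fixed_value
        return theta

    def expand(self, theta_free: np.ndarray) -> np.ndarray:
        theta = self.theta_template()
        theta[self.free_indices] = theta_free
        return theta

    def pack(self, theta_full: np.ndarray):
        """Split a full vector into kernel arrays (tn, ta, tc, ts, rates[P, 4])."""
        tn = np.asarray(theta_full[:16], dtype=float)
        ta = np.asarray(theta_full[16:23], dtype=float)
        tc = np.asarray(theta_full[23:28], dtype=float)
        ts = np.asarray(theta_full[28:34], dtype=float)
        rates = np.asarray(theta_full[34:], dtype=float).reshape(self.n_periods, 4)
        return tn, ta, tc, ts, rates

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_panel(
        cls,
        panel: SchoolPanel,
        *,
        exclude: Iterable[str] = (),
        fix: Mapping[str, float] | None = None,
        dimensions: Sequence[str] = DIMENSIONS,
    ) -> "ModelSpec":
        """Build the full effect set for one school.

        ``exclude`` fixes named effects at 0; ``fix`` fixes them at a given
        value; ``dimensions`` lists the co-evolving dependent variables —
        behaviours left out are treated as static covariates (their shape
        and rate parameters are fixed at 0).  Zero-variance covariate
        effects (same-gender and gender predictors in single-sex schools)
        are fixed at 0 automatically.
        """
        return cls.build(
            panel.n_waves - 1, centering_constants(panel),
            exclude=exclude, fix=fix, dimensions=dimensions,
            single_sex=panel.school_type in ("girls", "boys"))

    @classmethod
    def build(
        cls,
        n_periods: int,
        consts: np.ndarray | None = None,
        *,
        exclude: Iterable[str] = (),
        fix: Mapping[str, float] | None = None,
        dimensions: Sequence[str] = DIMENSIONS,
        single_sex: bool = False,
    ) -> "ModelSpec":
        """Build a spec without data, e.g. to drive the synthetic generator.

        Default centering constants put the behaviour means at scale
        midpoints with mean similarities typical of tertiled covariates.
        """
        if consts is None:
            consts = np.array([2.0, 2.0, 2.0, 0.65, 0.65, 0.65, 0.7, 3.0, 2.0, 2.0])
        effects = _base_effects(n_periods)
        fix = dict(fix or {})
        for name in exclude:
            fix.setdefault(name, 0.0)
        if single_sex:
            for name in ("same_gender", "alc_gender", "con_gender", "sec_gender"):
                fix.setdefault(name, 0.0)
        inactive = [d for d in DIMENSIONS if d not in dimensions]
        for e in effects:
            if e.kind == "rate" and e.dependent in inactive:
                fix.setdefault(e.name, 0.0)
            if e.kind != "rate" and e.dependent in inactive and e.dependent != "network":
                fix.setdefault(e.name, 0.0)
        unknown = set(fix) - {e.name for e in effects}
        if unknown:
            raise EffectError(f"unknown effect names: {sorted(unknown)}")
        out = [replace(e, fixed=True, fixed_value=float(fix[e.name]))
               if e.name in fix else e for e in effects]
        return cls(out, np.asarray(consts, dtype=float), n_periods)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_periods": self.n_periods,
            "consts": self.consts.tolist(),
            "effects": [
                {"name": e.name, "dependent": e.dependent, "kind": e.kind,
                 "index": e.index, "fixed": e.fixed, "fixed_value": e.fixed_value,
                 "period": e.period}
                for e in self.effects
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        effects = [EffectSpec(**e) for e in d["effects"]]
        return cls(effects, np.asarray(d["consts"], dtype=float), int(d["n_periods"]))


# ---------------------------------------------------------------------------
# Centering constants
# ---------------------------------------------------------------------------

def centering_constants(panel: SchoolPanel) -> np.ndarray:
    """Per-school behaviour means and mean similarities over observed actor-waves."""
    zbar = []
    sbar = []
    for b, attr in enumerate(("alcohol", "control", "secrecy")):
        rng = BEH_RANGES[attr]
        all_vals = np.concatenate([getattr(w, attr)[~np.isnan(getattr(w, attr))]
                                   for w in panel.waves])
        zbar.append(float(all_vals.mean()) if all_vals.size else 0.0)
        sims = []
        for w in panel.waves:
            v = getattr(w, attr)
            obs = v[~np.isnan(v)]
            if obs.size >= 2:
                diff = np.abs(obs[:, None] - obs[None, :])
                k = obs.size
                sims.append((1.0 - diff / rng)[~np.eye(k, dtype=bool)].mean())
        sbar.append(float(np.mean(sims)) if sims else 0.0)
    f = panel.fsm.astype(float)
    n = len(f)
    if n >= 2:
        diff = np.abs(f[:, None] - f[None, :])
        sbar_fsm = float((1.0 - diff)[~np.eye(n, dtype=bool)].mean())
    else:
        sbar_fsm = 0.0
    return np.array(zbar + sbar + [sbar_fsm, 3.0, 2.0, 2.0])


# ---------------------------------------------------------------------------
# Reference (readable) statistic implementations
# ---------------------------------------------------------------------------

def dyadic_similarity(v_i: float, v_j: float, value_range: float) -> float:
    """sim(i, j) = 1 - |v_i - v_j| / range, in [0, 1]."""
    if value_range <= 0:
        raise EffectError("similarity range must be positive")
    d = abs(v_i - v_j)
    if d > value_range:
        raise EffectError("attribute difference exceeds the declared range")
    return 1.0 - d / value_range


def network_statistics(i: int, adj: np.ndarray, beh: np.ndarray,
                       gender: np.ndarray, fsm: np.ndarray,
                       consts: np.ndarray) -> np.ndarray:
    """The 16 network evaluation statistics of actor ``i`` (readable form)."""
    zbar = consts[0:3]
    sbar = consts[3:6]
    sbar_f = consts[6]
    rng = consts[7:10]
    alc, con, sec = beh
    x = adj
    n = x.shape[0]
    row = x[i].astype(float)
    outdeg = row.sum()
    indeg = x.sum(axis=0).astype(float)
    s = np.zeros(16)
    s[0] = outdeg
    s[1] = float(row @ x[:, i])
    s[2] = sum(float(x[i, j] and x[j, h] and x[i, h])
               for j in range(n) for h in range(n))
    s[3] = float(row @ np.sqrt(indeg))
    s[4] = float(row @ (gender == gender[i]))
    s[5] = float(row @ (1.0 - np.abs(fsm - fsm[i]) - sbar_f))
    for b, v in enumerate((alc, con, sec)):
        if np.isnan(v[i]) or np.any(np.isnan(v[row == 1])):
            raise EffectError("missing behaviour value; impute before evaluation")
        sim = 1.0 - np.abs(v - v[i]) / rng[b]
        s[6 + 3 * b] = float(row @ (v - zbar[b]))
        s[7 + 3 * b] = (v[i] - zbar[b]) * outdeg
        s[8 + 3 * b] = float(row @ (sim - sbar[b]))
    sim_a = 1.0 - np.abs(alc - alc[i]) / rng[0]
    s[15] = (con[i] - zbar[1]) * float(row @ (sim_a - sbar[0]))
    return s


def behavior_statistics(i: int, behavior: str, z_i: float, adj: np.ndarray,
                        beh: np.ndarray, gender: np.ndarray, fsm: np.ndarray,
                        consts: np.ndarray) -> np.ndarray:
    """Evaluation statistics of actor ``i`` for one behaviour at level ``z_i``."""
    lo, hi = BEH_BOUNDS[behavior]
    if not lo <= z_i <= hi:
        raise EffectError(f"candidate level {z_i} outside [{lo}, {hi}]")
    zbar = consts[0:3]
    sbar = consts[3:6]
    rng = consts[7:10]
    alc, con, sec = beh
    row = adj[i].astype(float)
    outdeg = row.sum()
    b = BEHAVIORS.index(behavior)
    c = z_i - zbar[b]
    if behavior == "alcohol":
        sim = 1.0 - np.abs(alc - z_i) / rng[0]
        tot = float(row @ (sim - sbar[0]))
        return np.array([
            c, c * c, tot,
            (con[i] - zbar[1]) * tot,
            (sec[i] - zbar[2]) * tot,
            c * gender[i], c * fsm[i],
        ])
    if behavior == "control":
        return np.array([c, c * c, c * (alc[i] - zbar[0]),
                         c * gender[i], c * fsm[i]])
    sim = 1.0 - np.abs(sec - z_i) / rng[2]
    denom = max(1.0, outdeg)
    avsim = float(row @ (sim - sbar[2])) / denom
    av_drink = float(row @ (alc - zbar[0])) / denom
    return np.array([c, c * c, avsim, c * av_drink, c * gender[i], c * fsm[i]])


def network_evaluation(i: int, adj: np.ndarray, beh: np.ndarray,
                       gender: np.ndarray, fsm: np.ndarray,
                       theta: np.ndarray, spec: ModelSpec) -> float:
    """Actor ``i``'s network objective f_i = sum_k theta_k s_ik."""
    tn = spec.pack(np.asarray(theta, dtype=float))[0]
    return float(tn @ network_statistics(i, adj, beh, gender, fsm, spec.consts))


def behavior_evaluation(i: int, behavior: str, z_i: float, adj: np.ndarray,
                        beh: np.ndarray, gender: np.ndarray, fsm: np.ndarray,
                        theta: np.ndarray, spec: ModelSpec) -> float:
    """Actor ``i``'s behaviour objective for candidate level ``z_i``."""
    _, ta, tc, ts, _ = spec.pack(np.asarray(theta, dtype=float))
    coef = {"alcohol": ta, "control": tc, "secrecy": ts}[behavior]
    return float(coef @ behavior_statistics(i, behavior, z_i, adj, beh,
                                            gender, fsm, spec.consts))


# ---------------------------------------------------------------------------
# Method-of-moments targets
# ---------------------------------------------------------------------------

def eval_stats_state(adj: np.ndarray, beh: np.ndarray, gender: np.ndarray,
                     fsm: np.ndarray, consts: np.ndarray) -> np.ndarray:
    """All 34 evaluation statistics of one state, summed over actors (fast path)."""
    alc, con, sec = np.ascontiguousarray(beh)
    net = kernels.network_stats_total(adj, alc, con, sec, gender, fsm, consts)
    bstats = kernels.behavior_stats_total(adj, alc, con, sec, gender, fsm, consts)
    return np.concatenate([net, bstats])


def period_eval_stats(adj0: np.ndarray, beh0: np.ndarray,
                      adj1: np.ndarray, beh1: np.ndarray,
                      gender: np.ndarray, fsm: np.ndarray,
                      consts: np.ndarray) -> np.ndarray:
    """Cross-lagged evaluation-statistic targets for one period.

    Network-effect statistics pair the period-end network with the
    period-start behaviours; each behaviour's statistics pair its
    period-end values with the period-start network and the other
    behaviours at period start.  The cross-lagging is what separates
    selection from influence: evaluated on a common end state, the
    network-similarity and total-similarity statistics would be the same
    number and the two processes could not be told apart.
    """
    alc0, con0, sec0 = np.ascontiguousarray(beh0)
    alc1, con1, sec1 = np.ascontiguousarray(beh1)
    net = kernels.network_stats_total(adj1, alc0, con0, sec0, gender, fsm, consts)
    a = kernels.behavior_stats_total(adj0, alc1, con0, sec0, gender, fsm, consts)[:7]
    c = kernels.behavior_stats_total(adj0, alc0, con1, sec0, gender, fsm, consts)[7:12]
    s = kernels.behavior_stats_total(adj0, alc0, con0, sec1, gender, fsm, consts)[12:18]
    return np.concatenate([net, a, c, s])


def change_amounts(adj0, adj1, beh0, beh1, row_mask, beh_mask) -> np.ndarray:
    """Observed amount of change in one period: (network Hamming, sum |dz| x3).

    Restricted to jointly observed out-rows / behaviour values so imputed
    entries never contribute to rate targets.
    """
    net = float(np.abs(adj1[row_mask].astype(int) - adj0[row_mask].astype(int)).sum())
    beh = [float(np.abs(beh1[b][beh_mask[b]] - beh0[b][beh_mask[b]]).sum())
           for b in range(3)]
    return np.array([net] + beh)


def period_masks(imp: ImputedPanel, m: int):
    """Joint-observation masks for period m (waves m, m+1; 0-based)."""
    row_mask = imp.row_observed[m] & imp.row_observed[m + 1]
    beh_mask = imp.beh_observed[m] & imp.beh_observed[m + 1]
    return row_mask, beh_mask


def target_statistics(panel: SchoolPanel, spec: ModelSpec,
                      imp: ImputedPanel | None = None) -> np.ndarray:
    """Observed targets, ordered like the free parameters of ``spec``.

    Evaluation effects: cross-lagged statistics summed over actors and
    end-of-period observations m = 2..M (see :func:`period_eval_stats`).
    Rate effects: observed change amount in their period.
    """
    imp = imp if imp is not None else impute_panel(panel)
    if imp.n_waves != spec.n_periods + 1:
        raise EffectError("spec/panel wave count mismatch")
    eval_sum = np.zeros(N_EVAL)
    changes = []
    for m in range(spec.n_periods):
        eval_sum += period_eval_stats(imp.adjacency[m], imp.behaviors[m],
                                      imp.adjacency[m + 1], imp.behaviors[m + 1],
                                      imp.gender, imp.fsm, spec.consts)
        row_mask, beh_mask = period_masks(imp, m)
        changes.append(change_amounts(imp.adjacency[m], imp.adjacency[m + 1],
                                      imp.behaviors[m], imp.behaviors[m + 1],
                                      row_mask, beh_mask))
    full = np.concatenate([eval_sum] + changes)
    return full[spec.free_indices]
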