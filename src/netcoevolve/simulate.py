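"""Continuous-time actor-oriented microstep simulation.

Actors get change opportunities as a Poisson process: with per-actor rates
(lambda_net, lambda_alc, lambda_con, lambda_sec) the total event rate is
n * sum(lambda); waiting times are exponential, and at each event a random
actor either toggles one outgoing tie (respecting the 10-nomination cap)
or moves one behaviour by -1/0/+1 within its range, choosing among the
candidate states by a multinomial logit over the objective function.  The
observation-period horizon is fixed at 1.0; the rates carry the timescale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernels
from .effects import BEH_BOUNDS, ModelSpec
from .panels import SchoolPanel, WaveObservation


class SimulationError(ValueError):
    pass


@dataclass
class RateSet:
    """Per-actor change rates for one period.

    A rate of exactly 0 switches a dimension off (it is then excluded from
    estimation as well); negative rates are invalid.
    """

    network: float
    alcohol: float
    control: float
    secrecy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.network, self.alcohol, self.control, self.secrecy])

    def validate(self) -> "RateSet":
        arr = self.as_array()
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise SimulationError("rates must be finite and nonnegative")
        if arr.sum() <= 0:
            raise SimulationError("at least one rate must be positive")
        return self


@dataclass
class SystemState:
    """Network plus the three behaviour vectors at one instant."""

    adjacency: np.ndarray          # (n, n) int8 binary
    alcohol: np.ndarray            # (n,) float
    control: np.ndarray
    secrecy: np.ndarray
    clock: float = 0.0

    @property
    def n_actors(self) -> int:
        return self.adjacency.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(self.adjacency.copy(), self.alcohol.copy(),
                           self.control.copy(), self.secrecy.copy(), self.clock)

    def validate(self) -> "SystemState":
        adj = self.adjacency
        if np.any(np.diag(adj) != 0):
            raise SimulationError("adjacency diagonal must be zero")
        if not np.isin(adj, (0, 1)).all():
            raise SimulationError("adjacency must be binary")
        if np.any(adj.sum(axis=1) > kernels.CAP):
            raise SimulationError(f"outdegree above the cap of {kernels.CAP}")
        for name, v in (("alcohol", self.alcohol), ("control", self.control),
                        ("secrecy", self.secrecy)):
            lo, hi = BEH_BOUNDS[name]
            if np.any(v < lo) or np.any(v > hi):
                raise SimulationError(f"{name} levels outside [{lo}, {hi}]")
        return self


def choice_probabilities(objective_values: np.ndarray) -> np.ndarray:
    """Multinomial-logit probabilities with log-sum-exp stabilisation."""
    f = np.asarray(objective_values, dtype=float)
    if f.size == 0:
        raise SimulationError("empty choice set")
    if np.any(np.isnan(f)):
        raise SimulationError("NaN objective value")
    w = np.exp(f - f.max())
    return w / w.sum()


def network_choice_set(i: int, state: SystemState) -> list[SystemState]:
    """The no-change state plus every permissible single-tie toggle by actor i."""
    state.validate()
    out = [state.copy()]
    at_cap = state.adjacency[i].sum() >= kernels.CAP
    for j in range(state.n_actors):
        if j == i:
            continue
        if state.adjacency[i, j] == 0 and at_cap:
            continue
        cand = state.copy()
        cand.adjacency[i, j] = 1 - cand.adjacency[i, j]
        out.append(cand)
    return out


def _theta_arrays(theta: np.ndarray, spec: ModelSpec):
    tn, ta, tc, ts, _ = spec.pack(np.asarray(theta, dtype=float))
    return (np.ascontiguousarray(tn), np.ascontiguousarray(ta),
            np.ascontiguousarray(tc), np.ascontiguousarray(ts))


_TABLE_CACHE: dict[bytes, tuple] = {}


def dyad_class_tables(tn: np.ndarray, consts: np.ndarray):
    """Memoised 144 x 144 attribute-class weight tables for (tn, consts)."""
    key = tn.tobytes() + consts.tobytes()
    hit = _TABLE_CACHE.get(key)
    if hit is None:
        if len(_TABLE_CACHE) > 256:
            _TABLE_CACHE.clear()
        hit = kernels.class_tables(np.ascontiguousarray(tn),
                                   np.ascontiguousarray(consts))
        _TABLE_CACHE[key] = hit
    return hit


def simulate_period(start: SystemState, theta: np.ndarray, rates: RateSet,
                    spec: ModelSpec, gender: np.ndarray, fsm: np.ndarray,
                    seed: int, horizon: float = 1.0) -> tuple[SystemState, int]:
    """Simulate one observation period; returns (end state, microstep count).

    Deterministic given (seed, inputs).
    """
    rates.validate()
    if not np.all(np.isfinite(theta)):
        raise SimulationError("non-finite parameter value")
    end = start.copy()
    tn, ta, tc, ts = _theta_arrays(theta, spec)
    edy, inv_edy = dyad_class_tables(tn, spec.consts)
    nsteps = kernels.simulate_period_inplace(
        end.adjacency, end.alcohol, end.control, end.secrecy,
        np.ascontiguousarray(gender, dtype=float),
        np.ascontiguousarray(fsm, dtype=float),
        tn, ta, tc, ts, rates.as_array(), spec.consts,
        float(horizon), int(seed) & 0x7FFFFFFF, edy, inv_edy)
    end.clock = start.clock + horizon
    return end, int(nsteps)


def simulate_panel(wave1: SystemState, theta: np.ndarray,
                   rates_per_period: list[RateSet], spec: ModelSpec,
                   gender: np.ndarray, fsm: np.ndarray, seed: int,
                   school_id: str = "sim", school_type: str = "coed") -> SchoolPanel:
    """Chain periods from a wave-1 state into a fully observed panel."""
    if len(rates_per_period) < 1:
        raise SimulationError("need at least one period")
    rng = np.random.SeedSequence(int(seed))
    seeds = rng.generate_state(len(rates_per_period)) >> 1
    states = [wave1.validate().copy()]
    for m, rates in enumerate(rates_per_period):
        nxt, _ = simulate_period(states[-1], theta, rates, spec,
                                 gender, fsm, int(seeds[m]))
        states.append(nxt)
    n = wave1.n_actors
    waves = [
        WaveObservation(
            adjacency=s.adjacency.astype(np.int8),
            present=np.ones(n, dtype=bool),
            alcohol=s.alcohol.astype(float),
            control=s.control.astype(float),
            secrecy=s.secrecy.astype(float),
        )
        for s in states
    ]
    return SchoolPanel(
        school_id=school_id, school_type=school_type,
        actor_ids=[f"a{k:03d}" for k in range(n)],
        waves=waves, gender=np.asarray(gender, dtype=float),
        fsm=np.asarray(fsm, dtype=float),
    ).validate()
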