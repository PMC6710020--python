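"""Synthetic multi-school studies with known ground truth.

The generator emulates the structure of a five-wave adolescent cohort:
22 schools (9 coeducational, 8 girls-only, 5 boys-only) of 60-210 pupils,
a directed friendship network capped at 10 nominations, drinking frequency
on a never/rarely/monthly/weekly 1-4 scale starting near 5% weekly and
rising across waves, parental-control and secrecy tertiles, and roughly
12% wave-level absence.  True parameter values echo plausible pooled
estimates for such cohorts; school-context moderator offsets (e.g. a
boys-school shift on the secrecy-alter selection effect) are part of the
ground truth so the meta-regression stage can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .effects import DIMENSIONS, ModelSpec
from .panels import SchoolPanel
from .simulate import RateSet, SystemState, simulate_panel

DEFAULT_THETA = {
    "outdegree": -2.2,
    "reciprocity": 1.5,
    "trans_trip": 0.3,
    "in_pop_sqrt": 0.2,
    "same_gender": 0.5,       # coeducational schools only
    "fsm_sim": 0.2,
    "alc_sim": 0.35,
    "alc_totsim": 0.46,
    "con_sim": 0.12,
    "sec_avsim": 1.2,
    "con_from_alc": -0.25,
    # behaviour shape drifts: rising drinking, slowly declining control,
    # slowly rising secrecy across adolescence
    "alc_linear": 1.1,
    "alc_quad": -0.05,
    "con_linear": -0.15,
    "sec_linear": 0.10,
}

DEFAULT_RATES = (5.0, 1.2, 0.6, 0.6)     # network, alcohol, control, secrecy


@dataclass
class SynthConfig:
    """Study-design knobs; the defaults are the emulated cohort conditions."""

    n_coed: int = 9
    n_girls: int = 8
    n_boys: int = 5
    size_range: tuple[int, int] = (60, 210)
    waves: int = 5
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    rates: tuple[float, float, float, float] = DEFAULT_RATES
    #: boys/girls offsets and prevalence slopes added to named true effects
    moderator_offsets: dict = field(
        default_factory=lambda: {"sec_alter": {"boys": 0.4}})
    wave1_alcohol_probs: tuple[float, ...] = (0.55, 0.30, 0.10, 0.05)
    absence_prob: float = 0.12
    mean_outdegree: float = 4.0
    gender_homophily: float = 0.8
    fsm_prob_range: tuple[float, float] = (0.05, 0.45)
    dimensions: tuple[str, ...] = DIMENSIONS
    seed: int = 0

    @property
    def n_schools(self) -> int:
        return self.n_coed + self.n_girls + self.n_boys

    def school_type(self, school_index: int) -> str:
        if school_index < self.n_coed:
            return "coed"
        if school_index < self.n_coed + self.n_girls:
            return "girls"
        return "boys"

    def validate(self) -> "SynthConfig":
        if not 0.0 <= self.absence_prob <= 0.5:
            raise ValueError("absence_prob must be in [0, 0.5]")
        if abs(sum(self.wave1_alcohol_probs) - 1.0) > 1e-9:
            raise ValueError("wave-1 alcohol probabilities must sum to 1")
        if self.waves < 2:
            raise ValueError("need at least two waves")
        return self


@dataclass
class GroundTruth:
    """What the generator actually used for one school."""

    school_id: str
    school_type: str
    n_actors: int
    theta: np.ndarray              # full parameter vector after moderator offsets
    rates: np.ndarray              # (n_periods, 4)
    seed: int
    moderator_row: dict

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta"] = self.theta.tolist()
        d["rates"] = self.rates.tolist()
        return d


def _school_spec(config: SynthConfig, school_type: str) -> ModelSpec:
    return ModelSpec.build(
        config.waves - 1,
        single_sex=school_type in ("girls", "boys"),
        dimensions=config.dimensions,
    )


def true_theta(config: SynthConfig, spec: ModelSpec, school_type: str,
               prevalence_centered: float = 0.0) -> np.ndarray:
    """Full true parameter vector for one school, offsets applied."""
    theta = spec.theta_template()
    for name, value in config.theta.items():
        e = spec[name]
        if not e.fixed:
            theta[e.index] = value
    for name, offs in config.moderator_offsets.items():
        e = spec[name]
        if e.fixed:
            continue
        theta[e.index] += offs.get(school_type, 0.0)
        theta[e.index] += offs.get("prevalence", 0.0) * prevalence_centered
    for e in spec.effects:
        if e.kind == "rate" and not e.fixed:
            theta[e.index] = config.rates[DIMENSIONS.index(e.dependent)]
    return theta


def _wave1_state(config: SynthConfig, n: int, school_type: str,
                 rng: np.random.Generator) -> tuple[SystemState, np.ndarray, np.ndarray]:
    if school_type == "girls":
        gender = np.ones(n)
    elif school_type == "boys":
        gender = np.zeros(n)
    else:
        gender = (rng.random(n) < 0.5).astype(float)
    fsm = (rng.random(n) < rng.uniform(*config.fsm_prob_range)).astype(float)

    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        d = int(min(10, rng.poisson(config.mean_outdegree)))
        if d == 0:
            continue
        w = np.exp(config.gender_homophily * (gender == gender[i]).astype(float))
        w[i] = 0.0
        w /= w.sum()
        alters = rng.choice(n, size=d, replace=False, p=w)
        adj[i, alters] = 1

    alcohol = rng.choice(np.arange(1.0, 5.0), size=n, p=config.wave1_alcohol_probs)
    control = rng.choice(np.arange(1.0, 4.0), size=n)
    secrecy = rng.choice(np.arange(1.0, 4.0), size=n)
    state = SystemState(adj, alcohol, control, secrecy).validate()
    return state, gender, fsm


def generate_school(config: SynthConfig, school_index: int) -> tuple[SchoolPanel, GroundTruth]:
    """One school: wave-1 state, forward simulation, absence injection.

    Fully reproducible from (config.seed, school_index).
    """
    config.validate()
    ss = np.random.SeedSequence([int(config.seed), int(school_index)])
    rng = np.random.default_rng(ss)
    sim_seed = int(rng.integers(2**31))
    school_type = config.school_type(school_index)
    school_id = f"s{school_index:02d}_{school_type}"
    n = int(rng.integers(config.size_range[0], config.size_range[1] + 1))

    state, gender, fsm = _wave1_state(config, n, school_type, rng)
    spec = _school_spec(config, school_type)
    wave1_weekly = float(np.mean(state.alcohol == 4.0))
    prev_centered = wave1_weekly - config.wave1_alcohol_probs[-1]
    theta = true_theta(config, spec, school_type, prev_centered)
    rates_arr = spec.pack(theta)[4]
    rates = [RateSet(*row) for row in rates_arr]

    panel = simulate_panel(state, theta, rates, spec, gender, fsm, sim_seed,
                           school_id=school_id, school_type=school_type)
    year3 = min(3, config.waves) - 1
    panel.year3_weekly_prevalence = float(np.mean(panel.waves[year3].alcohol == 4.0))
    panel = inject_missingness(panel, config.absence_prob, rng)

    truth = GroundTruth(
        school_id=school_id, school_type=school_type, n_actors=n,
        theta=theta, rates=rates_arr, seed=sim_seed,
        moderator_row={"school_type": school_type,
                       "wave1_weekly": wave1_weekly},
    )
    return panel, truth


def inject_missingness(panel: SchoolPanel, absence_prob: float,
                       rng: np.random.Generator) -> SchoolPanel:
    """Mark random actor-waves absent: missing out-row and behaviours.

    Wave-1 absence is capped so at least 80% of actors stay observed at
    baseline.  Observed entries are never altered.
    """
    if not 0.0 <= absence_prob <= 0.5:
        raise ValueError("absence_prob must be in [0, 0.5]")
    out = panel.copy()
    n = out.n_actors
    for m, wave in enumerate(out.waves):
        absent = rng.random(n) < absence_prob
        if m == 0:
            cap = int(np.floor(0.2 * n))
            if absent.sum() > cap:
                drawn = np.flatnonzero(absent)
                keep = rng.choice(drawn, size=cap, replace=False)
                absent = np.zeros(n, dtype=bool)
                absent[keep] = True
        idx = np.flatnonzero(absent)
        wave.present[idx] = False
        wave.adjacency[idx, :] = -1
        wave.alcohol[idx] = np.nan
        wave.control[idx] = np.nan
        wave.secrecy[idx] = np.nan
    return out.validate()


def generate_study(config: SynthConfig) -> tuple[list[SchoolPanel], list[GroundTruth], pd.DataFrame]:
    """All schools of one synthetic study plus the school metadata table."""
    panels, truths = [], []
    for k in range(config.n_schools):
        panel, truth = generate_school(config, k)
        panels.append(panel)
        truths.append(truth)
    metadata = pd.DataFrame([
        {"school_id": p.school_id, "school_type": p.school_type,
         "year3_weekly_prevalence": p.year3_weekly_prevalence}
        for p in panels
    ])
    return panels, truths, metadata


def write_study(panels: list[SchoolPanel], truths: list[GroundTruth],
                metadata: pd.DataFrame, out_dir: str | Path) -> None:
    """Emit the CSV dialects of :mod:`netcoevolve.panels` plus ground_truth.json."""
    from .panels import save_panel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for panel in panels:
        save_panel(panel, out / panel.school_id)
    metadata.to_csv(out / "school_metadata.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1)
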