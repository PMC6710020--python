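"""Longitudinal school network-behaviour panels: containers, I/O, recoding, filtering.

A panel holds one school's friendship nominations (a directed adjacency
matrix per annual wave, at most 10 nominations per pupil) together with
per-wave ordinal behaviours — drinking frequency on a 1-4 scale, parental
control and child secrecy as tertile scores 1-3 — and the wave-constant
covariates gender and free-school-meal (FSM) eligibility.

Conventions
-----------
* Adjacency matrices are ``int8`` with entries ``0`` (no tie), ``1`` (tie)
  and ``-1`` (missing).  A pupil absent at a wave has their whole out-row
  missing; for a present pupil every unlisted alter is an observed zero,
  because the nomination instrument is a roster ("name your best friend and
  up to nine other friends").
* Behaviours are ``float64`` with ``nan`` for missing.
* Actors are indexed 0..n-1 internally; string identifiers are preserved
  for I/O.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MAX_NOMINATIONS = 10

ALCOHOL_RANGE = (1, 4)
TERTILE_RANGE = (1, 3)

_FREQ_LEVELS = ("none", "infrequent", "monthly", "weekly_plus")
SCHOOL_TYPES = ("coed", "girls", "boys")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel data."""


@dataclass
class WaveObservation:
    """One wave of one school: adjacency plus per-actor behaviours."""

    adjacency: np.ndarray          # (n, n) int8 in {0, 1, -1}
    present: np.ndarray            # (n,) bool
    alcohol: np.ndarray            # (n,) float64 in {1..4} or nan
    control: np.ndarray            # (n,) float64 in {1..3} or nan
    secrecy: np.ndarray            # (n,) float64 in {1..3} or nan

    def validate(self, n: int) -> None:
        adj = self.adjacency
        if adj.shape != (n, n):
            raise PanelError(f"adjacency shape {adj.shape} != ({n}, {n})")
        diag = np.diag(adj)
        if np.any((diag != 0) & (diag != -1)):   # -1: whole row missing
            raise PanelError("self-nominations on the adjacency diagonal")
        if not np.isin(adj, (-1, 0, 1)).all():
            raise PanelError("adjacency entries must be in {-1, 0, 1}")
        outdeg = (adj == 1).sum(axis=1)
        if np.any(outdeg > MAX_NOMINATIONS):
            bad = int(np.argmax(outdeg))
            raise PanelError(
                f"actor index {bad} has {int(outdeg[bad])} nominations "
                f"(limit {MAX_NOMINATIONS})"
            )
        for name, arr, (lo, hi) in (
            ("alcohol", self.alcohol, ALCOHOL_RANGE),
            ("control", self.control, TERTILE_RANGE),
            ("secrecy", self.secrecy, TERTILE_RANGE),
        ):
            vals = arr[~np.isnan(arr)]
            if vals.size and (vals.min() < lo or vals.max() > hi or np.any(vals != np.round(vals))):
                raise PanelError(f"{name} values outside integer range [{lo}, {hi}]")


@dataclass
class SchoolPanel:
    """All waves of one school, with constant covariates and metadata."""

    school_id: str
    school_type: str                     # coed | girls | boys
    actor_ids: list[str]
    waves: list[WaveObservation]
    gender: np.ndarray                   # (n,) 0/1, 1 = female
    fsm: np.ndarray                      # (n,) 0/1
    year3_weekly_prevalence: float = float("nan")

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    def validate(self) -> "SchoolPanel":
        n = self.n_actors
        if self.school_type not in SCHOOL_TYPES:
            raise PanelError(f"unknown school_type {self.school_type!r}")
        if self.n_waves < 2:
            raise PanelError("a panel needs at least two waves")
        if self.gender.shape != (n,) or self.fsm.shape != (n,):
            raise PanelError("gender/fsm must have one entry per actor")
        if self.school_type == "girls" and not np.all(self.gender == 1):
            raise PanelError("girls school with non-female actors")
        if self.school_type == "boys" and not np.all(self.gender == 0):
            raise PanelError("boys school with female actors")
        p = self.year3_weekly_prevalence
        if not np.isnan(p) and not 0.0 <= p <= 1.0:
            raise PanelError("year3_weekly_prevalence outside [0, 1]")
        for w in self.waves:
            w.validate(n)
        return self

    def missing_nomination_fraction(self) -> float:
        """Fraction of actor-waves whose entire out-row is missing."""
        total = self.n_actors * self.n_waves
        missing = sum(int(np.all(w.adjacency == -1, axis=1).sum()) for w in self.waves)
        return missing / total

    def copy(self) -> "SchoolPanel":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Recoding
# ---------------------------------------------------------------------------

def recode_alcohol(ever_used: int | bool, frequency_item: str) -> int:
    """Combine the ever-used screen with the frequency item into a 1-4 score.

    never -> 1, infrequent -> 2, monthly -> 3, weekly or more -> 4.
    """
    if frequency_item not in _FREQ_LEVELS:
        raise PanelError(f"unknown frequency item {frequency_item!r}")
    ever = bool(ever_used)
    if not ever:
        if frequency_item != "none":
            raise PanelError(
                "inconsistent report: never used alcohol but frequency "
                f"{frequency_item!r}"
            )
        return 1
    return {"none": 1, "infrequent": 2, "monthly": 3, "weekly_plus": 4}[frequency_item]


def tertile_split(scores: np.ndarray) -> np.ndarray:
    """Map raw scale scores to tertile ranks 1/2/3 within one school-wave.

    Cut points are the empirical 1/3 and 2/3 quantiles of the non-missing
    scores; values exactly at a boundary go to the lower tertile.  An
    all-constant vector maps everyone to the middle tertile.  Missing
    values (nan) are preserved.
    """
    scores = np.asarray(scores, dtype=float)
    obs = ~np.isnan(scores)
    vals = scores[obs]
    if vals.size == 0:
        raise PanelError("tertile_split: all values missing")
    if vals.size < 3:
        raise PanelError("tertile_split: need at least 3 non-missing values")
    out = np.full(scores.shape, np.nan)
    if np.all(vals == vals[0]):
        out[obs] = 2.0
        return out
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    ranks = np.ones(vals.shape)
    ranks[vals > q1] = 2.0
    ranks[vals > q2] = 3.0
    out[obs] = ranks
    return out


def filter_schools(panels: Iterable[SchoolPanel], threshold: float = 0.20) -> list[SchoolPanel]:
    """Keep schools whose missing-nomination fraction is strictly below threshold."""
    if not 0.0 < threshold <= 1.0:
        raise PanelError("threshold must be in (0, 1]")
    return [p for p in panels if p.missing_nomination_fraction() < threshold]


# ---------------------------------------------------------------------------
# CSV I/O
#
# Edge list CSV (one file per wave): school_id, wave, ego_id, alter_id.
# Attribute CSV (one row per actor-wave): school_id, wave, actor_id, present,
#   gender, fsm, ever_alcohol, alcohol_freq, control_score, secrecy_score.
# Metadata CSV: school_id, school_type, year3_weekly_prevalence.
# ---------------------------------------------------------------------------

def load_panel(
    network_files: Sequence[str | Path],
    attribute_file: str | Path,
    metadata: dict | pd.Series,
) -> SchoolPanel:
    """Assemble and validate a SchoolPanel from per-wave edge lists and attributes.

    ``metadata`` must provide ``school_id``, ``school_type`` and optionally
    ``year3_weekly_prevalence``.  Raw control/secrecy scale scores are
    tertiled per wave; the alcohol items are recoded to the 1-4 frequency
    scale.  A pupil marked absent gets a missing out-row and missing
    behaviours at that wave.
    """
    attrs = pd.read_csv(attribute_file, dtype={"actor_id": str, "school_id": str})
    required = {
        "school_id", "wave", "actor_id", "present", "gender", "fsm",
        "ever_alcohol", "alcohol_freq", "control_score", "secrecy_score",
    }
    missing_cols = required - set(attrs.columns)
    if missing_cols:
        raise PanelError(f"attribute file missing columns: {sorted(missing_cols)}")

    school_id = str(metadata["school_id"])
    school_type = str(metadata["school_type"])
    attrs = attrs[attrs["school_id"].astype(str) == school_id]
    if attrs.empty:
        raise PanelError(f"no attribute rows for school {school_id!r}")

    actor_ids = sorted(attrs["actor_id"].unique())
    index = {a: k for k, a in enumerate(actor_ids)}
    n = len(actor_ids)
    n_waves = len(network_files)

    # wave-constant covariates: first non-missing observation
    gender = np.zeros(n)
    fsm = np.zeros(n)
    for aid, grp in attrs.sort_values("wave").groupby("actor_id"):
        k = index[aid]
        g = grp["gender"].dropna()
        f = grp["fsm"].dropna()
        gender[k] = float(g.iloc[0]) if len(g) else 0.0
        fsm[k] = float(f.iloc[0]) if len(f) else 0.0

    waves: list[WaveObservation] = []
    for w in range(1, n_waves + 1):
        adj = np.zeros((n, n), dtype=np.int8)
        present = np.zeros(n, dtype=bool)
        alcohol = np.full(n, np.nan)
        control_raw = np.full(n, np.nan)
        secrecy_raw = np.full(n, np.nan)

        rows = attrs[attrs["wave"] == w]
        for _, row in rows.iterrows():
            k = index[str(row["actor_id"])]
            is_present = bool(row["present"]) if not pd.isna(row["present"]) else False
            present[k] = is_present
            if not is_present:
                adj[k, :] = -1
                continue
            if not pd.isna(row["ever_alcohol"]):
                freq = row["alcohol_freq"]
                freq = "none" if pd.isna(freq) else str(freq)
                alcohol[k] = recode_alcohol(int(row["ever_alcohol"]), freq)
            if not pd.isna(row["control_score"]):
                control_raw[k] = float(row["control_score"])
            if not pd.isna(row["secrecy_score"]):
                secrecy_raw[k] = float(row["secrecy_score"])
        # actors with no attribute row at this wave: treat as absent
        seen = {index[str(a)] for a in rows["actor_id"]}
        for k in range(n):
            if k not in seen:
                present[k] = False
                adj[k, :] = -1

        edges = pd.read_csv(network_files[w - 1], dtype={"ego_id": str, "alter_id": str})
        for line_no, row in enumerate(edges.itertuples(index=False), start=2):
            ego, alter = str(row.ego_id), str(row.alter_id)
            if ego not in index:
                raise PanelError(
                    f"{network_files[w - 1]}:{line_no}: unknown ego {ego!r}")
            if alter not in index:
                raise PanelError(
                    f"{network_files[w - 1]}:{line_no}: unknown alter {alter!r}")
            if ego == alter:
                raise PanelError(
                    f"{network_files[w - 1]}:{line_no}: self-nomination {ego!r}")
            i, j = index[ego], index[alter]
            if adj[i, j] == 1:
                continue
            if (adj[i] == 1).sum() >= MAX_NOMINATIONS:
                raise PanelError(
                    f"{network_files[w - 1]}:{line_no}: actor {ego!r} exceeds "
                    f"{MAX_NOMINATIONS} nominations")
            adj[i, j] = 1
            present_row = present[i]
            if not present_row:
                raise PanelError(
                    f"{network_files[w - 1]}:{line_no}: nomination by actor "
                    f"{ego!r} marked absent at wave {w}")

        control = _tertile_or_nan(control_raw)
        secrecy = _tertile_or_nan(secrecy_raw)
        waves.append(WaveObservation(adj, present, alcohol, control, secrecy))

    prevalence = float(metadata.get("year3_weekly_prevalence", float("nan")))
    panel = SchoolPanel(
        school_id=school_id,
        school_type=school_type,
        actor_ids=list(actor_ids),
        waves=waves,
        gender=gender,
        fsm=fsm,
        year3_weekly_prevalence=prevalence,
    )
    return panel.validate()


def _tertile_or_nan(raw: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(raw)
    if obs.sum() < 3:
        return np.full(raw.shape, np.nan)
    # already-tertiled input (integers 1..3) passes through unchanged
    vals = raw[obs]
    if np.all(np.isin(vals, (1.0, 2.0, 3.0))) and len(np.unique(vals)) > 1:
        return raw.copy()
    return tertile_split(raw)


def save_panel(panel: SchoolPanel, out_dir: str | Path) -> dict[str, list[Path] | Path]:
    """Write a panel back to the CSV dialect read by :func:`load_panel`.

    Behaviours are written as already-tertiled control/secrecy scores, so a
    save/load round trip is structurally the identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = panel.school_id
    net_paths = []
    for w, wave in enumerate(panel.waves, start=1):
        rows = []
        egos, alters = np.nonzero(wave.adjacency == 1)
        for i, j in zip(egos, alters):
            rows.append((sid, w, panel.actor_ids[i], panel.actor_ids[j]))
        df = pd.DataFrame(rows, columns=["school_id", "wave", "ego_id", "alter_id"])
        path = out / f"{sid}_wave{w}_edges.csv"
        df.to_csv(path, index=False)
        net_paths.append(path)

    rows = []
    for w, wave in enumerate(panel.waves, start=1):
        for k, aid in enumerate(panel.actor_ids):
            alc = wave.alcohol[k]
            rows.append({
                "school_id": sid,
                "wave": w,
                "actor_id": aid,
                "present": int(wave.present[k]),
                "gender": int(panel.gender[k]),
                "fsm": int(panel.fsm[k]),
                "ever_alcohol": "" if np.isnan(alc) else int(alc > 1),
                "alcohol_freq": "" if np.isnan(alc) else _FREQ_LEVELS[int(alc) - 1],
                "control_score": "" if np.isnan(wave.control[k]) else int(wave.control[k]),
                "secrecy_score": "" if np.isnan(wave.secrecy[k]) else int(wave.secrecy[k]),
            })
    attr_path = out / f"{sid}_attributes.csv"
    pd.DataFrame(rows).to_csv(attr_path, index=False)

    meta_path = out / f"{sid}_metadata.csv"
    pd.DataFrame([{
        "school_id": sid,
        "school_type": panel.school_type,
        "year3_weekly_prevalence": panel.year3_weekly_prevalence,
    }]).to_csv(meta_path, index=False)
    return {"networks": net_paths, "attributes": attr_path, "metadata": meta_path}


def load_metadata(metadata_file: str | Path) -> pd.DataFrame:
    df = pd.read_csv(metadata_file, dtype={"school_id": str})
    bad = set(df["school_type"]) - set(SCHOOL_TYPES)
    if bad:
        raise PanelError(f"unknown school types in metadata: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Imputation for model evaluation (documented approximation):
# last observation carried forward; wave-1 missing behaviour -> school-wave
# mode; wave-1 missing out-row -> zeros.  Imputed entries feed simulations
# but are excluded from rate targets via the joint-observation masks.
# ---------------------------------------------------------------------------

@dataclass
class ImputedPanel:
    """Dense arrays for simulation/estimation plus observation masks."""

    adjacency: list[np.ndarray]          # per wave (n, n) int8 in {0, 1}
    behaviors: list[np.ndarray]          # per wave (3, n) float64: alc, con, sec
    row_observed: list[np.ndarray]       # per wave (n,) bool: out-row observed
    beh_observed: list[np.ndarray]       # per wave (3, n) bool
    gender: np.ndarray
    fsm: np.ndarray

    @property
    def n_waves(self) -> int:
        return len(self.adjacency)


def impute_panel(panel: SchoolPanel) -> ImputedPanel:
    n = panel.n_actors
    adjacency, behaviors, row_obs, beh_obs = [], [], [], []
    for m, wave in enumerate(panel.waves):
        adj = wave.adjacency.copy()
        robs = ~np.all(adj == -1, axis=1)
        beh = np.vstack([wave.alcohol, wave.control, wave.secrecy])
        bobs = ~np.isnan(beh)
        if m == 0:
            adj[adj == -1] = 0
            for b in range(3):
                row = beh[b]
                if np.isnan(row).any():
                    obs = row[~np.isnan(row)]
                    if obs.size:
                        vals, counts = np.unique(obs, return_counts=True)
                        mode = vals[np.argmax(counts)]
                    else:
                        mode = 1.0 if b else 1.0
                    row[np.isnan(row)] = mode
        else:
            prev_adj, prev_beh = adjacency[m - 1], behaviors[m - 1]
            miss_rows = np.all(wave.adjacency == -1, axis=1)
            adj[miss_rows] = prev_adj[miss_rows]
            adj[adj == -1] = 0
            for b in range(3):
                row = beh[b]
                row[np.isnan(row)] = prev_beh[b][np.isnan(row)]
        adjacency.append(adj.astype(np.int8))
        behaviors.append(beh)
        row_obs.append(robs)
        beh_obs.append(bobs)
    return ImputedPanel(adjacency, behaviors, row_obs, beh_obs,
                        panel.gender.astype(float), panel.fsm.astype(float))
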