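"""Ego-alter selection tables.

A selection table turns the fitted ego, alter and similarity parameters of
one behaviour into a category-by-category matrix of tie log-odds relative
to a reference dyad in which both pupils sit at the school-mean level of
the behaviour:

    cell(e, a) = b_ego (v_e - vbar) + b_alt (v_a - vbar)
               + b_sim (sim(v_e, v_a) - sbar) - b_sim (sim(vbar, vbar) - sbar)

Cell variances follow by the delta method from the fitted parameter
covariance; per-school tables are pooled cellwise by random-effects
meta-analysis on the log scale and exponentiated into odds ratios.
Asymmetries such as "opportunity hoarding" appear as contrasts between
cell (e, a) and its transpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import BEH_RANGES, ModelSpec
from .estimate import FitResult
from .meta import pool_random_effects

_Z = 1.959963984540054

CATEGORY_LABELS = {
    "alcohol": ("never", "rarely", "monthly", "frequently"),
    "control": ("low", "moderate", "high"),
    "secrecy": ("secretive", "moderate", "disclosive"),
}
_EFFECT_TRIPLES = {
    "alcohol": ("alc_ego", "alc_alter", "alc_sim"),
    "control": ("con_ego", "con_alter", "con_sim"),
    "secrecy": ("sec_ego", "sec_alter", "sec_sim"),
}


class SelectionTableError(ValueError):
    pass


def default_categories(behavior: str) -> np.ndarray:
    hi = {"alcohol": 4, "control": 3, "secrecy": 3}[behavior]
    return np.arange(1, hi + 1, dtype=float)


def school_log_odds_table(
    fit: FitResult, spec: ModelSpec, behavior: str,
    categories: np.ndarray | None = None,
    school_mean: float | None = None,
    value_range: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-school K x K log-odds matrix and delta-method variances.

    The reference contrast at (vbar, vbar) makes the mean-mean cell exactly
    zero; the similarity coefficient in the contrast gradient is
    sim(e, a) - sim(vbar, vbar) = sim(e, a) - 1.
    """
    cats = default_categories(behavior) if categories is None else np.asarray(categories, float)
    vbar = spec.consts[("alcohol", "control", "secrecy").index(behavior)] \
        if school_mean is None else float(school_mean)
    rng = BEH_RANGES[behavior] if value_range is None else float(value_range)
    names = _EFFECT_TRIPLES[behavior]
    for nm in names:
        if spec[nm].fixed:
            raise SelectionTableError(
                f"effect {nm} is fixed in this school's model; no covariance available")
    free_pos = {name: k for k, name in enumerate(fit.free_names)}
    idx = [free_pos[nm] for nm in names]
    beta = np.array([fit.theta[spec[nm].index] for nm in names])
    cov = fit.covariance[np.ix_(idx, idx)]
    if not np.all(np.isfinite(cov)):
        raise SelectionTableError("missing covariance entries for ego/alter/similarity")
    K = cats.size
    L = np.zeros((K, K))
    V = np.zeros((K, K))
    for e in range(K):
        for a in range(K):
            sim = 1.0 - abs(cats[e] - cats[a]) / rng
            g = np.array([cats[e] - vbar, cats[a] - vbar, sim - 1.0])
            L[e, a] = float(g @ beta)
            V[e, a] = float(g @ cov @ g)
    return L, V


@dataclass
class SelectionTable:
    """Pooled K x K selection table for one behaviour and school stratum."""

    behavior: str
    categories: np.ndarray
    log_odds: np.ndarray
    variances: np.ndarray
    or_matrix: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    flagged: np.ndarray          # CI of the pooled log-odds excludes 0
    stratum: str = "all"
    n_schools: int = 1

    def to_frame(self) -> pd.DataFrame:
        labels = CATEGORY_LABELS.get(self.behavior,
                                     tuple(str(int(c)) for c in self.categories))
        rows = []
        K = self.categories.size
        for e in range(K):
            for a in range(K):
                rows.append({
                    "stratum": self.stratum, "behavior": self.behavior,
                    "ego_category": labels[e], "alter_category": labels[a],
                    "odds_ratio": self.or_matrix[e, a],
                    "ci_low": self.ci_low[e, a], "ci_high": self.ci_high[e, a],
                    "flagged": bool(self.flagged[e, a]),
                })
        return pd.DataFrame(rows)


def pool_selection_tables(
    tables: list[tuple[np.ndarray, np.ndarray]],
    behavior: str,
    categories: np.ndarray | None = None,
    stratum: str = "all",
) -> SelectionTable:
    """Cellwise random-effects pooling of per-school (log-odds, variance) pairs."""
    if not tables:
        raise SelectionTableError("no tables to pool")
    cats = default_categories(behavior) if categories is None else np.asarray(categories, float)
    K = cats.size
    for L, V in tables:
        if L.shape != (K, K) or V.shape != (K, K):
            raise SelectionTableError("mismatched category grids")
    L_pool = np.zeros((K, K))
    V_pool = np.zeros((K, K))
    lo = np.zeros((K, K))
    hi = np.zeros((K, K))
    for e in range(K):
        for a in range(K):
            ests = np.array([L[e, a] for L, _ in tables])
            ses = np.sqrt(np.array([max(V[e, a], 0.0) for _, V in tables]))
            if np.all(ses == 0):
                # reference-type cell: identical zero variance in every school
                L_pool[e, a] = float(ests.mean())
                V_pool[e, a] = 0.0
                lo[e, a] = hi[e, a] = L_pool[e, a]
                continue
            ses = np.maximum(ses, 1e-12)
            pe = pool_random_effects(ests, ses)
            L_pool[e, a] = pe.estimate
            V_pool[e, a] = pe.se**2
            lo[e, a], hi[e, a] = pe.ci_low, pe.ci_high
    flagged = (lo > 0) | (hi < 0)
    return SelectionTable(
        behavior=behavior, categories=cats, log_odds=L_pool, variances=V_pool,
        or_matrix=np.exp(L_pool), ci_low=np.exp(lo), ci_high=np.exp(hi),
        flagged=flagged, stratum=stratum, n_schools=len(tables))


def asymmetry_contrast(table: SelectionTable, e: int, a: int) -> tuple[float, float, tuple[float, float]]:
    """Pooled log-odds(e, a) - log-odds(a, e) with an independence-approximate CI.

    Cells are pooled marginally, so their covariance is unavailable and the
    variance treats them as independent; the per-school exact contrast
    (:func:`school_asymmetry_contrast`) is the preferred inferential path.
    """
    if e == a:
        raise SelectionTableError("asymmetry contrast needs two distinct categories")
    est = float(table.log_odds[e, a] - table.log_odds[a, e])
    se = float(np.sqrt(table.variances[e, a] + table.variances[a, e]))
    return est, se, (est - _Z * se, est + _Z * se)


def school_asymmetry_contrast(fit: FitResult, spec: ModelSpec, behavior: str,
                              e_val: float, a_val: float,
                              school_mean: float | None = None) -> tuple[float, float]:
    """Exact per-school contrast cell(e,a) - cell(a,e) using the full covariance.

    The similarity terms cancel, leaving (b_ego - b_alt)(v_e - v_a).
    """
    names = _EFFECT_TRIPLES[behavior]
    free_pos = {name: k for k, name in enumerate(fit.free_names)}
    idx = [free_pos[nm] for nm in names[:2]]
    b_ego = fit.theta[spec[names[0]].index]
    b_alt = fit.theta[spec[names[1]].index]
    dv = float(e_val - a_val)
    est = (b_ego - b_alt) * dv
    g = np.array([dv, -dv])
    cov = fit.covariance[np.ix_(idx, idx)]
    return float(est), float(np.sqrt(g @ cov @ g))


def tables_from_fits(fits: list[FitResult], specs: list[ModelSpec],
                     behavior: str, school_types: list[str] | None = None,
                     strata: tuple[str, ...] = ("all",)) -> dict[str, SelectionTable]:
    """Build pooled tables for the requested strata from per-school fits."""
    per_school = []
    for fit, spec in zip(fits, specs):
        try:
            per_school.append(school_log_odds_table(fit, spec, behavior))
        except SelectionTableError:
            per_school.append(None)
    out = {}
    for stratum in strata:
        pairs = [t for t, st in zip(per_school, school_types or ["all"] * len(per_school))
                 if t is not None and (stratum == "all" or st == stratum)]
        if pairs:
            out[stratum] = pool_selection_tables(pairs, behavior, stratum=stratum)
    return out
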