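"""Random-effects pooling and meta-regression across schools.

Per-school SAOM parameters theta_s with standard errors se_s are combined
under the additive heterogeneity model

    theta_s ~ N(x_s' beta, se_s^2 + tau^2),

with the between-school variance tau^2 estimated by the Paule-Mandel
(empirical Bayes) criterion: tau^2 is chosen so the weighted residual sum
of squares equals its degrees of freedom.  Moderators follow the study
design: school gender status (coeducational reference, boys, girls
dummies) and the school's Year-3 weekly-drinking prevalence centered on
the sample mean, so the intercept is the expected parameter for a
coeducational school at mean prevalence.  Inference is Wald/normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODERATOR_NAMES = ("intercept", "boys", "girls", "prevalence_c")


class MetaError(ValueError):
    pass


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    resid = y - X @ beta
    return beta, resid


def estimate_tau2(estimates: np.ndarray, ses: np.ndarray,
                  design: np.ndarray | None = None,
                  tol: float = 1e-8, max_iter: int = 200) -> float:
    """Paule-Mandel between-school variance under an optional design matrix.

    Solves  sum_s w_s r_s^2 = S - rank(X)  with  w_s = 1/(se_s^2 + tau^2)
    and residuals r_s from the weighted fit; returns 0 when even tau^2 = 0
    leaves the weighted residuals below their degrees of freedom.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    if y.size < 2:
        raise MetaError("need at least two schools")
    if np.any(v <= 0):
        raise MetaError("standard errors must be positive")
    X = np.ones((y.size, 1)) if design is None else np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise MetaError("design matrix is rank deficient")
    df = y.size - rank

    def excess(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        _, resid = _wls(y, X, w)
        return float(w @ resid**2) - df

    if df <= 0:
        return 0.0
    if excess(0.0) <= 0.0:
        return 0.0
    hi = max(1.0, 10.0 * float(v.max()))
    it = 0
    while excess(hi) > 0.0:
        hi *= 4.0
        it += 1
        if it > max_iter:
            raise MetaError(f"Paule-Mandel iteration failed to bracket; last tau2 = {hi}")
    return float(optimize.brentq(excess, 0.0, hi, xtol=tol, maxiter=max_iter))


@dataclass
class PooledEffect:
    """Random-effects summary of one parameter across schools."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    n_schools: int
    pooled: bool = True          # False when only a single school was available


def _wald(est: float, se: float) -> tuple[float, float, float]:
    ci = 1.959963984540054 * se
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else (1.0 if est == 0 else 0.0)
    return est - ci, est + ci, float(p)


def pool_random_effects(estimates: np.ndarray, ses: np.ndarray,
                        tau2: float | None = None) -> PooledEffect:
    """Inverse-variance pooling with Paule-Mandel heterogeneity."""
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if y.size == 1:
        lo, hi, p = _wald(float(y[0]), float(s[0]))
        return PooledEffect(float(y[0]), float(s[0]), lo, hi, p, 0.0, 1, pooled=False)
    t2 = estimate_tau2(y, s) if tau2 is None else float(tau2)
    w = 1.0 / (s**2 + t2)
    mu = float(w @ y / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    lo, hi, p = _wald(mu, se)
    return PooledEffect(mu, se, lo, hi, p, t2, int(y.size))


def encode_moderators(metadata: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """School-context design matrix: intercept, boys, girls, centered prevalence."""
    types = metadata["school_type"].astype(str).to_numpy()
    unknown = set(types) - {"coed", "girls", "boys"}
    if unknown:
        raise MetaError(f"unknown school types: {sorted(unknown)}")
    prev = metadata["year3_weekly_prevalence"].astype(float).to_numpy()
    if np.any((prev < 0) | (prev > 1)):
        raise MetaError("prevalence outside [0, 1]")
    X = np.column_stack([
        np.ones(len(types)),
        (types == "boys").astype(float),
        (types == "girls").astype(float),
        prev - prev.mean(),
    ])
    return X, list(MODERATOR_NAMES)


@dataclass
class MetaRegression:
    """Weighted least-squares meta-regression block for one parameter."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    tau2: float
    n_schools: int


def meta_regression(estimates: np.ndarray, ses: np.ndarray,
                    design: np.ndarray, names: list[str] | None = None) -> MetaRegression:
    """Random-effects meta-regression with PM tau^2 under the same design."""
    y = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    X = np.asarray(design, dtype=float)
    names = names or [f"x{k}" for k in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the caller
        bad = []
        for k in range(X.shape[1]):
            others = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[k])
        raise MetaError(f"collinear moderator columns: {bad}")
    if y.size <= rank:
        raise MetaError("need more schools than moderator columns")
    t2 = estimate_tau2(y, s, design=X)
    w = 1.0 / (s**2 + t2)
    beta, _ = _wls(y, X, w)
    cov = np.linalg.inv((X.T * w) @ X)
    se_b = np.sqrt(np.diag(cov))
    lo = np.empty_like(beta)
    hi = np.empty_like(beta)
    p = np.empty_like(beta)
    for k in range(beta.size):
        lo[k], hi[k], p[k] = _wald(float(beta[k]), float(se_b[k]))
    return MetaRegression(list(names), beta, se_b, lo, hi, p, t2, int(y.size))


@dataclass
class MetaResult:
    """Pooled summary plus meta-regression for a set of effects."""

    effects: list[str]
    pooled: dict[str, PooledEffect]
    regressions: dict[str, MetaRegression]
    n_schools: int
    excluded_schools: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Wide table mirroring a per-effect pooled + moderator layout."""
        rows = []
        for name in self.effects:
            pe = self.pooled[name]
            row = {
                "effect": name, "pooled": pe.estimate, "pooled_se": pe.se,
                "pooled_ci_low": pe.ci_low, "pooled_ci_high": pe.ci_high,
                "pooled_p": pe.p, "tau2": pe.tau2, "n_schools": pe.n_schools,
            }
            reg = self.regressions.get(name)
            if reg is not None:
                for k, mod in enumerate(reg.names):
                    row[f"{mod}"] = reg.coef[k]
                    row[f"{mod}_ci_low"] = reg.ci_low[k]
                    row[f"{mod}_ci_high"] = reg.ci_high[k]
                    row[f"{mod}_p"] = reg.p[k]
            rows.append(row)
        return pd.DataFrame(rows)


def meta_analyse_fits(fits: list, specs: list, metadata: pd.DataFrame,
                      effect_names: list[str],
                      require_converged: bool = True) -> MetaResult:
    """Pool named effects across schools and run per-effect meta-regressions.

    Schools whose fit did not converge are excluded (with their ids
    recorded); effects fixed in a school's spec are skipped for that school.
    """
    keep, excluded = [], []
    for fit, spec in zip(fits, specs):
        if require_converged and not fit.converged:
            excluded.append(fit.school_id)
        else:
            keep.append((fit, spec))
    if not keep:
        raise MetaError("no converged schools to pool")
    meta_idx = metadata.set_index(metadata["school_id"].astype(str))
    pooled, regressions = {}, {}
    for name in effect_names:
        ests, ses, rows = [], [], []
        for fit, spec in keep:
            if spec[name].fixed:
                continue
            est, se = fit.get(name, spec)
            if not np.isfinite(se) or se <= 0:
                continue
            ests.append(est)
            ses.append(se)
            rows.append(meta_idx.loc[str(fit.school_id)])
        if not ests:
            continue
        ests = np.asarray(ests)
        ses = np.asarray(ses)
        pooled[name] = pool_random_effects(ests, ses)
        sub = pd.DataFrame(rows)
        try:
            X, mod_names = encode_moderators(sub)
            # drop zero-variance dummies (e.g. single-type strata)
            keep_cols = [0] + [k for k in range(1, X.shape[1]) if np.ptp(X[:, k]) > 0]
            regressions[name] = meta_regression(
                ests, ses, X[:, keep_cols], [mod_names[k] for k in keep_cols])
        except MetaError:
            pass
    return MetaResult(list(pooled), pooled, regressions,
                      n_schools=len(keep), excluded_schools=excluded)
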