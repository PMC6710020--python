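"""Unconditional method-of-moments estimation via Robbins-Monro approximation.

Parameters (evaluation effects plus per-period rates) are chosen so that
the expected simulated target statistics equal their observed values.  The
scheme follows the classic three phases:

phase 1
    estimate the derivative matrix of expected statistics with respect to
    the parameters by common-random-number forward finite differences;
phase 2
    stochastic-approximation updates ``theta <- theta - a D^-1 (S - s)``:
    a damped-Newton travel stage with the derivative refreshed along the
    way, followed by a long Polyak-averaged polishing stage at a fixed
    derivative;
phase 3
    independent simulations at the final estimate give the statistic
    covariance, convergence t-ratios (threshold .1 per parameter), the
    overall convergence ratio (threshold .25) and the parameter covariance
    ``D^-1 Sigma D^-T``.

Estimation is *unconditional*: rate parameters are free and matched to the
observed amount-of-change targets rather than conditioned on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import kernels
from .effects import (ModelSpec, N_EVAL, change_amounts, period_eval_stats,
                      period_masks)
from .panels import ImputedPanel, SchoolPanel, impute_panel
from .simulate import dyad_class_tables


class EstimationError(RuntimeError):
    pass


@dataclass
class EstimationOptions:
    """Control settings; defaults are sized for desk-scale schools."""

    n1: int = 12                     # finite-difference replications per column
    delta: float = 0.3               # FD step for evaluation effects
    rate_delta: float = 0.25         # relative FD step for rates
    newton_iters: int = 14           # travel updates
    refresh_every: int = 2           # derivative refresh interval during travel
    n_dev: int = 25                  # simulations averaged per travel update
    newton_gain: float = 0.8
    final_iters: int = 30            # Polyak-averaged polishing updates
    final_gain: float = 0.15
    n_avg: int = 4                   # simulations averaged per polishing update
    max_step: float = 1.0            # cap on the largest update component
    n3: int = 500                    # phase-3 replications
    use_best_guard: bool = True      # fall back to the best travel iterate
    max_restarts: int = 3
    min_rate: float = 0.05
    max_abs_param: float = 8.0
    max_rate: float = 20.0


@dataclass
class FitResult:
    """Per-school estimate: parameters, uncertainty and convergence diagnostics."""

    theta: np.ndarray                # full parameter vector (fixed slots included)
    se: np.ndarray                   # full-length; NaN for fixed effects
    covariance: np.ndarray           # free x free
    rates: np.ndarray                # (n_periods, 4)
    t_ratios: np.ndarray             # free-length
    overall_ratio: float
    converged: bool
    n_phase3: int
    seed: int
    free_names: list[str]
    free_indices: np.ndarray
    school_id: str = ""

    def get(self, name: str, spec: ModelSpec) -> tuple[float, float]:
        """(estimate, se) of one effect by name; fixed effects have se NaN."""
        e = spec[name]
        return float(self.theta[e.index]), float(self.se[e.index])

    def free_theta(self) -> np.ndarray:
        return self.theta[self.free_indices]

    def to_json(self, path=None) -> str:
        d = {
            "theta": self.theta.tolist(), "se": self.se.tolist(),
            "covariance": self.covariance.tolist(), "rates": self.rates.tolist(),
            "t_ratios": self.t_ratios.tolist(),
            "overall_ratio": self.overall_ratio, "converged": bool(self.converged),
            "n_phase3": self.n_phase3, "seed": self.seed,
            "free_names": self.free_names,
            "free_indices": self.free_indices.tolist(),
            "school_id": self.school_id,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source: str) -> "FitResult":
        d = json.loads(source)
        return cls(
            theta=np.asarray(d["theta"]), se=np.asarray(d["se"]),
            covariance=np.asarray(d["covariance"]), rates=np.asarray(d["rates"]),
            t_ratios=np.asarray(d["t_ratios"]),
            overall_ratio=float(d["overall_ratio"]), converged=bool(d["converged"]),
            n_phase3=int(d["n_phase3"]), seed=int(d["seed"]),
            free_names=list(d["free_names"]),
            free_indices=np.asarray(d["free_indices"], dtype=int),
            school_id=d.get("school_id", ""),
        )


# ---------------------------------------------------------------------------
# Simulation of targets
# ---------------------------------------------------------------------------

class TargetSimulator:
    """Simulates the method-of-moments statistic vector for one school.

    Each period starts from the (imputed) observed earlier wave, so periods
    are conditionally independent given the data.
    """

    def __init__(self, panel: SchoolPanel, spec: ModelSpec,
                 imp: ImputedPanel | None = None):
        self.spec = spec
        self.imp = imp if imp is not None else impute_panel(panel)
        if self.imp.n_waves != spec.n_periods + 1:
            raise EstimationError("spec/panel wave count mismatch")
        self.gender = np.ascontiguousarray(self.imp.gender)
        self.fsm = np.ascontiguousarray(self.imp.fsm)
        self.masks = [period_masks(self.imp, m) for m in range(spec.n_periods)]
        self.free = spec.free_indices

    def observed(self) -> np.ndarray:
        full_eval = np.zeros(N_EVAL)
        changes = []
        for m in range(self.spec.n_periods):
            full_eval += period_eval_stats(
                self.imp.adjacency[m], self.imp.behaviors[m],
                self.imp.adjacency[m + 1], self.imp.behaviors[m + 1],
                self.gender, self.fsm, self.spec.consts)
            row_mask, beh_mask = self.masks[m]
            changes.append(change_amounts(
                self.imp.adjacency[m], self.imp.adjacency[m + 1],
                self.imp.behaviors[m], self.imp.behaviors[m + 1],
                row_mask, beh_mask))
        return np.concatenate([full_eval] + changes)[self.free]

    def simulate(self, theta_full: np.ndarray, seed: int) -> np.ndarray:
        spec = self.spec
        theta_full = np.ascontiguousarray(theta_full)
        tn = theta_full[:16]
        ta, tc, ts = theta_full[16:23], theta_full[23:28], theta_full[28:34]
        rates = theta_full[34:].reshape(spec.n_periods, 4)
        edy, inv_edy = dyad_class_tables(tn, spec.consts)
        full_eval = np.zeros(N_EVAL)
        changes = []
        seed = int(seed)
        for m in range(spec.n_periods):
            adj = self.imp.adjacency[m].copy()
            beh = self.imp.behaviors[m].copy()
            alc, con, sec = beh
            # cheap decorrelated per-period seeds (Knuth multiplicative)
            period_seed = (seed * 2654435761 + 97 * m + 13) & 0x7FFFFFFF
            kernels.simulate_period_inplace(
                adj, alc, con, sec, self.gender, self.fsm,
                tn, ta, tc, ts, rates[m], spec.consts,
                1.0, period_seed, edy, inv_edy)
            full_eval += period_eval_stats(
                self.imp.adjacency[m], self.imp.behaviors[m],
                adj, beh, self.gender, self.fsm, spec.consts)
            row_mask, beh_mask = self.masks[m]
            changes.append(change_amounts(self.imp.adjacency[m], adj,
                                          self.imp.behaviors[m], beh,
                                          row_mask, beh_mask))
        return np.concatenate([full_eval] + changes)[self.free]


# ---------------------------------------------------------------------------
# Phases
# ---------------------------------------------------------------------------

_WIDE_DELTA_EFFECTS = ("sec_avsim", "sec_alt_avg_alc", "con_ego_x_alc_sim",
                       "alc_con_x_totsim", "alc_sec_x_totsim")


def _fd_deltas(theta_full: np.ndarray, free: np.ndarray, names: Sequence[str],
               options: EstimationOptions) -> np.ndarray:
    """Per-effect finite-difference steps.

    Weakly identified effects (averaged similarities, interactions) get a
    wider probe so their derivative columns rise above simulation noise;
    rates use a relative step.
    """
    deltas = np.full(free.shape, options.delta)
    for k, idx in enumerate(free):
        if idx >= N_EVAL:  # rate parameter: relative step
            deltas[k] = max(0.05, options.rate_delta * abs(theta_full[idx]))
        elif names[k] in _WIDE_DELTA_EFFECTS:
            deltas[k] = 3.0 * options.delta
        elif names[k].endswith("quad"):
            deltas[k] = 2.0 * options.delta
    return deltas


def _derivative(sim: TargetSimulator, theta_full: np.ndarray,
                options: EstimationOptions, seed: int,
                return_sd: bool = False):
    """Forward finite differences with common random numbers across the pair."""
    free = sim.free
    p = len(free)
    seeds = np.random.SeedSequence(int(seed)).generate_state(options.n1) >> 1
    base_runs = np.array([sim.simulate(theta_full, int(s)) for s in seeds])
    base = base_runs.mean(axis=0)
    deltas = _fd_deltas(theta_full, free, sim.spec.free_names, options)
    D = np.empty((p, p))
    for col, idx in enumerate(free):
        th = theta_full.copy()
        th[idx] += deltas[col]
        pert = np.mean([sim.simulate(th, int(s)) for s in seeds], axis=0)
        D[:, col] = (pert - base) / deltas[col]
    if return_sd:
        sd = base_runs.std(axis=0, ddof=1)
        return D, np.where(sd > 0, sd, 1.0)
    return D


def derivative_matrix(theta: np.ndarray, spec: ModelSpec, panel: SchoolPanel,
                      n1: int = 20, delta: float = 0.2,
                      seed: int = 0) -> np.ndarray:
    """Public finite-difference derivative of expected targets at ``theta``."""
    if delta <= 0:
        raise EstimationError("delta must be positive")
    if n1 < 2:
        raise EstimationError("n1 too small")
    sim = TargetSimulator(panel, spec)
    options = EstimationOptions(n1=n1, delta=delta)
    return _derivative(sim, np.asarray(theta, dtype=float), options, seed)


def _solve_factor(D: np.ndarray, free_names: Sequence[str], rcond: float = 1e-6):
    """Truncated-SVD solver for Robbins-Monro steps.

    Directions whose derivative signal is below ``rcond`` of the leading
    singular value are left un-updated (their finite-difference columns are
    noise); exactly flat or duplicated columns indicate a structurally
    collinear effect set and raise.
    """
    norms = np.linalg.norm(D, axis=0)
    if norms.max() <= 0:
        raise EstimationError("derivative matrix is zero")
    flat = np.flatnonzero(norms < 1e-12 * norms.max())
    if flat.size:
        # a column can come out flat when common random numbers leave every
        # paired path unchanged; that direction simply is not updated
        warnings.warn("flat derivative columns for: "
                      + ", ".join(free_names[k] for k in flat))
        D = D.copy()
        D[:, flat] = 0.0
        norms = np.where(norms > 0, norms, 1.0)
    G = D / norms
    C = np.abs(G.T @ G)
    np.fill_diagonal(C, 0.0)
    k, l = np.unravel_index(np.argmax(C), C.shape)
    if C[k, l] > 1.0 - 1e-10 and min(norms[k], norms[l]) > 0.2 * norms.max():
        # structurally duplicated statistics (weak columns that merely
        # coincide under common random numbers are handled by the
        # truncated inverse instead)
        raise EstimationError(
            "derivative matrix singular; collinear effects: "
            f"{free_names[k]}, {free_names[l]}")
    u, s, vt = np.linalg.svd(D)
    sinv = np.where(s > rcond * s[0], 1.0 / np.where(s > 0, s, 1.0), 0.0)
    return lambda dev: vt.T @ (sinv * (u.T @ dev))


def convergence_diagnostics(simulated_stats: np.ndarray,
                            observed: np.ndarray) -> tuple[np.ndarray, float]:
    """t-ratios and overall convergence ratio of simulated vs observed targets."""
    S = np.asarray(simulated_stats, dtype=float)
    obs = np.asarray(observed, dtype=float)
    N, p = S.shape
    if N < p + 2:
        raise EstimationError("need at least p + 2 phase-3 simulations")
    dev = S.mean(axis=0) - obs
    sd = S.std(axis=0, ddof=1)
    t = np.empty(p)
    for k in range(p):
        if sd[k] == 0.0:
            t[k] = 0.0 if dev[k] == 0.0 else np.inf
        else:
            t[k] = dev[k] / sd[k]
    cov = np.cov(S, rowvar=False)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < p:
        warnings.warn("rank-deficient statistic covariance; using pseudo-inverse")
    overall = float(np.sqrt(max(0.0, dev @ np.linalg.pinv(cov) @ dev)))
    return t, overall


def _clip_theta(theta_full: np.ndarray, free: np.ndarray,
                options: EstimationOptions) -> None:
    for idx in free:
        if idx >= N_EVAL:
            theta_full[idx] = min(max(theta_full[idx], options.min_rate),
                                  options.max_rate)
        else:
            theta_full[idx] = min(max(theta_full[idx], -options.max_abs_param),
                                  options.max_abs_param)


def _shape_init(values: np.ndarray, zbar: float, levels: np.ndarray) -> tuple[float, float]:
    """Moment-match Gibbs weights exp(lin c + quad c^2) to an observed histogram.

    Gives the linear/quadratic shape parameters whose single-actor
    stationary distribution approximately reproduces the observed mean and
    variance -- a far better starting point than zero for these weakly
    identified directions.
    """
    c = levels - zbar
    obs_m1 = float(np.mean(values - zbar))
    obs_m2 = float(np.mean((values - zbar) ** 2))
    lin = quad = 0.0
    for _ in range(25):
        w = np.exp(np.clip(lin * c + quad * c**2, -30, 30))
        w /= w.sum()
        m1 = float(w @ c)
        m2 = float(w @ c**2)
        g = np.array([obs_m1 - m1, obs_m2 - m2])
        # Jacobian of moments wrt (lin, quad) is the covariance of (c, c^2)
        cc = np.vstack([c, c**2])
        cov = (cc * w) @ cc.T - np.outer([m1, m2], [m1, m2])
        try:
            step = np.linalg.solve(cov + 1e-8 * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -1.0, 1.0)
        lin += step[0]
        quad += step[1]
        if np.max(np.abs(g)) < 1e-6:
            break
    return float(np.clip(lin, -3, 3)), float(np.clip(quad, -3, 3))


def initial_theta(spec: ModelSpec, s_obs: np.ndarray,
                  imp: ImputedPanel) -> np.ndarray:
    """Data-driven start values.

    Outdegree and reciprocity start at observed-density log-odds, behaviour
    shapes at marginal moment-matched values, rates at scaled observed
    change amounts; everything else starts at zero.
    """
    theta = spec.theta_template()
    free_names = spec.free_names
    pos = {name: k for k, name in enumerate(free_names)}
    n = len(imp.gender)
    dens = np.mean([a.mean() for a in imp.adjacency]) * n / (n - 1)
    dens = min(max(dens, 1e-3), 0.5)
    if "outdegree" in pos:
        # start near the observed density on the logit scale
        theta[spec["outdegree"].index] = float(np.log(dens / (1.0 - dens)))
    if "reciprocity" in pos:
        # crude moment start: excess log-odds of reciprocation given a tie
        ties = recip = 0.0
        for a in imp.adjacency:
            ties += a.sum()
            recip += (a * a.T).sum()
        r = min(max(recip / max(ties, 1.0), 1e-3), 0.95)
        theta[spec["reciprocity"].index] = float(
            np.log(r / (1 - r)) - np.log(dens / (1 - dens)))
    zbars = spec.consts[0:3]
    tops = (4.0, 3.0, 3.0)
    for b, (lin_name, quad_name) in enumerate((("alc_linear", "alc_quad"),
                                               ("con_linear", "con_quad"),
                                               ("sec_linear", "sec_quad"))):
        if lin_name in pos or quad_name in pos:
            vals = np.concatenate([imp.behaviors[m][b]
                                   for m in range(1, imp.n_waves)])
            lin, quad = _shape_init(vals, zbars[b],
                                    np.arange(1.0, tops[b] + 1.0))
            if lin_name in pos:
                theta[spec[lin_name].index] = lin
            if quad_name in pos:
                theta[spec[quad_name].index] = quad
    n = len(imp.gender)
    for e in spec.effects:
        if e.kind == "rate" and not e.fixed:
            m = e.period - 1
            row_mask, beh_mask = period_masks(imp, m)
            if e.dependent == "network":
                denom = max(1, int(row_mask.sum()))
            else:
                b = {"alcohol": 0, "control": 1, "secrecy": 2}[e.dependent]
                denom = max(1, int(beh_mask[b].sum()))
            observed_change = s_obs[pos[e.name]]
            theta[e.index] = 1.5 * observed_change / denom + 0.2
    return theta


def estimate_school(panel: SchoolPanel, spec: ModelSpec,
                    options: EstimationOptions | None = None,
                    seed: int = 0) -> FitResult:
    """Fit one school by unconditional method of moments.

    Never raises on non-convergence: after ``max_restarts`` automatic
    restarts from the last iterate the result is returned with
    ``converged=False``.
    """
    options = options or EstimationOptions()
    if panel.n_waves < 2:
        raise EstimationError("need at least two waves")
    if spec.n_free < 1:
        raise EstimationError("no free parameters")
    sim = TargetSimulator(panel, spec)
    s_obs = sim.observed()
    free = sim.free
    p = len(free)
    free_names = spec.free_names
    theta = initial_theta(spec, s_obs, sim.imp)
    ss = np.random.SeedSequence(int(seed))
    all_seeds = ss.generate_state(4 * (options.max_restarts + 1), dtype=np.uint64)

    result = None
    for attempt in range(options.max_restarts + 1):
        phase_seeds = all_seeds[4 * attempt:4 * attempt + 4]
        d_seed = int(phase_seeds[0] & 0x7FFFFFFF)
        iter_seed_root = int(phase_seeds[1] & 0x7FFFFFFF)
        counter = 0

        def sims_mean(n_sims):
            nonlocal counter
            out = []
            for _ in range(n_sims):
                out.append(sim.simulate(
                    theta, (iter_seed_root + 7919 * counter) & 0x7FFFFFFF))
                counter += 1
            return np.mean(out, axis=0)

        # phase 2a: damped-Newton travel.  The derivative is re-estimated
        # at every iterate (phase 1 is simply the first of these); the
        # best iterate by a standardised-deviation loss is retained so a
        # noisy excursion cannot end the phase far from the root.
        best = (np.inf, theta[free].copy())
        for it in range(options.newton_iters):
            # refresh densely while travelling fast, sparsely near the root
            if it < 3 or it % options.refresh_every == 0:
                D, sd_ref = _derivative(sim, theta, options,
                                        (d_seed + 65537 * it) & 0x7FFFFFFF,
                                        return_sd=True)
                solve = _solve_factor(D, free_names)
            dev = sims_mean(options.n_dev) - s_obs
            loss = float(np.mean(np.abs(dev) / sd_ref))
            if loss < best[0]:
                best = (loss, theta[free].copy())
            step = solve(dev)
            big = np.max(np.abs(step))
            if big > options.max_step:   # rescale, preserving direction
                step = step * (options.max_step / big)
            theta[free] = theta[free] - options.newton_gain * step
            _clip_theta(theta, free, options)
        if options.use_best_guard:
            dev = sims_mean(options.n_dev) - s_obs
            if float(np.mean(np.abs(dev) / sd_ref)) > best[0]:
                theta[free] = best[1]

        # phase 2b: Polyak-averaged polishing at a fixed derivative
        D, sd_ref = _derivative(sim, theta, options,
                                (d_seed + 524287) & 0x7FFFFFFF, return_sd=True)
        solve = _solve_factor(D, free_names)
        iterates = []
        for it in range(options.final_iters):
            dev = sims_mean(options.n_avg) - s_obs
            step = solve(dev)
            big = np.max(np.abs(step))
            if big > options.max_step:
                step = step * (options.max_step / big)
            theta[free] = theta[free] - options.final_gain * step
            _clip_theta(theta, free, options)
            iterates.append(theta[free].copy())
        theta[free] = np.mean(iterates, axis=0)
        _clip_theta(theta, free, options)

        # phase 3: independent simulations at theta-hat
        p3_root = int(phase_seeds[2] & 0x7FFFFFFF)
        stats = np.array([sim.simulate(theta, (p3_root + 104729 * r) & 0x7FFFFFFF)
                          for r in range(options.n3)])
        t_ratios, overall = convergence_diagnostics(stats, s_obs)
        Dinv = np.linalg.pinv(D)
        sigma = np.atleast_2d(np.cov(stats, rowvar=False))
        covariance = Dinv @ sigma @ Dinv.T
        se_free = np.sqrt(np.clip(np.diag(covariance), 0.0, None))
        se = np.full(spec.n_params, np.nan)
        se[free] = se_free
        rates = spec.pack(theta)[4]
        converged = bool(np.max(np.abs(t_ratios)) < 0.1 and overall < 0.25)
        result = FitResult(
            theta=theta.copy(), se=se, covariance=covariance, rates=rates,
            t_ratios=t_ratios, overall_ratio=overall, converged=converged,
            n_phase3=options.n3, seed=int(seed), free_names=free_names,
            free_indices=free.copy(), school_id=panel.school_id)
        if converged:
            break
    return result
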