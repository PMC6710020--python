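"""End-to-end pipeline: synth -> estimate -> gof -> meta -> tables.

Driven by a single YAML/JSON config with blocks ``synth``, ``model``,
``estimation``, ``meta`` and ``tables``.  Every stage writes its outputs
under the run directory and records them in ``manifest.json`` (seeds,
config hash, package version, per-school status); with ``resume=True``
schools whose fit artefact already exists are not recomputed.  Per-school
estimation failures are logged and the school skipped — a partial study
still produces pooled output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import ModelSpec
from .estimate import EstimationOptions, FitResult, estimate_school
from .gof import auxiliary_vector, gof_frame, gof_test
from .meta import meta_analyse_fits
from .panels import SchoolPanel, filter_schools, impute_panel, load_metadata, load_panel
from .selection import tables_from_fits
from .synth import SynthConfig, generate_study, write_study

log = logging.getLogger("netcoevolve")

STAGES = ("synth", "estimate", "gof", "meta", "tables")

DEFAULT_META_EFFECTS = [
    "alc_alter", "alc_ego", "alc_sim",
    "sec_alter", "sec_ego", "sec_sim",
    "con_alter", "con_ego", "con_sim",
    "con_ego_x_alc_sim", "alc_totsim", "alc_con_x_totsim",
    "alc_sec_x_totsim", "sec_avsim", "sec_alt_avg_alc", "con_from_alc",
]


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(cfg) - {"stages", "seed", "out", "synth", "data", "model",
                          "estimation", "meta", "tables", "gof"}
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _spec_for(panel: SchoolPanel, model_cfg: dict) -> ModelSpec:
    return ModelSpec.from_panel(
        panel,
        exclude=model_cfg.get("exclude", ()),
        fix=model_cfg.get("fix"),
        dimensions=tuple(model_cfg.get("dimensions",
                                       ("network", "alcohol", "control", "secrecy"))),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None,
                 seed: int | None = None, resume: bool = False,
                 schools: list[str] | None = None,
                 stages: list[str] | None = None) -> Path:
    """Execute the requested stages; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    stages = list(stages or config.get("stages", STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(out_dir or config.get("out", "run"))
    out.mkdir(parents=True, exist_ok=True)

    manifest_path = out / "manifest.json"
    manifest = {
        "version": __version__, "seed": seed, "config_hash": _config_hash(config),
        "stages": stages, "schools": {}, "excluded_schools": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # ---- data: synthesise or load ---------------------------------------
    panels: list[SchoolPanel] = []
    if "synth" in stages:
        synth_cfg = SynthConfig(**{**config.get("synth", {}), "seed": seed})
        panels, truths, metadata = generate_study(synth_cfg)
        write_study(panels, truths, metadata, out / "data")
        log.info("synth: wrote %d schools", len(panels))
    else:
        data_cfg = config.get("data", {})
        if not data_cfg:
            raise ConfigError("no synth stage and no data block")
        metadata = load_metadata(data_cfg["metadata"])
        for _, row in metadata.iterrows():
            sid = str(row["school_id"])
            base = Path(data_cfg["root"]) / sid
            net_files = sorted(base.glob(f"{sid}_wave*_edges.csv"))
            panels.append(load_panel(net_files, base / f"{sid}_attributes.csv", row))

    threshold = config.get("data", {}).get("missing_threshold", 0.20)
    panels = filter_schools(panels, threshold)
    if schools:
        panels = [p for p in panels if p.school_id in schools]
    metadata = metadata[metadata["school_id"].isin([p.school_id for p in panels])]

    if set(stages) == {"synth"}:
        manifest["schools"] = {p.school_id: {"status": "generated"} for p in panels}
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return out

    # ---- per-school estimation (and GOF) --------------------------------
    model_cfg = config.get("model", {})
    opts = EstimationOptions(**config.get("estimation", {}))
    gof_cfg = config.get("gof", {})
    fits, specs, kept_panels = [], [], []
    fit_dir = out / "fits"
    fit_dir.mkdir(exist_ok=True)
    for k, panel in enumerate(panels):
        sid = panel.school_id
        fit_path = fit_dir / f"{sid}.json"
        spec = _spec_for(panel, model_cfg)
        school_seed = int(np.random.SeedSequence([seed, 11, k]).generate_state(1)[0] >> 1)
        try:
            if resume and fit_path.exists():
                fit = FitResult.from_json(fit_path.read_text())
                log.info("%s: resumed", sid)
            else:
                t0 = time.time()
                fit = estimate_school(panel, spec, opts, seed=school_seed)
                log.info("%s: fitted in %.1fs, converged=%s, max|t|=%.3f",
                         sid, time.time() - t0, fit.converged,
                         float(np.max(np.abs(fit.t_ratios))))
                fit.to_json(fit_path)
        except Exception as exc:                     # noqa: BLE001 - per-school isolation
            log.warning("%s: estimation failed (%s); school skipped", sid, exc)
            manifest["schools"][sid] = {"status": "failed", "error": str(exc)}
            continue
        manifest["schools"][sid] = {
            "status": "converged" if fit.converged else "not_converged",
            "seed": school_seed, "overall_ratio": fit.overall_ratio,
        }
        if not fit.converged:
            manifest["excluded_schools"].append(sid)
        fits.append(fit)
        specs.append(spec)
        kept_panels.append(panel)

        if "gof" in stages and fit.converged:
            _run_gof(panel, spec, fit, out / "gof", school_seed,
                     n_replicates=int(gof_cfg.get("replicates", 200)))

    # ---- pooling ---------------------------------------------------------
    require_converged = bool(config.get("meta", {}).get("require_converged", True))
    if "meta" in stages and fits:
        effect_names = config.get("meta", {}).get(
            "effects", [n for n in DEFAULT_META_EFFECTS
                        if any(not s[n].fixed for s in specs)])
        result = meta_analyse_fits(fits, specs, metadata, effect_names,
                                   require_converged=require_converged)
        result.to_frame().to_csv(out / "meta_table.csv", index=False)
        log.info("meta: pooled %d effects over %d schools (%d excluded)",
                 len(result.effects), result.n_schools,
                 len(result.excluded_schools))

    if "tables" in stages and fits:
        behaviors = config.get("tables", {}).get(
            "behaviors", ["alcohol", "control", "secrecy"])
        types = [p.school_type for p in kept_panels]
        frames = []
        conv = [(f, s, t) for f, s, t in zip(fits, specs, types)
                if f.converged or not require_converged]
        if conv:
            cf, cs, ct = zip(*conv)
            for beh in behaviors:
                strata = ("all", "coed", "girls", "boys") if beh == "secrecy" else ("all",)
                for st, table in tables_from_fits(list(cf), list(cs), beh,
                                                  list(ct), strata).items():
                    frames.append(table.to_frame())
        if frames:
            pd.concat(frames).to_csv(out / "selection_tables.csv", index=False)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out


def _run_gof(panel: SchoolPanel, spec: ModelSpec, fit: FitResult,
             gof_dir: Path, seed: int, n_replicates: int = 200) -> None:
    """Simulate the reference cloud at theta-hat and write distances + CSV."""
    from . import kernels
    from .simulate import dyad_class_tables

    gof_dir.mkdir(exist_ok=True)
    imp = impute_panel(panel)
    tn, ta, tc, ts, rates = spec.pack(fit.theta)
    tn, ta, tc, ts = (np.ascontiguousarray(a) for a in (tn, ta, tc, ts))
    edy, inv_edy = dyad_class_tables(tn, spec.consts)
    gender = np.ascontiguousarray(imp.gender)
    fsm = np.ascontiguousarray(imp.fsm)
    obs = np.zeros_like(auxiliary_vector(imp.adjacency[-1]))
    for m in range(1, imp.n_waves):
        obs += auxiliary_vector(imp.adjacency[m])
    sims = []
    seeds = np.random.SeedSequence([seed, 17]).generate_state(n_replicates * spec.n_periods) >> 1
    si = 0
    for r in range(n_replicates):
        acc = None
        for m in range(spec.n_periods):
            adj = imp.adjacency[m].copy()
            beh = imp.behaviors[m].copy()
            kernels.simulate_period_inplace(
                adj, beh[0], beh[1], beh[2], gender, fsm, tn, ta, tc, ts,
                np.ascontiguousarray(rates[m]), spec.consts, 1.0, int(seeds[si]),
                edy, inv_edy)
            si += 1
            aux = auxiliary_vector(adj)
            acc = aux if acc is None else acc + aux
        sims.append(acc)
    sims = np.asarray(sims)
    distance, p = gof_test(obs, sims)
    frame = gof_frame(obs, sims)
    frame.to_csv(gof_dir / f"{panel.school_id}_aux.csv", index=False)
    with open(gof_dir / f"{panel.school_id}_test.json", "w") as fh:
        json.dump({"distance": distance, "p_value": p,
                   "n_replicates": n_replicates}, fh)
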