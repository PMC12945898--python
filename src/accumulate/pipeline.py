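"""End-to-end study runner: synth -> qc -> fit -> checks -> measures -> association.

A study is described by one YAML-style config with ``synth``, ``fit`` and
``associate`` sections; :func:`run_study` executes the stages in order and
writes every artifact table plus a manifest (config hash, seeds, versions)
that suffices to reproduce the run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_table, correlation_table
from .checks import coverage, posterior_predictive
from .fitting import FitConfig, fit_cohort
from .measures import measures_table
from .synth import CriterionSpec, PopulationSpec, generate_study
from .trial_data import apply_qc, measures_frame, write_trials

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "synth": {
        "task": "nback",
        "n_subjects": 40,
        "trials_per_condition": 300,
        "seed": 1,
    },
    "qc": {"accuracy_floor": 0.55, "omission_ceiling": 0.25},
    "fit": {
        "models": ["lba", "ddm"],
        "burn_in": 300,
        "block": 150,
        "max_iter": 600,
        "seed": 1,
        "include_nonconverged": True,
    },
    "checks": {"n_draws": 50, "seed": 1},
    "associate": {
        "nest": ["family", "site"],
        "n_boot": 200,
        "seed": 1,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    for section in cfg:
        if section not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config section {section!r}")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _population_spec(synth_cfg: dict) -> PopulationSpec:
    kwargs = dict(synth_cfg)
    if "criteria" in kwargs:
        kwargs["criteria"] = tuple(
            CriterionSpec(**c) for c in kwargs["criteria"]
        )
    return PopulationSpec(**kwargs)


def run_study(config, out_dir) -> dict:
    """Run a full synthetic study; returns the manifest dictionary.

    Writes trials.csv, criteria.csv, truth.csv, qc.csv, fits_<model>.csv,
    ppc.csv, measures.csv, correlations.csv, association.csv and
    manifest.json into ``out_dir``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- synth ---------------------------------------------------------
    spec = _population_spec(cfg["synth"])
    cohort, trials, criteria = generate_study(spec, seed=cfg["synth"]["seed"])
    write_trials(trials, out / "trials.csv")
    criteria.to_csv(out / "criteria.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)

    # --- qc ------------------------------------------------------------
    retained, excluded = apply_qc(
        trials,
        accuracy_floor=cfg["qc"]["accuracy_floor"],
        omission_ceiling=cfg["qc"]["omission_ceiling"],
    )
    qc_rows = measures_frame(trials)
    reasons = {e.dataset.subject_id: e.reason for e in excluded}
    qc_rows["excluded"] = qc_rows["subject"].isin(reasons)
    qc_rows["reason"] = qc_rows["subject"].map(reasons).fillna("")
    qc_rows.to_csv(out / "qc.csv", index=False)
    logger.info("QC: %d retained, %d excluded", len(retained), len(excluded))

    # --- fits ----------------------------------------------------------
    fit_cfg = FitConfig(
        burn_in=cfg["fit"]["burn_in"],
        block=cfg["fit"]["block"],
        max_iter=cfg["fit"]["max_iter"],
    )
    fits = {}
    for model in cfg["fit"]["models"]:
        results = fit_cohort(retained, model=model, config=fit_cfg,
                             master_seed=cfg["fit"]["seed"])
        fits[model] = results
        tables = []
        for res in results:
            t = res.summary.copy()
            t.insert(0, "subject", res.subject_id)
            t["converged"] = res.converged
            t["max_rhat"] = res.max_rhat
            tables.append(t)
        pd.concat(tables, ignore_index=True).to_csv(
            out / f"fits_{model}.csv", index=False)

    # --- posterior predictive checks ----------------------------------
    ppc_rows = []
    rng = np.random.default_rng(cfg["checks"]["seed"])
    by_subject = {ds.subject_id: ds for ds in retained}
    for model, results in fits.items():
        for res in results:
            tab = posterior_predictive(
                by_subject[res.subject_id], res,
                n_draws=cfg["checks"]["n_draws"],
                seed=np.random.default_rng(rng.integers(2**31 - 1)))
            tab.insert(0, "model", model)
            tab.insert(0, "subject", res.subject_id)
            ppc_rows.append(tab)
    ppc = pd.concat(ppc_rows, ignore_index=True)
    ppc.to_csv(out / "ppc.csv", index=False)

    # --- measures ------------------------------------------------------
    lba_fits = fits.get("lba", [])
    ddm_fits = fits.get("ddm")
    measures = measures_table(lba_fits, ddm_fits)
    if not cfg["fit"]["include_nonconverged"]:
        keep = measures["converged_lba"]
        if "converged_ddm" in measures:
            keep &= measures["converged_ddm"]
        measures = measures[keep]
    nesting = cohort.truth[["subject", "family", "site",
                            "EEA_true", "SEA_true"]]
    measures = measures.merge(nesting, on="subject", how="left")
    measures.to_csv(out / "measures.csv", index=False)

    # --- association ---------------------------------------------------
    assoc_cfg = cfg["associate"]
    corr = (correlation_table(measures)
            if "v_mean" in measures and len(measures) >= 3
            else pd.DataFrame(columns=["task", "predictor", "target",
                                       "r", "n", "p"]))
    corr.to_csv(out / "correlations.csv", index=False)
    crit_names = [c.name for c in spec.criteria]
    data = measures.merge(criteria.drop(columns=["family", "site"]),
                          on="subject", how="inner")
    if len(data) >= 4:
        assoc = association_table(
            data, crit_names, groups=list(assoc_cfg["nest"]),
            n_boot=assoc_cfg["n_boot"], seed=assoc_cfg["seed"])
    else:
        logger.warning("too few subjects for association models; "
                       "writing empty table")
        assoc = pd.DataFrame(columns=["criterion", "predictor", "part_r2",
                                      "ci_lo", "ci_hi", "n_boot"])
    assoc.to_csv(out / "association.csv", index=False)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "n_subjects": spec.n_subjects,
        "n_retained": len(retained),
        "n_converged": {
            m: int(sum(r.converged for r in res)) for m, res in fits.items()
        },
        "ppc_coverage": {
            m: float(coverage(ppc[ppc["model"] == m])) for m in fits
        },
        "artifacts": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
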