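"""Config-driven orchestration of the full exposome analysis.

Stages: simulate (or ingest CSVs) -> mixed correlation -> redundancy
reduction -> EFA + iterated target rotation -> bifactor fit + pruning ->
factor scores -> association models.  Every stage logs its parameters
and outputs; numeric CSV artifacts are rounded to 6 decimals so reruns
with an identical config hash identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import bifactor as bf
from .correlation import mixed_correlation_matrix
from .efa import extract_minres, iterated_target_rotation, retain_factors
from .manifest import VariableManifest
from .reduction import ReductionConfig, ReductionResult, reduce_redundancy
from .synthetic import (GenerativeSpec, OutcomeSpec, default_generative_spec,
                        simulate_cohort)

log = logging.getLogger("expofactor.pipeline")

_STAGES = ("simulate", "correlate", "reduce", "efa", "bifactor", "score",
           "associate")


@dataclass
class PipelineConfig:
    out_dir: str = "expofactor_run"
    seed: int = 0
    n_subjects: int = 3000
    n_specific: int = 4
    items_per_factor: int = 10
    icc_family: float = 0.3
    missing_rate: float = 0.02
    cutoff: float = 0.30
    k_override: int | None = None
    stages: tuple[str, ...] = _STAGES
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    input_dir: str | None = None  # if set, ingest CSVs instead of simulating

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        red = raw.pop("reduction", None)
        cfg = cls(**raw)
        if red:
            cfg.reduction = ReductionConfig(**red)
        cfg.stages = tuple(cfg.stages)
        return cfg


def _round_csv(df: pd.DataFrame, path: Path, index=False) -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].round(6)
    df.to_csv(path, index=index)
    return _sha256(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"seed": config.seed, "cutoff": config.cutoff,
                               "stages": list(config.stages)},
                    "stages": {}, "outputs": {}}

    def record(stage, **info):
        report["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3), **info}

    # --- simulate / ingest -------------------------------------------------
    t0 = time.time()
    if config.input_dir is None:
        spec = default_generative_spec(
            n_subjects=config.n_subjects, n_specific=config.n_specific,
            items_per_factor=config.items_per_factor,
            icc_family=config.icc_family, missing_rate=config.missing_rate,
            seed=config.seed)
        cohort = simulate_cohort(spec, OutcomeSpec(
            beta_specific=OutcomeSpec().beta_specific[:config.n_specific],
            seed=config.seed))
        items, manifest = cohort.items, cohort.manifest
        covariates, outcomes = cohort.covariates, cohort.outcomes
        family_id = cohort.family_id
        if "simulate" in config.stages:
            cohort.write_csv(out / "cohort")
            report["outputs"]["items"] = _sha256(out / "cohort" / "items.csv")
    else:
        indir = Path(config.input_dir)
        items = pd.read_csv(indir / "items.csv")
        manifest = VariableManifest.from_csv(indir / "manifest.csv")
        covariates = pd.read_csv(indir / "covariates.csv")
        outcomes = pd.read_csv(indir / "outcomes.csv")
        latent = indir / "latent_scores.csv"
        family_id = (pd.read_csv(latent)["family_id"].to_numpy()
                     if latent.exists() else np.zeros(len(items), int))
    record("simulate", n_subjects=len(items), n_items=items.shape[1])
    log.info("cohort ready: %d x %d", len(items), items.shape[1])

    # --- reduce ------------------------------------------------------------
    t0 = time.time()
    if "reduce" in config.stages:
        red: ReductionResult = reduce_redundancy(items, manifest,
                                                 config.reduction)
        items_red, manifest_red = red.table, red.manifest
        report["outputs"]["reduction_audit"] = _round_csv(
            red.audit_frame(), out / "reduction_audit.csv")
        record("reduce", n_before=items.shape[1], n_after=len(red.surviving),
               iterations=red.iterations)
    else:
        items_red, manifest_red = items, manifest
        record("reduce", skipped=True)

    # --- correlate ---------------------------------------------------------
    t0 = time.time()
    R = mixed_correlation_matrix(items_red, manifest_red, deletion="pairwise")
    rpath = out / "correlation.csv"
    R.to_csv(rpath)
    report["outputs"]["correlation"] = _sha256(rpath)
    record("correlate", p=R.p, smoothed=R.smoothed)

    # --- efa ---------------------------------------------------------------
    t0 = time.time()
    n_eff = len(items_red)
    if config.k_override is not None:
        k = config.k_override
    else:
        k, _, _ = retain_factors(R, n_eff, seed=config.seed)
    unrot = extract_minres(R, k)
    rotated = iterated_target_rotation(unrot, cutoff=config.cutoff)
    report["outputs"]["efa_loadings"] = _round_csv(
        pd.DataFrame(rotated.loadings, index=R.names,
                     columns=[f"F{j + 1}" for j in range(k)]),
        out / "efa_loadings.csv", index=True)
    report["outputs"]["efa_phi"] = _round_csv(
        pd.DataFrame(rotated.phi), out / "efa_phi.csv")
    record("efa", k=k, itr_iterations=rotated.iterations,
           converged=rotated.converged)

    # --- bifactor ----------------------------------------------------------
    t0 = time.time()
    model_spec = bf.configure_bifactor(rotated, R.names, cutoff=config.cutoff)
    idx = [R.names.index(it) for it in model_spec.items]
    from .correlation import CorrelationMatrix

    R_model = CorrelationMatrix(R.values[np.ix_(idx, idx)], model_spec.items)
    fit = bf.fit_bifactor(R_model, model_spec, n_obs=n_eff, seed=config.seed)
    fit, prune_audit = bf.prune_and_refit(fit, R_model, n_eff,
                                          cutoff=config.cutoff,
                                          seed=config.seed)
    names_final = fit.spec.items
    idx2 = [R.names.index(it) for it in names_final]
    R_final = CorrelationMatrix(R.values[np.ix_(idx2, idx2)], names_final)
    indices = bf.bifactor_indices(fit, R_final)
    fitidx = bf.fit_indices(fit, R_final)
    report["outputs"]["bifactor_loadings"] = _round_csv(
        fit.to_frame(), out / "bifactor_loadings.csv")
    (out / "bifactor_summary.json").write_text(json.dumps({
        "items_before_pruning": model_spec.p,
        "items_after_pruning": fit.spec.p,
        "pruned": [a["item"] for a in prune_audit],
        "cfi": round(fitidx.cfi, 6), "rmsea": round(fitidx.rmsea, 6),
        "srmr": round(fitidx.srmr, 6), "ecv": round(indices.ecv, 6),
        "omega_h": round(indices.omega_h, 6),
        "fd": [round(float(x), 6) for x in indices.fd],
    }, indent=2))
    report["outputs"]["bifactor_summary"] = _sha256(out / "bifactor_summary.json")
    record("bifactor", items=fit.spec.p, n_specific=fit.spec.n_specific,
           srmr=round(fitidx.srmr, 6), rmsea=round(fitidx.rmsea, 6))

    # --- score -------------------------------------------------------------
    t0 = time.time()
    std_items = bf.standardize_items(items_red[names_final],
                                     manifest_red.subset(names_final))
    scores = bf.factor_scores(std_items, fit, R_final, indices,
                              orthogonalize=True)
    report["outputs"]["factor_scores"] = _round_csv(
        scores.scores.reset_index().rename(columns={"index": "subject"}),
        out / "factor_scores.csv")
    record("score", n_scored=len(scores.scores), n_dropped=scores.n_dropped)

    # --- associate ---------------------------------------------------------
    t0 = time.time()
    if "associate" in config.stages:
        rows = scores.scores.index
        preds = scores.scores
        covs = covariates.loc[rows]
        y = outcomes.loc[rows, "p_factor"]
        lin = assoc.standardized_linear_model(y, preds, covs)
        dr2 = assoc.delta_r2(y, covs, preds)
        logi = assoc.logistic_model(outcomes.loc[rows, "obesity"], preds, covs)
        contrast = assoc.group_contrast(preds["general"],
                                        covs["low_income"])
        report["outputs"]["association"] = _round_csv(
            lin.to_frame().reset_index().rename(columns={"index": "predictor"}),
            out / "association_linear.csv")
        report["outputs"]["association_logistic"] = _round_csv(
            logi.to_frame().reset_index().rename(columns={"index": "predictor"}),
            out / "association_logistic.csv")
        record("associate", n=lin.n,
               adj_r2_base=round(dr2.adj_r2_base, 6),
               adj_r2_full=round(dr2.adj_r2_full, 6),
               beta_general=round(float(lin.beta["general"]), 6),
               or_general=round(float(logi.odds_ratio["general"]), 6),
               d_income=round(contrast.cohens_d, 6))
    else:
        record("associate", skipped=True)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
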