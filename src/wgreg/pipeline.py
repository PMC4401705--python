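"""End-to-end orchestration: simulate -> QC -> GRM -> model fits -> family CV -> report.

Runs the standard model sequence on a (synthetic) cohort: the covariates
baseline, an optional known-marker fixed-effect benchmark, and the requested
whole-genome regression priors; then family-blocked cross-validation and a
side-by-side AUC table plus the heritability summary. Every stage logs its
seed and every output file is declared in a manifest so a run can be
replayed byte-for-byte from its serialized config.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .crossval import CohortData, RiskScores, assign_family_folds, cross_validate, fold_auc_summary
from .genodata import compute_pcs, impute_missing, qc_filter, write_genotypes
from .grm import compute_grm
from .report import fixed_effect_report
from .samplers import MCMCConfig, ModelSpec, fit_probit_wgr

WGR_PRIORS = ("bayes-a", "bayes-c-pi", "b-lasso", "gblup-brr")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (serialized alongside outputs)."""

    outdir: str = "wgreg_run"
    seed: int = 0
    # cohort
    n_families: int = 150
    family_size_range: tuple = (4, 6)
    p_markers: int = 2000
    h2_target: float = 0.5
    pi_nonnull: float = 1.0
    # analysis
    maf_min: float = 0.05
    max_missing: float = 0.10
    downsample_fraction: float = 1.0
    n_pcs: int = 2
    models: tuple = ("fixed-only",) + WGR_PRIORS
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 5
    cv_folds: int = 10
    run_cv: bool = True

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        if path.endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _validate(config: RunConfig) -> None:
    from .samplers import _PRIOR_FAMILIES

    bad = [m for m in config.models if m not in _PRIOR_FAMILIES]
    if bad:
        raise ValueError(f"unknown prior families requested: {bad}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to disk)."""
    _validate(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "files": []}
    t0 = time.time()
    log_path = out / "run.log"  # timing log, deliberately outside the manifest
    log_fh = open(log_path, "w")

    def log_stage(name: str, **info):
        rec = {"stage": name, "elapsed_s": round(time.time() - t0, 2), "seed": config.seed, **info}
        log_fh.write(json.dumps(rec) + "\n")
        log_fh.flush()

    def emit(name: str, writer):
        path = out / name
        writer(path)
        manifest["files"].append(name)
        return path

    # --- simulate ---
    cfg = sim.SimulationConfig(
        n_families=config.n_families,
        family_size_range=tuple(config.family_size_range),
        p_markers=config.p_markers,
        h2_target=config.h2_target,
        pi_nonnull=config.pi_nonnull,
        seed=config.seed,
    )
    ped, geno, cov, pheno, truth = sim.simulate_cohort(cfg)
    emit("pedigree.tsv", lambda p: ped.to_csv(p, sep="\t", index=False))
    emit("covariates.tsv", lambda p: cov.to_csv(p, sep="\t", index=False))
    emit("phenotypes.tsv", lambda p: pheno.to_csv(p, sep="\t", index=False))
    emit("true_architecture.tsv", lambda p: truth.to_frame().to_csv(p, sep="\t", index=False))
    emit("genotypes.tsv", lambda p: write_genotypes(geno, str(p)))
    log_stage("simulate", n_subjects=geno.n_subjects, n_markers=geno.n_markers,
              prevalence=float(np.mean(pheno["y"])))

    # --- qc + imputation ---
    geno_qc, qc_report = qc_filter(geno, maf_min=config.maf_min, max_missing=config.max_missing)
    if config.downsample_fraction < 1.0:
        from .genodata import downsample_markers

        geno_qc = downsample_markers(geno_qc, config.downsample_fraction, seed=config.seed)
    geno_qc = impute_missing(geno_qc)
    log_stage("qc", **qc_report.to_dict())

    # --- covariate design: sex, cohort, age, PC1..PCk ---
    pcs = compute_pcs(geno_qc, k=config.n_pcs)
    cov_design = cov.set_index("individual_id").loc[list(geno_qc.subject_ids)]
    design = pd.DataFrame(
        {
            "sex": cov_design["sex"].to_numpy(dtype=float),
            "cohort": cov_design["cohort"].to_numpy(dtype=float),
            "age": cov_design["age"].to_numpy() - cov_design["age"].to_numpy().mean(),
        }
    )
    for i in range(config.n_pcs):
        design[f"PC{i + 1}"] = pcs.scores[:, i]
    y = pheno.set_index("individual_id").loc[list(geno_qc.subject_ids), "y"].to_numpy()
    W = np.column_stack([np.ones(len(design)), design.to_numpy()])
    names = ["intercept"] + list(design.columns)

    # --- GRM + heritability from the BRR fit ---
    grm = compute_grm(geno_qc)
    emit("grm.tsv", lambda p: grm.write_tsv(str(p)))
    log_stage("grm", mean_diag=float(np.mean(np.diag(grm.matrix))))

    mcmc = MCMCConfig(
        n_iter=config.n_iter, burn_in=config.burn_in, thin=config.thin, seed=config.seed
    )
    report: dict = {"models": {}, "heritability": None, "auc": []}
    for prior in config.models:
        spec = ModelSpec(prior_family=prior)
        genetic = None if prior == "fixed-only" else (grm if prior == "gblup-grm" else geno_qc)
        fit = fit_probit_wgr(y, W, genetic, spec, mcmc, fixed_names=names)
        entry = {
            "fixed_effects": fixed_effect_report(
                fit.alpha_names, fit.alpha_mean, fit.alpha_sd
            ).to_dict(orient="records"),
            "geweke_z": {k: (None if np.isnan(v) else float(v)) for k, v in fit.geweke_z.items()},
        }
        if fit.h2 is not None:
            entry["sigma_u2"] = [fit.h2.sigma_u2_mean, fit.h2.sigma_u2_sd]
            entry["h2"] = [fit.h2.h2_mean, fit.h2.h2_sd]
        if "nonnull_fraction" in fit.samples:
            s = fit.samples["nonnull_fraction"]
            entry["nonnull_fraction"] = [float(s.mean()), float(s.std(ddof=1))]
        report["models"][prior] = entry
        if prior == "gblup-brr" and fit.h2 is not None:
            report["heritability"] = {
                "sigma_u2_mean": fit.h2.sigma_u2_mean,
                "sigma_u2_sd": fit.h2.sigma_u2_sd,
                "h2_mean": fit.h2.h2_mean,
                "h2_sd": fit.h2.h2_sd,
            }
        for trace_name, trace in fit.traces.items():
            emit(
                f"trace_{prior}_{trace_name}.csv",
                lambda p, tr=trace: pd.DataFrame({trace_name: tr}).to_csv(p, index=False),
            )
        log_stage(f"fit_{prior}")

    # --- family-blocked cross-validation ---
    if config.run_cv:
        folds = assign_family_folds(ped, k=config.cv_folds, seed=config.seed)
        emit(
            "folds.tsv",
            lambda p: folds.subject_to_fold.rename("fold").to_frame().to_csv(p, sep="\t"),
        )
        data = CohortData(
            y=y, fixed_design=W, subject_ids=geno_qc.subject_ids,
            genotypes=geno_qc, fixed_names=names,
        )
        for prior in config.models:
            spec = ModelSpec(prior_family=prior)
            risk = cross_validate(data, spec, mcmc, folds, label=prior)
            emit(
                f"risk_scores_{prior}.tsv",
                lambda p, r=risk: r.scores.to_csv(p, sep="\t", index=False),
            )
            report["auc"].append(fold_auc_summary(risk))
            log_stage(f"cv_{prior}")

    emit("report.json", lambda p: p.write_text(json.dumps(report, indent=2, sort_keys=True)))
    emit("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True)))
    log_fh.close()
    return report
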