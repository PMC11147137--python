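"""Orchestrated discovery / validation / intervention analysis runs.

``run_discovery`` executes the full exposure-versus-metabolome analysis:
preprocessing, 25(OH)D calibration, the univariate FDR screen, OPLS-Y with
double cross-validation and permutation testing, VIP > threshold selection,
PCA score construction on the selection, an OPLS-Y refit on the selection,
PC-score and per-metabolite clinical association batteries, and sub-pathway
enrichment.  ``run_validation`` re-derives PCA scores for a discovery
selection inside an independent cohort and reruns the association battery.
``run_intervention_analysis`` contrasts randomization arms (OPLS-DA +
adjusted logistic screen) and reproduces a baseline-table group-difference
report.

Every run writes tab-separated tables plus a JSON manifest (config hash,
seed, package version, per-stage sizes); reruns with identical config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import double_cv, permutation_test, select_n_ortho
from .enrichment import PathwayAnnotation, enrich_subpathways
from .opls import OPLS, OPLSDA, fit_pca, select_vip, vip_scores
from .outcomes import (AssociationResult, chisq_contingency, fit_cox,
                       fit_linear, fit_logistic, fit_quasipoisson,
                       stratified_battery, univariate_screen, welch_t)
from .preprocess import (MetabolomeMatrix, calibrate_exposure, impute_halfmin,
                         log_zscore, qc_filter)
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_validation",
           "run_intervention_analysis"]


class AlignmentError(ValueError):
    """Sample identifiers differ between the metabolome and phenotype tables."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; loadable from YAML."""

    metabolome_path: str = "metabolome.tsv"
    annotation_path: str = "annotation.tsv"
    phenotype_path: str = "phenotypes.tsv"
    output_dir: str = "results"
    max_missing_frac: float = 0.20
    vip_threshold: float = 2.0
    fdr_level: float = 0.05
    outer_folds: int = 10
    inner_folds: int = 7
    max_ortho: int = 5
    n_perm: int = 1000
    seed: int = 0
    exposure_col: str = "vitd"
    arm_col: str = "arm"
    calibration_covariates: tuple[str, ...] = ("arm", "pufa", "smoking", "sex", "season")
    outcome_covariates: tuple[str, ...] = (
        "pufa", "smoking", "breastfeeding_days", "sex", "daycare_start_age", "season")
    survival_outcomes: tuple[tuple[str, str], ...] = (
        ("recurrent_wheeze_time", "recurrent_wheeze_event"),
        ("exacerbation_time", "exacerbation_event"))
    count_outcomes: tuple[str, ...] = (
        "trols_count", "cold_count", "tonsillitis_count", "otitis_count",
        "croup_count", "lri_count")
    binary_outcomes: tuple[str, ...] = ("sensitization",)
    continuous_outcomes: tuple[str, ...] = ("fev1_z", "sraw_z")
    strata_col: str = "genotype17q21"
    per_metabolite_battery: bool = True
    validation_opls: bool = True
    baseline_continuous: tuple[str, ...] = ("vitd",)
    baseline_categorical: tuple[str, ...] = ("smoking", "sex", "season")
    baseline_yates: bool = True
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be positive")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[f.name])
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.as_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_inputs(config: RunConfig) -> tuple[MetabolomeMatrix, PathwayAnnotation, pd.DataFrame]:
    """Read and align the three delimited-text inputs by sample id."""
    data = pd.read_csv(config.metabolome_path, sep="\t", index_col=0)
    annotation = PathwayAnnotation(
        pd.read_csv(config.annotation_path, sep="\t", index_col=0))
    phen = pd.read_csv(config.phenotype_path, sep="\t", index_col=0)
    only_met = data.index.difference(phen.index)
    only_phen = phen.index.difference(data.index)
    if len(only_met) or len(only_phen):
        raise AlignmentError(
            f"sample-id mismatch: {list(only_met[:5])} only in metabolome, "
            f"{list(only_phen[:5])} only in phenotypes")
    phen = phen.loc[data.index]
    matrix = MetabolomeMatrix(data=data, state="raw", annotation=annotation)
    logger.info("loaded %d samples x %d metabolites", *data.shape)
    return matrix, annotation, phen


def preprocess_matrix(matrix: MetabolomeMatrix, config: RunConfig) -> MetabolomeMatrix:
    """qc_filter -> impute_halfmin -> log_zscore."""
    return log_zscore(impute_halfmin(qc_filter(matrix, config.max_missing_frac)))


def _outdir(config: RunConfig, names: Sequence[str]) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.overwrite:
        clashes = [str(out / n) for n in names if (out / n).exists()]
        if clashes:
            raise FileExistsError(
                f"outputs exist; pass overwrite/--force to replace: {clashes}")
    return out


def _write_manifest(out: Path, config: RunConfig, stages: dict) -> None:
    manifest = {
        "config": config.as_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _battery(phen: pd.DataFrame, exposures: pd.DataFrame, config: RunConfig,
             stratify_exposures: Sequence[str] = ()) -> pd.DataFrame:
    """Association battery of every exposure column against all outcomes."""
    cov = list(config.outcome_covariates)
    results: list[AssociationResult] = []
    for name in exposures.columns:
        df = phen.join(exposures[[name]])
        for time_col, event_col in config.survival_outcomes:
            results.append(fit_cox(df, time_col, event_col, name, cov))
        for count_col in config.count_outcomes:
            results.append(fit_quasipoisson(df, count_col, name, cov))
        for bin_col in config.binary_outcomes:
            results.append(fit_logistic(df, bin_col, name, cov))
        for cont_col in config.continuous_outcomes:
            results.append(fit_linear(df, cont_col, name, cov))
        if name in stratify_exposures and config.strata_col in df.columns:
            pool = {"CG": "CG/CC", "CC": "CG/CC"}
            for time_col, event_col in config.survival_outcomes:
                results.extend(stratified_battery(
                    df, "cox", config.strata_col, pool=pool,
                    time=time_col, event=event_col, exposure=name, covariates=cov))
    table = pd.DataFrame([r.as_dict() for r in results])
    ok = table["p_value"].notna()
    table["q_value"] = np.nan
    if ok.any():
        table.loc[ok, "q_value"] = bh_adjust(table.loc[ok, "p_value"].to_numpy())
    return table


def run_discovery(config: RunConfig) -> dict:
    """Full discovery analysis; returns the report bundle it also writes."""
    t0 = time.perf_counter()
    files = ["screen.tsv", "vip.tsv", "pca_scores.tsv", "associations.tsv",
             "enrichment.tsv", "opls_summary.json"]
    out = _outdir(config, files + ["manifest.json"])
    matrix, annotation, phen = load_inputs(config)
    z = preprocess_matrix(matrix, config)
    logger.info("preprocessing kept %d metabolites", z.n_metabolites)

    cal = calibrate_exposure(phen[config.exposure_col],
                             phen[list(config.calibration_covariates)])
    z_cal = MetabolomeMatrix(z.data.loc[cal.sample_ids], state="zscored",
                             annotation=z.annotation)
    y = cal.calibrated

    screen = univariate_screen(z_cal, y, family="linear")
    screen.to_csv(out / "screen.tsv", sep="\t")

    X = z_cal.data.to_numpy()
    yv = y.to_numpy()
    n_ortho = select_n_ortho(X, yv, config.inner_folds, config.max_ortho, config.seed)
    cv = double_cv(X, yv, config.outer_folds, config.inner_folds,
                   config.max_ortho, config.seed)
    perm = permutation_test(X, yv, config.n_perm, config.seed,
                            config.outer_folds, config.inner_folds, config.max_ortho)
    model = OPLS(n_ortho=n_ortho).fit(X, yv)
    vip = vip_scores(model, z_cal.metabolite_ids)
    selection = select_vip(vip, config.vip_threshold)
    vip_table = vip.to_frame()
    vip_table["selected"] = vip_table.index.isin(selection)
    vip_table.sort_values("vip", ascending=False, kind="mergesort").to_csv(
        out / "vip.tsv", sep="\t")

    summary = {
        "n_samples": int(z_cal.n_samples),
        "n_metabolites": int(z_cal.n_metabolites),
        "n_ortho": int(n_ortho),
        "q2": cv.q2,
        "r2y_train_mean": cv.r2y_train_mean,
        "r2x": model.r2x_, "r2y": model.r2y_,
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
        "n_selected": len(selection),
        "selection": selection,
    }

    pca_scores = pd.DataFrame(index=z_cal.sample_ids)
    enrichment = pd.DataFrame()
    assoc = pd.DataFrame()
    if len(selection) >= 2:
        pca = fit_pca(z_cal.data[selection], n_components=2)
        pca_scores = pca.scores
        summary["pc_variance_fraction"] = pca.explained_variance_fraction.tolist()

        refit_cv = double_cv(z_cal.data[selection].to_numpy(), yv,
                             config.outer_folds, config.inner_folds,
                             config.max_ortho, config.seed)
        refit_perm = permutation_test(z_cal.data[selection].to_numpy(), yv,
                                      config.n_perm, config.seed,
                                      config.outer_folds, config.inner_folds,
                                      config.max_ortho)
        summary["refit_q2"] = refit_cv.q2
        summary["refit_permutation_p"] = refit_perm.p_value

        pc_vs_exposure = []
        for pc in ("PC1", "PC2"):
            df = pd.DataFrame({pc: pca_scores[pc], "calibrated_vitd": y})
            r = fit_linear(df, "calibrated_vitd", pc, standardize_outcome=False)
            pc_vs_exposure.append(r.as_dict())
        summary["pc_vs_exposure"] = pc_vs_exposure

        exposures = pca_scores.copy()
        if config.per_metabolite_battery:
            exposures = pd.concat([exposures, z_cal.data[selection]], axis=1)
        assoc = _battery(phen.loc[z_cal.sample_ids], exposures, config,
                         stratify_exposures=("PC1", "PC2"))
        enrichment = enrich_subpathways(selection, z_cal.annotation,
                                        list(z_cal.metabolite_ids))
    else:
        logger.warning("selection has %d metabolite(s); downstream PCA/"
                       "enrichment skipped", len(selection))

    pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    with open(out / "opls_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_manifest(out, config, {
        "n_samples": int(z_cal.n_samples),
        "n_metabolites_postqc": int(z.n_metabolites),
        "n_selected": len(selection),
    })
    logger.info("discovery run complete in %.1f s", time.perf_counter() - t0)
    return {"summary": summary, "screen": screen, "vip": vip_table,
            "pca_scores": pca_scores, "associations": assoc,
            "enrichment": enrichment, "selection": selection}


def run_validation(discovery_selection: Sequence[str], config: RunConfig) -> dict:
    """Refit PCA scores for a discovery selection inside another cohort."""
    files = ["validation_pca_scores.tsv", "validation_associations.tsv",
             "validation_vip.tsv", "validation_enrichment.tsv"]
    out = _outdir(config, files + ["manifest.json"])
    matrix, annotation, phen = load_inputs(config)
    z = preprocess_matrix(matrix, config)

    available = [m for m in discovery_selection if m in z.metabolite_ids]
    dropped = [m for m in discovery_selection if m not in z.metabolite_ids]
    if dropped:
        logger.warning("validation: %d selected metabolite(s) unavailable: %s",
                       len(dropped), dropped[:5])
    if len(available) < 2:
        raise ValueError(
            "validation infeasible: fewer than 2 selected metabolites available")

    pca = fit_pca(z.data[available], n_components=2)
    pca.scores.to_csv(out / "validation_pca_scores.tsv", sep="\t")
    assoc = _battery(phen.loc[z.sample_ids], pca.scores, config)
    assoc.to_csv(out / "validation_associations.tsv", sep="\t", index=False)

    summary = {
        "n_available": len(available),
        "n_dropped": len(dropped),
        "dropped": dropped,
        "pc_variance_fraction": pca.explained_variance_fraction.tolist(),
    }
    vip_table = pd.DataFrame()
    enr = pd.DataFrame()
    if config.validation_opls:
        cal = calibrate_exposure(phen.loc[z.sample_ids, config.exposure_col],
                                 phen.loc[z.sample_ids,
                                          list(config.calibration_covariates)])
        zc = z.data.loc[cal.sample_ids]
        yv = cal.calibrated.to_numpy()
        n_ortho = select_n_ortho(zc.to_numpy(), yv, config.inner_folds,
                                 config.max_ortho, config.seed)
        model = OPLS(n_ortho=n_ortho).fit(zc.to_numpy(), yv)
        vip = vip_scores(model, zc.columns)
        sel = select_vip(vip, config.vip_threshold)
        vip_table = vip.to_frame()
        vip_table["selected"] = vip_table.index.isin(sel)
        summary["validation_n_selected"] = len(sel)
        if len(sel) >= 1:
            enr = enrich_subpathways(sel, z.annotation, list(z.metabolite_ids))
    vip_table.to_csv(out / "validation_vip.tsv", sep="\t")
    enr.to_csv(out / "validation_enrichment.tsv", sep="\t", index=False)
    _write_manifest(out, config, summary)
    return {"summary": summary, "pca_scores": pca.scores, "associations": assoc,
            "vip": vip_table, "enrichment": enr, "available": available}


def run_intervention_analysis(config: RunConfig) -> dict:
    """High-dose vs standard-dose arm analysis of the metabolome."""
    files = ["intervention_screen.tsv", "baseline.tsv", "intervention_opls.json"]
    out = _outdir(config, files + ["manifest.json"])
    matrix, annotation, phen = load_inputs(config)
    if config.arm_col not in phen.columns:
        raise ValueError(f"arm column {config.arm_col!r} missing from phenotypes")
    z = preprocess_matrix(matrix, config)
    phen = phen.loc[z.sample_ids]
    arm = phen[config.arm_col]
    dummy = np.where(arm == sorted(arm.unique())[1], 1.0, -1.0)

    X = z.data.to_numpy()
    cv = double_cv(X, dummy, config.outer_folds, config.inner_folds,
                   config.max_ortho, config.seed)
    perm = permutation_test(X, dummy, config.n_perm, config.seed,
                            config.outer_folds, config.inner_folds,
                            config.max_ortho)
    n_ortho = select_n_ortho(X, dummy, config.inner_folds, config.max_ortho,
                             config.seed)
    model = OPLSDA(n_ortho=n_ortho).fit(X, arm.to_numpy())
    summary = {
        "q2": cv.q2, "permutation_p": perm.p_value, "n_perm": perm.n_perm,
        "n_ortho": int(n_ortho), "r2x": model.r2x_, "r2y": model.r2y_,
    }

    screen_cov = phen[["pufa", "smoking", "sex", "season"]] \
        if set(["pufa", "smoking", "sex", "season"]) <= set(phen.columns) else None
    screen = univariate_screen(z, arm, covariates=screen_cov, family="logistic")
    screen.to_csv(out / "intervention_screen.tsv", sep="\t")
    summary["n_fdr_significant"] = int((screen["q_value"] < config.fdr_level).sum())

    rows = []
    groups = [g for _, g in phen.groupby(arm)]
    for var in config.baseline_continuous:
        g0, g1 = groups[0][var].dropna(), groups[1][var].dropna()
        t, p = welch_t(g0.mean(), g0.std(ddof=1), len(g0),
                       g1.mean(), g1.std(ddof=1), len(g1))
        rows.append({"variable": var, "test": "welch_t", "statistic": t, "p_value": p})
    for var in config.baseline_categorical:
        tab = pd.crosstab(arm, phen[var])
        chi2, df, p = chisq_contingency(tab.to_numpy(),
                                        yates=config.baseline_yates and tab.shape == (2, 2))
        rows.append({"variable": var, "test": "chisq", "statistic": chi2, "p_value": p})
    baseline = pd.DataFrame(rows)
    baseline.to_csv(out / "baseline.tsv", sep="\t", index=False)
    with open(out / "intervention_opls.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    _write_manifest(out, config, {"n_samples": int(z.n_samples),
                                  "n_metabolites_postqc": int(z.n_metabolites)})
    return {"summary": summary, "screen": screen, "baseline": baseline}
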