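"""Synthetic mother-child cohort generator.

Emulates the statistical structure of a randomized prenatal vitamin-D
supplementation cohort with untargeted maternal blood metabolomics:

* a latent vitamin-D "metabolic axis" L ~ N(0,1) per mother;
* maternal 25(OH)D (nmol/L) built from a baseline, a randomized high-dose
  arm shift, a loading on L, a birth-month sinusoid (seasonality), a smoking
  decrement, and residual noise — anchored to the observed cohort scale
  (baseline ~88 nmol/L, arm shift ~33 nmol/L, overall SD ~36 nmol/L);
* log-normal metabolite intensities: a designated block of "signal"
  metabolites, all in one sub-pathway, loads on L on the log scale; all
  other metabolites are pure noise;
* child clinical outcomes whose hazard (time-to-event), rate (episode
  counts), odds (sensitization) and mean (lung function) depend on L;
* completely-at-random missingness and administrative censoring at a fixed
  horizon.

Defaults mirror the discovery cohort the pipeline targets: 672 mothers,
753 annotated metabolites in 9 super-pathways, 46 signal metabolites in one
sub-pathway.  Identical seeds give bit-identical cohorts and output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import PathwayAnnotation
from .preprocess import MetabolomeMatrix

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SyntheticCohort", "generate_annotation", "generate_cohort",
           "write_cohort", "read_cohort"]

SEASON_OF_MONTH = {12: "winter", 1: "winter", 2: "winter",
                   3: "spring", 4: "spring", 5: "spring",
                   6: "summer", 7: "summer", 8: "summer",
                   9: "fall", 10: "fall", 11: "fall"}

# 25(OH)D generating constants (nmol/L), anchored to the discovery cohort's
# printed postpartum distribution (mean ~88, SD ~36, high-dose shift ~33).
VITD_BASELINE = 88.0
VITD_LATENT_LOADING = 15.0
VITD_SEASON_AMP = 10.0
VITD_SMOKING_SHIFT = -8.0
VITD_RESID_SD = 15.0

# baseline hazard: ~30% cumulative event incidence by 3 years when L = 0
BASE_HAZARD = -np.log(0.7) / 3.0


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort draw.

    Effects are on standardized scales: ``exposure_loading`` is the shift in
    log-intensity of each signal metabolite per SD of the latent axis;
    ``outcome_loghazard``, ``count_lograte``, ``binary_logodds`` and
    ``linear_beta`` are per-SD effects of the latent axis on the respective
    outcome families.  ``dose_effect`` is the mean 25(OH)D increment (nmol/L)
    in the high-dose arm.
    """

    n_mothers: int = 672
    n_metabolites: int = 753
    n_subpathways: int = 60
    signal_subpathway: str = "SUB_01"
    n_signal_metabolites: int = 46
    exposure_loading: float = 0.5
    dose_effect: float = 33.0
    outcome_loghazard: float = -0.35
    count_lograte: float = -0.15
    binary_logodds: float = -0.25
    linear_beta: float = 0.2
    noise_sd: float = 1.0
    missing_frac: float = 0.05
    censor_time: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mothers", "n_metabolites", "n_subpathways", "n_signal_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_signal_metabolites > self.n_metabolites:
            raise ValueError("n_signal_metabolites exceeds n_metabolites")
        if self.n_subpathways > self.n_metabolites:
            raise ValueError("n_subpathways exceeds n_metabolites")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth planted into it."""

    metabolome: MetabolomeMatrix
    annotation: PathwayAnnotation
    phenotypes: pd.DataFrame
    truth: dict


def generate_annotation(
    n_metabolites: int,
    n_subpathways: int,
    seed: int,
    *,
    n_superpathways: int = 9,
    reserve: tuple[str, int] | None = None,
) -> PathwayAnnotation:
    """Random partition of metabolites into non-empty sub-pathways.

    Every metabolite is assigned exactly one sub-pathway; sub-pathways are
    cycled across ``n_superpathways`` super-pathways.  ``reserve`` pins a
    named sub-pathway to an exact member count (used to plant a signal
    block); the remaining metabolites are spread over the other sub-pathways
    with each guaranteed at least one member.
    """
    if n_metabolites <= 0 or n_subpathways <= 0:
        raise ValueError("counts must be positive")
    if n_subpathways > n_metabolites:
        raise ValueError("n_subpathways exceeds n_metabolites")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_metabolites)))
    met_ids = [f"MET_{i + 1:0{width}d}" for i in range(n_metabolites)]
    sub_ids = [f"SUB_{i + 1:02d}" for i in range(n_subpathways)]
    if reserve is not None:
        name, count = reserve
        if name not in sub_ids:
            raise ValueError(f"reserved sub-pathway {name!r} not among generated ids")
        if count < 1 or count > n_metabolites - (n_subpathways - 1):
            raise ValueError("reserved count leaves some sub-pathway empty")
    labels = np.empty(n_metabolites, dtype=object)
    order = rng.permutation(n_metabolites)
    pos = 0
    for sub in sub_ids:
        take = reserve[1] if (reserve is not None and sub == reserve[0]) else 1
        labels[order[pos:pos + take]] = sub
        pos += take
    if pos < n_metabolites:
        free_subs = [s for s in sub_ids if reserve is None or s != reserve[0]]
        labels[order[pos:]] = rng.choice(free_subs, size=n_metabolites - pos)
    super_of_sub = {sub: f"SUPER_{(i % n_superpathways) + 1}" for i, sub in enumerate(sub_ids)}
    table = pd.DataFrame(
        {"super_pathway": [super_of_sub[s] for s in labels], "sub_pathway": labels},
        index=pd.Index(met_ids, name="metabolite_id"),
    )
    return PathwayAnnotation(table)


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one cohort under ``config``; identical seeds are bit-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_mothers
    p = config.n_metabolites

    annotation = generate_annotation(
        p, config.n_subpathways, seed=config.seed,
        reserve=(config.signal_subpathway, config.n_signal_metabolites),
    )
    signal_ids = annotation.members(config.signal_subpathway)
    met_ids = list(annotation.metabolite_ids)
    signal_mask = np.isin(met_ids, signal_ids)

    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    latent = rng.standard_normal(n)

    arm = rng.integers(0, 2, size=n)                      # 1 = high-dose vitamin D
    pufa = rng.integers(0, 2, size=n)                     # factorial n-3 PUFA arm
    smoking = (rng.random(n) < 0.08).astype(int)          # third-trimester smoking
    sex = (rng.random(n) < 0.5).astype(int)               # 1 = male
    birth_month = rng.integers(1, 13, size=n)
    season = np.array([SEASON_OF_MONTH[m] for m in birth_month])
    breastfeeding_days = np.clip(rng.normal(150.0, 80.0, size=n), 0.0, None)
    daycare_start_age = np.clip(rng.normal(1.0, 0.25, size=n), 0.3, 3.0)
    g = rng.random(n)
    genotype = np.where(g < 0.4225, "GG", np.where(g < 0.8775, "CG", "CC"))

    vitd = (
        VITD_BASELINE
        + config.dose_effect * arm
        + VITD_LATENT_LOADING * latent
        + VITD_SEASON_AMP * np.cos(2 * np.pi * (birth_month - 7) / 12.0)
        + VITD_SMOKING_SHIFT * smoking
        + VITD_RESID_SD * rng.standard_normal(n)
    )
    child_vitd = 40.0 + 0.3 * vitd + 12.0 * rng.standard_normal(n)

    # log-normal metabolome: signal block loads on the latent axis
    baseline = rng.normal(10.0, 0.5, size=p)
    log_intensity = (
        baseline
        + np.outer(latent, config.exposure_loading * signal_mask)
        + config.noise_sd * rng.standard_normal((n, p))
    )
    intensity = np.exp(log_intensity)
    if config.missing_frac > 0:
        mask = rng.random((n, p)) < config.missing_frac
        intensity[mask] = np.nan
    data = pd.DataFrame(intensity, index=sample_ids, columns=met_ids)

    def _survival(lh: float) -> tuple[np.ndarray, np.ndarray]:
        rate = BASE_HAZARD * np.exp(lh * latent)
        t = rng.exponential(1.0 / rate)
        event = (t <= config.censor_time).astype(int)
        return np.minimum(t, config.censor_time), event

    rw_time, rw_event = _survival(config.outcome_loghazard)
    ex_time, ex_event = _survival(config.outcome_loghazard)

    def _count(intercept: float) -> np.ndarray:
        return rng.poisson(np.exp(intercept + config.count_lograte * latent))

    phen = pd.DataFrame(
        {
            "vitd": vitd,
            "child_vitd": child_vitd,
            "arm": arm,
            "pufa": pufa,
            "smoking": smoking,
            "sex": sex,
            "birth_month": birth_month,
            "season": season,
            "breastfeeding_days": breastfeeding_days,
            "daycare_start_age": daycare_start_age,
            "genotype17q21": genotype,
            "recurrent_wheeze_time": rw_time,
            "recurrent_wheeze_event": rw_event,
            "exacerbation_time": ex_time,
            "exacerbation_event": ex_event,
            "trols_count": _count(np.log(3.5)),
            "cold_count": _count(np.log(2.5)),
            "tonsillitis_count": _count(np.log(0.4)),
            "otitis_count": _count(np.log(0.6)),
            "croup_count": _count(np.log(0.3)),
            "lri_count": _count(np.log(0.5)),
            "sensitization": rng.binomial(
                1, 1.0 / (1.0 + np.exp(-(np.log(0.25 / 0.75) + config.binary_logodds * latent)))
            ),
            "fev1_z": config.linear_beta * latent + rng.standard_normal(n),
            "sraw_z": -config.linear_beta * latent + rng.standard_normal(n),
        },
        index=sample_ids,
    )

    truth = {
        "latent": latent.tolist(),
        "signal_metabolites": sorted(signal_ids),
        "signal_subpathway": config.signal_subpathway,
        "config": asdict(config),
    }
    metabolome = MetabolomeMatrix(data=data, state="raw", annotation=annotation)
    logger.info("generated cohort: %d mothers, %d metabolites (%d signal), seed=%d",
                n, p, len(signal_ids), config.seed)
    return SyntheticCohort(metabolome=metabolome, annotation=annotation,
                           phenotypes=phen, truth=truth)


_FILES = ("metabolome.tsv", "annotation.tsv", "phenotypes.tsv", "truth.json")


def write_cohort(cohort: SyntheticCohort, directory: str | Path,
                 overwrite: bool = False) -> dict[str, Path]:
    """Write the three delimited-text pipeline inputs plus the truth file.

    Refuses to clobber existing files unless ``overwrite`` is set.  Missing
    intensities are written as empty cells; the files round-trip losslessly
    through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / name for name in _FILES}
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite without overwrite=True: {existing}")
    cohort.metabolome.data.to_csv(paths["metabolome.tsv"], sep="\t", na_rep="")
    cohort.annotation.table.to_csv(paths["annotation.tsv"], sep="\t")
    cohort.phenotypes.to_csv(paths["phenotypes.tsv"], sep="\t")
    with open(paths["truth.json"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    data = pd.read_csv(directory / "metabolome.tsv", sep="\t", index_col="sample_id")
    annotation = PathwayAnnotation(
        pd.read_csv(directory / "annotation.tsv", sep="\t", index_col="metabolite_id"))
    phen = pd.read_csv(directory / "phenotypes.tsv", sep="\t", index_col="sample_id")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    metabolome = MetabolomeMatrix(data=data, state="raw", annotation=annotation)
    return SyntheticCohort(metabolome=metabolome, annotation=annotation,
                           phenotypes=phen, truth=truth)
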