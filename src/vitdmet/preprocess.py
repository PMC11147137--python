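"""Metabolome quality control, imputation, normalization, and exposure calibration.

The preprocessing contract is a fixed pipeline on the raw intensity matrix:

    qc_filter  ->  impute_halfmin  ->  log_zscore

after which each retained metabolite column is natural-log transformed and
standardized to mean 0, SD 1 (population SD, divisor n).  The 25(OH)D
exposure is "calibrated" before multivariate modelling: residualized by
ordinary least squares on design covariates (vitamin-D / PUFA intervention
arms, third-trimester smoking, offspring sex, season of birth) and recentred
at the grand mean, so the calibrated exposure is orthogonal to every
calibration covariate while staying on the nmol/L scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import PathwayAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolomeMatrix",
    "CalibratedExposure",
    "qc_filter",
    "impute_halfmin",
    "log_zscore",
    "calibrate_exposure",
]

#: allowed values of MetabolomeMatrix.state, in pipeline order
STATES = ("raw", "zscored")


@dataclass
class MetabolomeMatrix:
    """Samples x metabolites intensity grid with annotation linkage.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are metabolites; NaN marks a missing
        intensity.
    state : {"raw", "zscored"}
        Tracks whether the grid still holds raw positive intensities or has
        been log-transformed and standardized; guards against re-applying
        :func:`log_zscore`.
    annotation : PathwayAnnotation, optional
        Metabolite id -> (super-pathway, sub-pathway); pruned consistently by
        :func:`qc_filter`.
    """

    data: pd.DataFrame
    state: str = "raw"
    annotation: PathwayAnnotation | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.data.columns.has_duplicates or self.data.index.has_duplicates:
            raise ValueError("duplicate sample or metabolite identifiers")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def _with(self, data: pd.DataFrame, state: str | None = None,
              annotation: PathwayAnnotation | None = None) -> "MetabolomeMatrix":
        return MetabolomeMatrix(
            data=data,
            state=self.state if state is None else state,
            annotation=self.annotation if annotation is None else annotation,
        )


def qc_filter(matrix: MetabolomeMatrix, max_missing_frac: float = 0.20) -> MetabolomeMatrix:
    """Drop metabolites whose missing fraction exceeds ``max_missing_frac``.

    Retains exactly the metabolites with missing fraction <= threshold; the
    sample set is unchanged and the annotation is pruned to the survivors.
    The default threshold of 20% is a common untargeted-metabolomics
    convention.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = matrix.missing_mask.mean(axis=0)
    keep = frac.index[frac <= max_missing_frac]
    if len(keep) == 0:
        raise ValueError("QC filter removed every metabolite")
    dropped = matrix.n_metabolites - len(keep)
    if dropped:
        logger.warning("QC filter dropped %d/%d metabolites (missing > %.0f%%)",
                       dropped, matrix.n_metabolites, 100 * max_missing_frac)
    annot = matrix.annotation.subset(keep) if matrix.annotation is not None else None
    return matrix._with(matrix.data[keep], annotation=annot)


def impute_halfmin(matrix: MetabolomeMatrix) -> MetabolomeMatrix:
    """Replace each missing intensity by half the column's observed minimum.

    The half-minimum floor is the standard untargeted-metabolomics stand-in
    for below-detection-limit values; it requires the raw positive scale.
    """
    if matrix.state != "raw":
        raise ValueError("half-minimum imputation requires raw-scale intensities")
    data = matrix.data.copy()
    fully_missing = data.columns[data.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"cannot impute fully-missing metabolites: {list(fully_missing)[:5]}")
    fill = data.min(axis=0, skipna=True) / 2.0
    data = data.fillna(fill)
    return matrix._with(data)


def log_zscore(matrix: MetabolomeMatrix) -> MetabolomeMatrix:
    """Natural-log transform then per-metabolite z-score (mean 0, SD 1).

    Uses the population SD (divisor n).  Columns that are constant after
    imputation carry no information and are dropped with a warning rather
    than aborting the run.  Already-standardized input is rejected via the
    state flag.

    Raises
    ------
    ValueError
        If the matrix is not raw-scale, still has missing values, or
        contains a non-positive intensity (the offending metabolite and
        sample are named).
    """
    if matrix.state != "raw":
        raise ValueError("log_zscore already applied (state flag is %r)" % matrix.state)
    if matrix.missing_mask.to_numpy().any():
        raise ValueError("log_zscore requires an imputed matrix without missing values")
    vals = matrix.values()
    bad = np.argwhere(vals <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity for metabolite {matrix.metabolite_ids[j]!r} "
            f"in sample {matrix.sample_ids[i]!r}"
        )
    logged = np.log(vals)
    sd = logged.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        names = list(matrix.metabolite_ids[constant])
        warnings.warn(f"dropping {len(names)} constant metabolite column(s): {names[:5]}")
        logger.warning("dropping constant metabolite columns: %s", names[:5])
    keep = ~constant
    z = (logged[:, keep] - logged[:, keep].mean(axis=0)) / sd[keep]
    data = pd.DataFrame(z, index=matrix.sample_ids, columns=matrix.metabolite_ids[keep])
    annot = (matrix.annotation.subset(data.columns)
             if matrix.annotation is not None else None)
    return MetabolomeMatrix(data=data, state="zscored", annotation=annot)


@dataclass
class CalibratedExposure:
    """Residualized exposure, recentred at the grand mean of the raw values.

    ``calibrated`` is orthogonal to every calibration design column and has
    the same mean as ``raw`` (complete cases only).
    """

    sample_ids: pd.Index
    raw: pd.Series
    calibrated: pd.Series
    covariates: list[str] = field(default_factory=list)


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns + treatment-coded dummies for categoricals."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            parts.append(s.astype(float))
        elif pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank growth
        aliased, r = [], 0
        for j, name in enumerate(design.columns):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                aliased.append(name)
            r = rj
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def calibrate_exposure(raw: pd.Series, covariates: pd.DataFrame) -> CalibratedExposure:
    """Residualize the exposure on covariates, recentred at the grand mean.

    OLS residuals of ``raw`` on an intercept plus the covariate design, plus
    the mean of ``raw``.  Rows with a missing exposure or covariate are
    dropped (complete-case) with a log message.  Calibrating an
    already-calibrated exposure with the same covariates is a no-op.
    """
    df = pd.concat([raw.rename("_raw"), covariates], axis=1)
    complete = df.dropna()
    n_drop = len(df) - len(complete)
    if n_drop:
        logger.warning("calibration: dropped %d incomplete case(s)", n_drop)
    if complete.empty:
        raise ValueError("no complete cases for exposure calibration")
    y = complete["_raw"].astype(float)
    design = _design_matrix(complete[covariates.columns])
    _check_full_rank(design)
    X = design.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - X @ beta
    calibrated = pd.Series(resid + y.mean(), index=complete.index, name="calibrated")
    return CalibratedExposure(
        sample_ids=complete.index,
        raw=y.rename(raw.name or "raw"),
        calibrated=calibrated,
        covariates=list(covariates.columns),
    )
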