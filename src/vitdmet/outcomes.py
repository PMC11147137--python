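"""Clinical outcome association battery and baseline-table tests.

One exposure (a PC score, a single metabolite z-score, or calibrated
25(OH)D) is related to one child outcome per model, with covariate
adjustment:

* time-to-event outcomes (age at onset of recurrent wheeze, persistent
  wheeze/asthma, exacerbations): Cox proportional hazards with Efron tie
  handling, reported as a hazard ratio (HR) per unit exposure;
* episode counts (troublesome lung symptoms, infections): quasi-Poisson
  regression — a log-link Poisson mean model with dispersion phi estimated
  by Pearson chi-squared / df and phi-scaled Wald intervals — reported as
  an incidence rate ratio (IRR);
* binary outcomes (allergic sensitization): logistic regression, odds
  ratio (OR);
* continuous outcomes (FEV1, specific airway resistance): linear
  regression on the z-scored outcome, beta per unit exposure.

Ratio-scale 95% CIs are Wald constructions exp(log-estimate +/- z * SE)
with z = Phi^{-1}(0.975).  The battery can be stratified by 17q21
rs12936231 genotype (GG is the low-risk group).  Group-difference tests
for baseline tables (Welch t from summary statistics, Pearson chi-squared
with optional Yates correction) live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .enrichment import bh_adjust
from .preprocess import MetabolomeMatrix, _design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult", "fit_cox", "fit_quasipoisson", "fit_logistic",
    "fit_linear", "stratified_battery", "univariate_screen",
    "welch_t", "chisq_contingency",
]

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class AssociationResult:
    """Effect estimate with Wald 95% CI for one exposure-outcome pair."""

    exposure: str
    outcome: str
    family: str                    # cox | quasipoisson | logistic | linear
    estimate: float                # HR / IRR / OR on ratio scale, beta for linear
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    stratum: str = "all"
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "family": self.family, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n": self.n, "stratum": self.stratum,
            "note": self.note,
        }


def _complete(data: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    sub = data[list(cols)]
    out = sub.dropna()
    if len(out) < len(sub):
        logger.info("dropped %d incomplete case(s) of %d", len(sub) - len(out), len(sub))
    return out


def _covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric covariate columns (categoricals dummy-coded), no intercept."""
    if not covariates:
        return pd.DataFrame(index=df.index)
    return _design_matrix(df[list(covariates)]).drop(columns="intercept")


def fit_cox(data: pd.DataFrame, time: str, event: str, exposure: str,
            covariates: Sequence[str] = (), stratum: str = "all") -> AssociationResult:
    """Cox proportional-hazards HR per unit exposure (Efron tie handling)."""
    df = _complete(data, [time, event, exposure, *covariates])
    n_events = int(df[event].sum())
    if n_events == 0:
        raise ValueError(f"degenerate outcome: no events for {event!r}")
    note = ""
    if n_events < 10:
        note = "low_events"
        logger.warning("only %d events for %s; estimate is low-powered", n_events, event)
    design = _covariate_design(df, covariates)
    frame = pd.concat(
        [df[[time, event]], df[[exposure]].astype(float), design], axis=1)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(frame, duration_col=time, event_col=event)
        for w in caught:
            logger.info("cox fit (%s ~ %s): %s", event, exposure,
                        str(w.message).splitlines()[0])
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed for {exposure!r} vs {event!r}: {exc}") from exc
    coef = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    p = 2.0 * float(stats.norm.sf(abs(coef / se)))
    return AssociationResult(
        exposure=exposure, outcome=event, family="cox",
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z975 * se)),
        ci_high=float(np.exp(coef + Z975 * se)),
        p_value=p, n=len(df), stratum=stratum, note=note,
    )


def _glm_ratio(df: pd.DataFrame, outcome: str, exposure: str,
               covariates: Sequence[str], family, scale=None):
    design = _covariate_design(df, covariates)
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="intercept"),
         df[[exposure]].astype(float), design], axis=1)
    model = sm.GLM(df[outcome].astype(float), X.astype(float), family=family)
    res = model.fit(scale=scale) if scale else model.fit()
    coef = float(res.params[exposure])
    se = float(res.bse[exposure])
    return res, coef, se


def fit_quasipoisson(data: pd.DataFrame, count: str, exposure: str,
                     covariates: Sequence[str] = (),
                     stratum: str = "all") -> AssociationResult:
    """Quasi-Poisson IRR per unit exposure with dispersion-scaled Wald CI."""
    df = _complete(data, [count, exposure, *covariates])
    y = df[count]
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if (y == 0).all():
        raise ValueError(f"degenerate outcome: all-zero counts for {count!r}")
    res, coef, se = _glm_ratio(df, count, exposure, covariates,
                               sm.families.Poisson(), scale="X2")
    p = 2.0 * float(stats.norm.sf(abs(coef / se)))
    return AssociationResult(
        exposure=exposure, outcome=count, family="quasipoisson",
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z975 * se)),
        ci_high=float(np.exp(coef + Z975 * se)),
        p_value=p, n=len(df), stratum=stratum,
        note=f"dispersion={float(res.scale):.3f}",
    )


def fit_logistic(data: pd.DataFrame, outcome: str, exposure: str,
                 covariates: Sequence[str] = (),
                 stratum: str = "all") -> AssociationResult:
    """Logistic-regression OR per unit exposure with Wald 95% CI."""
    df = _complete(data, [outcome, exposure, *covariates])
    y = df[outcome]
    if y.nunique() < 2:
        raise ValueError(f"degenerate outcome: single class for {outcome!r}")
    res, coef, se = _glm_ratio(df, outcome, exposure, covariates,
                               sm.families.Binomial())
    note = ""
    if abs(coef) > 15 or not np.isfinite(se):
        note = "separation"
        warnings.warn(
            f"possible separation fitting {outcome!r} on {exposure!r}; "
            "consider a penalized refit")
    p = 2.0 * float(stats.norm.sf(abs(coef / se)))
    return AssociationResult(
        exposure=exposure, outcome=outcome, family="logistic",
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z975 * se)),
        ci_high=float(np.exp(coef + Z975 * se)),
        p_value=p, n=len(df), stratum=stratum, note=note,
    )


def fit_linear(data: pd.DataFrame, outcome: str, exposure: str,
               covariates: Sequence[str] = (), stratum: str = "all",
               standardize_outcome: bool = True) -> AssociationResult:
    """Linear-regression beta per unit exposure on the z-scored outcome."""
    df = _complete(data, [outcome, exposure, *covariates])
    y = df[outcome].astype(float)
    sd = y.std(ddof=0)
    if sd == 0:
        raise ValueError(f"degenerate outcome: zero variance for {outcome!r}")
    if standardize_outcome:
        y = (y - y.mean()) / sd
    design = _covariate_design(df, covariates)
    X = pd.concat(
        [pd.Series(1.0, index=df.index, name="intercept"),
         df[[exposure]].astype(float), design], axis=1).astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"aliased design fitting {outcome!r}: rank {rank} < {X.shape[1]} columns")
    res = sm.OLS(y, X).fit()
    coef = float(res.params[exposure])
    lo, hi = res.conf_int().loc[exposure]
    return AssociationResult(
        exposure=exposure, outcome=outcome, family="linear",
        estimate=coef, ci_low=float(lo), ci_high=float(hi),
        p_value=float(res.pvalues[exposure]), n=len(df), stratum=stratum,
    )


_FITTERS: Mapping[str, Callable[..., AssociationResult]] = {
    "cox": fit_cox,
    "quasipoisson": fit_quasipoisson,
    "logistic": fit_logistic,
    "linear": fit_linear,
}


def stratified_battery(data: pd.DataFrame, family: str, strata: str,
                       pool: Mapping[str, str] | None = None,
                       **fit_kwargs) -> list[AssociationResult]:
    """Refit one model family within each stratum of ``strata``.

    ``pool`` optionally maps raw stratum labels to pooled ones (e.g.
    {"CG": "CG/CC", "CC": "CG/CC"} to contrast GG against carriers).
    Strata whose fit is degenerate yield a flagged placeholder result with
    NaN estimates; the remaining strata are still returned.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    labels = data[strata].astype(str)
    if pool:
        labels = labels.replace(dict(pool))
    results: list[AssociationResult] = []
    for level in sorted(labels.dropna().unique()):
        sub = data.loc[labels == level]
        try:
            results.append(_FITTERS[family](sub, stratum=level, **fit_kwargs))
        except ValueError as exc:
            logger.warning("stratum %s degenerate: %s", level, exc)
            results.append(AssociationResult(
                exposure=fit_kwargs.get("exposure", "?"),
                outcome=fit_kwargs.get("event") or fit_kwargs.get("count")
                or fit_kwargs.get("outcome", "?"),
                family=family, estimate=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), p_value=float("nan"), n=len(sub),
                stratum=level, note="degenerate"))
    return results


def univariate_screen(matrix: MetabolomeMatrix | pd.DataFrame, target: pd.Series,
                      covariates: pd.DataFrame | None = None,
                      family: str = "linear",
                      metabolite_as_response: bool = True) -> pd.DataFrame:
    """Per-metabolite regression screen with BH FDR across metabolites.

    ``family="linear"``: each (z-scored) metabolite is regressed on the
    continuous target (metabolite as response by default; set
    ``metabolite_as_response=False`` to regress the target on each
    metabolite instead).  ``family="logistic"``: the binary target is
    regressed on each metabolite plus covariates, as in the dose-arm screen.

    Returns a volcano-ready table indexed by metabolite id with columns
    ``estimate`` (per-SD effect), ``se``, ``p_value``, ``q_value`` and
    ``neg_log10_p``.  Metabolites whose fit fails are logged, reported with
    NaN, and excluded from the BH family size.
    """
    if isinstance(matrix, MetabolomeMatrix):
        if matrix.state != "zscored":
            raise ValueError("univariate screen requires a z-scored matrix")
        Ydf = matrix.data
    else:
        Ydf = matrix
    idx = Ydf.index.intersection(target.dropna().index)
    if covariates is not None:
        idx = idx.intersection(covariates.dropna().index)
    Ydf = Ydf.loc[idx]
    t = target.loc[idx].astype(float)
    cov = covariates.loc[idx] if covariates is not None else None

    if family == "linear":
        out = _linear_screen(Ydf, t, cov, metabolite_as_response)
    elif family == "logistic":
        out = _logistic_screen(Ydf, t, cov)
    else:
        raise ValueError(f"unknown family {family!r}")
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = bh_adjust(out.loc[ok, "p_value"].to_numpy())
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out


def _linear_screen(Y: pd.DataFrame, target: pd.Series,
                   covariates: pd.DataFrame | None,
                   metabolite_as_response: bool) -> pd.DataFrame:
    base = pd.DataFrame({"intercept": 1.0, "target": target})
    if covariates is not None and len(covariates.columns):
        base = pd.concat([base, _covariate_design(covariates.assign(), list(covariates.columns))],
                         axis=1)
    D = base.to_numpy(dtype=float)
    n, q = D.shape
    j = 1  # target column position
    if metabolite_as_response:
        # multi-response OLS: every metabolite on the same design
        Ymat = Y.to_numpy(dtype=float)
        B, *_ = np.linalg.lstsq(D, Ymat, rcond=None)
        resid = Ymat - D @ B
        dof = n - np.linalg.matrix_rank(D)
        sigma2 = (resid ** 2).sum(axis=0) / dof
        h = np.linalg.inv(D.T @ D)[j, j]
        est = B[j]
        se = np.sqrt(sigma2 * h)
        tstat = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        return pd.DataFrame({"estimate": est, "se": se, "p_value": p}, index=Y.columns)
    rows = []
    for met in Y.columns:
        Dm = np.column_stack([D[:, :1], Y[met].to_numpy(float), D[:, 2:] if q > 2 else np.empty((n, 0))])
        tm = target.to_numpy(float)
        B, *_ = np.linalg.lstsq(Dm, tm, rcond=None)
        resid = tm - Dm @ B
        dof = n - np.linalg.matrix_rank(Dm)
        sigma2 = float((resid ** 2).sum()) / dof
        se = float(np.sqrt(sigma2 * np.linalg.inv(Dm.T @ Dm)[1, 1]))
        tt = B[1] / se if se > 0 else np.nan
        rows.append((float(B[1]), se, 2.0 * float(stats.t.sf(abs(tt), dof))))
    return pd.DataFrame(rows, columns=["estimate", "se", "p_value"], index=Y.columns)


def _logistic_screen(Y: pd.DataFrame, target: pd.Series,
                     covariates: pd.DataFrame | None) -> pd.DataFrame:
    if target.nunique() != 2:
        raise ValueError("logistic screen requires a binary target")
    tbin = (target == sorted(target.unique())[1]).astype(float)
    cov_design = (_covariate_design(covariates, list(covariates.columns))
                  if covariates is not None and len(covariates.columns)
                  else pd.DataFrame(index=Y.index))
    rows = []
    for met in Y.columns:
        X = pd.concat([pd.Series(1.0, index=Y.index, name="intercept"),
                       Y[met].astype(float), cov_design], axis=1).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(tbin, X, family=sm.families.Binomial()).fit()
            coef = float(res.params[met])
            se = float(res.bse[met])
            if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 15:
                raise RuntimeError("separation / non-finite fit")
            p = 2.0 * float(stats.norm.sf(abs(coef / se)))
            rows.append((coef, se, p))
        except Exception as exc:
            logger.warning("logistic screen failed for %s: %s", met, exc)
            rows.append((np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["estimate", "se", "p_value"], index=Y.columns)


def welch_t(mean1: float, sd1: float, n1: int,
            mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Welch unequal-variance t test from summary statistics.

    Satterthwaite degrees of freedom; returns (t, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chisq_contingency(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a counts grid.

    ``yates`` applies the continuity correction (2x2 tables only, where
    df = 1).  Returns (chi2, df, two-sided p).
    """
    tab = np.asarray(table)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need a grid with at least 2 rows and 2 columns")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column marginal")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=yates)
    return float(chi2), int(df), float(p)
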