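"""Orthogonal projections to latent structures (OPLS / OPLS-DA), VIP, PCA.

OPLS splits metabolome variation into a single component predictive of a
continuous target (here: calibrated 25(OH)D) and components orthogonal to
it, following the orthogonal-deflation scheme: the predictive weight
``w`` is the (normalized) covariance direction X'y; each orthogonal
component removes from X the part of the current X-loading that is
orthogonal to ``w``.  By construction every orthogonal score is exactly
uncorrelated with the target, and the y-predictions of an OPLS model with
one predictive and k orthogonal components coincide with those of a
(k+1)-component NIPALS PLS regression.

The discriminant variant (OPLS-DA) encodes a two-class label as a centred
+/-1 dummy and delegates to the regression fit.

Variable influence on projection (VIP) summarizes each metabolite's
contribution to the predictive component; with a single predictive
component VIP_j = sqrt(p) * |w_j|, so the mean squared VIP is exactly 1.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn model selection; the PCA used for score construction is sklearn's,
wrapped with a deterministic sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.decomposition import PCA as _SkPCA
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = ["OPLS", "OPLSDA", "PcaModel", "fit_pca", "vip_scores", "select_vip"]


def _opls_core(X: np.ndarray, y: np.ndarray, n_ortho: int) -> dict:
    """Orthogonal-deflation OPLS on pre-centred arrays.

    Returns the predictive weight/score/loading, per-level y-loadings
    ``q_levels`` (q_levels[k] predicts y after removing k orthogonal
    components — the levels are nested, so one fit serves all smaller
    component counts), and the orthogonal weight/score/loading sets.
    """
    n, p = X.shape
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho > min(n, p) - 1:
        raise ValueError(f"n_ortho={n_ortho} exceeds what rank min(n,p)={min(n, p)} supports")
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw <= 0 or not np.isfinite(nw):
        raise ValueError("degenerate fit: X'y is zero (constant y or X?)")
    w = w / nw
    Xd = X.copy()
    Wo, Po, To, q_levels = [], [], [], []
    for k in range(n_ortho + 1):
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 1e-300:
            raise np.linalg.LinAlgError("predictive score collapsed; rank too low")
        q_levels.append(float(y @ t) / tt)
        if k == n_ortho:
            break
        p_load = Xd.T @ t / tt
        wo = p_load - float(w @ p_load) * w
        nrm = np.linalg.norm(wo)
        if nrm <= 1e-12 * np.linalg.norm(p_load) or nrm == 0.0:
            raise np.linalg.LinAlgError(
                f"only {k} orthogonal component(s) extractable; requested {n_ortho}")
        wo = wo / nrm
        to = Xd @ wo
        po = Xd.T @ to / float(to @ to)
        Xd = Xd - np.outer(to, po)
        Wo.append(wo)
        Po.append(po)
        To.append(to)
    t = Xd @ w
    tt = float(t @ t)
    p_load = Xd.T @ t / tt
    return {
        "w": w, "t": t, "p": p_load, "q": q_levels[-1], "q_levels": q_levels,
        "Wo": np.array(Wo).reshape(len(Wo), p),
        "Po": np.array(Po).reshape(len(Po), p),
        "To": np.array(To).reshape(len(To), n),
        "E": Xd - np.outer(t, p_load),
    }


def _core_predict(core: dict, Xc: np.ndarray, n_ortho: int | None = None) -> np.ndarray:
    """Predict centred y from centred X using a fitted core at a given level."""
    k = len(core["Wo"]) if n_ortho is None else n_ortho
    Xd = Xc
    for j in range(k):
        to = Xd @ core["Wo"][j]
        Xd = Xd - np.outer(to, core["Po"][j])
    return (Xd @ core["w"]) * core["q_levels"][k]


def _flip_sign(loading: np.ndarray) -> float:
    """-1 if the largest-magnitude loading entry is negative, else +1."""
    j = int(np.argmax(np.abs(loading)))
    return -1.0 if loading[j] < 0 else 1.0


class OPLS(RegressorMixin, BaseEstimator):
    """OPLS regression: one predictive + ``n_ortho`` orthogonal components.

    Parameters
    ----------
    n_ortho : int, default 1
        Number of orthogonal (y-uncorrelated) components to remove before
        the final predictive component.

    Attributes
    ----------
    predictive_weights_ : ndarray of shape (p,)
        Unit-norm predictive weight vector ``w``.
    predictive_scores_ : ndarray of shape (n,)
    predictive_loadings_ : ndarray of shape (p,)
    y_loading_ : float
    orthogonal_weights_, orthogonal_loadings_ : ndarray (n_ortho, p)
    orthogonal_scores_ : ndarray (n, n_ortho)
    r2x_, r2y_ : float
        Fractions of X- and y-variance captured by the model.

    Components are oriented so the largest-magnitude loading entry of each
    score/loading pair is positive, which removes the sign ambiguity.
    """

    def __init__(self, n_ortho: int = 1):
        self.n_ortho = n_ortho

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("y is constant; OPLS requires a non-constant target")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        core = _opls_core(Xc, yc, self.n_ortho)

        s = _flip_sign(core["p"])
        core["w"] *= s
        core["t"] *= s
        core["p"] *= s
        core["q"] *= s
        core["q_levels"] = [q * s for q in core["q_levels"]]
        for j in range(len(core["Wo"])):
            so = _flip_sign(core["Po"][j])
            core["Wo"][j] *= so
            core["Po"][j] *= so
            core["To"][j] *= so
        self._core = core

        self.predictive_weights_ = core["w"]
        self.predictive_scores_ = core["t"]
        self.predictive_loadings_ = core["p"]
        self.y_loading_ = core["q"]
        self.orthogonal_weights_ = core["Wo"]
        self.orthogonal_loadings_ = core["Po"]
        self.orthogonal_scores_ = (core["To"].T if core["To"].size
                                   else np.empty((X.shape[0], 0)))
        self.n_ortho_ = len(core["Wo"])
        ssx = float((Xc ** 2).sum())
        self.r2x_ = 1.0 - float((core["E"] ** 2).sum()) / ssx if ssx > 0 else 0.0
        ssy = float((yc ** 2).sum())
        resid = yc - core["t"] * core["q"]
        self.r2y_ = 1.0 - float((resid ** 2).sum()) / ssy
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, n_ortho: int | None = None):
        check_is_fitted(self, "predictive_weights_")
        X = check_array(X, dtype=float)
        Xc = X - self.x_mean_
        return _core_predict(self._core, Xc, n_ortho) + self.y_mean_

    def transform(self, X):
        """Project new samples: (predictive score, orthogonal scores)."""
        check_is_fitted(self, "predictive_weights_")
        X = check_array(X, dtype=float)
        Xd = X - self.x_mean_
        T_o = np.empty((X.shape[0], self.n_ortho_))
        for j in range(self.n_ortho_):
            to = Xd @ self._core["Wo"][j]
            T_o[:, j] = to
            Xd = Xd - np.outer(to, self._core["Po"][j])
        return Xd @ self._core["w"], T_o


class OPLSDA(ClassifierMixin, BaseEstimator):
    """OPLS discriminant analysis for a two-class label.

    Encodes the classes as a centred +/-1 dummy and delegates to
    :class:`OPLS`; class separation is read from the predictive scores.
    ``decision_function`` returns the continuous prediction on the dummy
    scale; ``predict`` assigns the nearer class code.
    """

    def __init__(self, n_ortho: int = 1):
        self.n_ortho = n_ortho

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA requires exactly two classes, got {len(classes)}")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")
        self.classes_ = classes
        dummy = np.where(y == classes[1], 1.0, -1.0)
        self._opls = OPLS(n_ortho=self.n_ortho).fit(X, dummy)
        for attr in ("predictive_weights_", "predictive_scores_", "predictive_loadings_",
                     "y_loading_", "orthogonal_weights_", "orthogonal_loadings_",
                     "orthogonal_scores_", "n_ortho_", "r2x_", "r2y_"):
            setattr(self, attr, getattr(self._opls, attr))
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        return self._opls.predict(X)

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def vip_scores(model: OPLS | OPLSDA,
               metabolite_ids: Sequence[str] | None = None) -> pd.Series:
    """Variable influence on projection toward the predictive component(s).

    VIP_j = sqrt(p * sum_a(w_aj^2 SSY_a) / sum_a SSY_a); with the single
    predictive component fitted here this reduces to sqrt(p) * |w_j|, and
    the mean squared VIP is exactly 1.
    """
    check_is_fitted(model, "predictive_weights_")
    w = np.atleast_2d(model.predictive_weights_)           # (a, p)
    t = np.atleast_2d(model.predictive_scores_)            # (a, n)
    q = np.atleast_1d(model.y_loading_)
    ssy = (t ** 2).sum(axis=1) * q ** 2                    # y-variance per component
    p = w.shape[1]
    vip = np.sqrt(p * (w ** 2 * ssy[:, None]).sum(axis=0) / ssy.sum())
    if metabolite_ids is None:
        metabolite_ids = [f"x{j}" for j in range(p)]
    return pd.Series(vip, index=pd.Index(metabolite_ids, name="metabolite_id"), name="vip")


def select_vip(vip: pd.Series, threshold: float = 2.0) -> list[str]:
    """Metabolites with VIP strictly greater than ``threshold``, descending.

    An empty selection is allowed (and logged); a threshold of 2 on VIP
    toward the predictive component is the key-metabolite criterion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    hits = vip[vip > threshold]
    out = hits.sort_values(ascending=False, kind="mergesort").index.tolist()
    if not out:
        logger.warning("VIP selection at threshold %.3g is empty", threshold)
    return out


@dataclass
class PcaModel:
    """PCA scores/loadings with a deterministic sign convention.

    ``loadings`` are orthonormal right-singular directions of the centred
    matrix (p x k); ``scores`` = centred data @ loadings;
    ``explained_variance_fraction`` is non-increasing.  Each component is
    oriented so its largest-magnitude loading entry is positive.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    mean_: np.ndarray

    def project(self, X: pd.DataFrame) -> pd.DataFrame:
        """Scores of new samples in this model's component space."""
        Xc = np.asarray(X, dtype=float) - self.mean_
        return pd.DataFrame(Xc @ self.loadings.to_numpy(),
                            index=getattr(X, "index", None),
                            columns=self.scores.columns)


def fit_pca(X, n_components: int) -> PcaModel:
    """Principal component analysis of a (z-scored) metabolite matrix.

    Thin wrapper over sklearn's full-SVD PCA adding id-carrying frames and
    the sign convention.  ``n_components`` must not exceed
    min(n_samples - 1, n_features).
    """
    idx = getattr(X, "index", None)
    cols = getattr(X, "columns", None)
    A = check_array(X, dtype=float)
    n, p = A.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    sk = _SkPCA(n_components=n_components, svd_solver="full").fit(A)
    load = sk.components_.T.copy()                        # p x k
    scores = (A - sk.mean_) @ load
    for j in range(n_components):
        s = _flip_sign(load[:, j])
        load[:, j] *= s
        scores[:, j] *= s
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    if cols is None:
        cols = [f"x{j}" for j in range(p)]
    if idx is None:
        idx = pd.RangeIndex(n)
    return PcaModel(
        loadings=pd.DataFrame(load, index=cols, columns=comp_names),
        scores=pd.DataFrame(scores, index=idx, columns=comp_names),
        explained_variance_fraction=sk.explained_variance_ratio_.copy(),
        mean_=sk.mean_,
    )
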