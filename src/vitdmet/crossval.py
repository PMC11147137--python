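"""Double cross-validation and permutation testing for OPLS models.

The predictive ability Q2 = 1 - PRESS/SS is estimated by a double
(nested) cross-validation: an outer 10-fold split provides held-out
predictions, while an inner cross-validation on each outer training set
selects the number of orthogonal components (ties broken toward the
smaller count).  SS is taken about the training-fold mean of y.  Model
significance is assessed by permuting y and recomputing Q2 with the
identical double-CV scheme and fold partition; the permutation p-value is
(1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1).

Three structural facts keep the permutation loop fast: the orthogonal
deflation is nested, so one pass at the maximal component count yields
held-out predictions at every smaller count; permuting y leaves X and the
fold partition untouched, so the centred X blocks of every fold are
computed once; and the whole fit is linear algebra in y, so a block of
permuted targets is processed together through batched matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = ["CvResult", "PermutationResult", "double_cv", "permutation_test",
           "select_n_ortho"]

#: cap on the extra memory (bytes) the batched permutation path may hold
_BATCH_BYTES = 2 * 10 ** 8


@dataclass
class CvResult:
    """Pooled out-of-fold predictive summary of a double cross-validation."""

    q2: float
    r2y_train_mean: float
    chosen_n_ortho: list[int]
    press: float
    ss: float
    seed: int


@dataclass
class PermutationResult:
    """Observed vs permuted Q2 with the one-sided permutation p-value."""

    observed_q2: float
    permuted_q2: np.ndarray
    p_value: float
    n_perm: int


def _check_folds(n: int, n_folds: int) -> None:
    if n_folds > n:
        raise ValueError(f"{n_folds} folds exceed {n} samples")
    if n // n_folds < 2:
        raise ValueError(f"{n_folds}-fold split of {n} samples leaves folds with < 2 samples")


class _FoldFit:
    """Centred train/test X blocks of one fold, reusable across targets."""

    __slots__ = ("tr", "te", "Xtr_c", "Xte_c")

    def __init__(self, X: np.ndarray, tr: np.ndarray, te: np.ndarray):
        self.tr = tr
        self.te = te
        xm = X[tr].mean(axis=0)
        self.Xtr_c = np.ascontiguousarray(X[tr] - xm)
        self.Xte_c = np.ascontiguousarray(X[te] - xm)

    def press_by_level(self, Y: np.ndarray, max_ortho: int,
                       train_resid: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Held-out PRESS at every orthogonal level for a block of targets.

        ``Y`` has one candidate target per column (shape (n, B)); returns
        ``press`` of shape (max_ortho + 1, B) and ``ss`` of shape (B,),
        both about the training-fold mean of each target.  One lockstep
        deflation of the training and test matrices serves every level; a
        column whose deflation collapses early keeps its deepest level for
        the larger counts.  ``train_resid`` (same shape as ``press``), when
        given, receives the training residual y-variance fraction.
        """
        ytr = Y[self.tr]
        ym = ytr.mean(axis=0)
        yc = ytr - ym                                        # (ntr, B)
        yte_c = Y[self.te] - ym                              # (nte, B)
        ss = (yte_c ** 2).sum(axis=0)
        B = Y.shape[1]
        K = max_ortho
        press = np.empty((K + 1, B))

        W = (self.Xtr_c.T @ yc).T                            # (B, p)
        nw = np.linalg.norm(W, axis=1)
        alive = nw > 0
        W = W / np.where(alive, nw, 1.0)[:, None]
        W[~alive] = 0.0                                      # dead columns predict the mean
        frozen_press = ss.copy()                             # value carried once a column dies
        frozen_resid = np.ones(B)
        ssy = (yc ** 2).sum(axis=0)

        Xd = np.repeat(self.Xtr_c[None, :, :], B, axis=0)
        Xte_d = np.repeat(self.Xte_c[None, :, :], B, axis=0)
        ycb = np.ascontiguousarray(yc.T)
        yteb = np.ascontiguousarray(yte_c.T)
        for k in range(K + 1):
            t = (Xd @ W[:, :, None])[:, :, 0]                # (B, ntr)
            tt = (t * t).sum(axis=1)
            live = alive & (tt > 1e-300)
            safe_tt = np.where(live, tt, 1.0)
            q = np.where(live, (ycb * t).sum(axis=1) / safe_tt, 0.0)
            yhat = (Xte_d @ W[:, :, None])[:, :, 0] * q[:, None]
            pk = ((yteb - yhat) ** 2).sum(axis=1)
            press[k] = np.where(live, pk, frozen_press)
            if train_resid is not None:
                res = ((ycb - t * q[:, None]) ** 2).sum(axis=1) / np.where(ssy > 0, ssy, 1.0)
                train_resid[k] = np.where(live, res, frozen_resid)
                frozen_resid = train_resid[k]
            frozen_press = press[k]
            if k == K:
                break
            p_load = (Xd.transpose(0, 2, 1) @ t[:, :, None])[:, :, 0] / safe_tt[:, None]
            wo = p_load - (W * p_load).sum(axis=1)[:, None] * W
            nrm = np.linalg.norm(wo, axis=1)
            live = live & (nrm > 1e-12 * np.linalg.norm(p_load, axis=1)) & (nrm > 0)
            alive = live
            wo = wo / np.where(nrm > 0, nrm, 1.0)[:, None]
            wo[~live] = 0.0                                  # frozen columns stop deflating
            to = (Xd @ wo[:, :, None])[:, :, 0]
            tot = (to * to).sum(axis=1)
            po = (Xd.transpose(0, 2, 1) @ to[:, :, None])[:, :, 0] \
                / np.where(tot > 0, tot, 1.0)[:, None]
            Xd -= to[:, :, None] * po[:, None, :]
            Xte_d -= ((Xte_d @ wo[:, :, None])[:, :, 0])[:, :, None] * po[:, None, :]
        return press, ss


class _CvPlan:
    """Fold structure (outer folds, each with inner folds) for a fixed X."""

    def __init__(self, X: np.ndarray, outer_folds: int, inner_folds: int,
                 max_ortho: int, seed: int):
        n = X.shape[0]
        _check_folds(n, outer_folds)
        self.max_ortho = max_ortho
        self.n = n
        outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
        inner_state = seed + 1
        self.outer: list[tuple[_FoldFit, list[_FoldFit]]] = []
        for tr, te in outer.split(X):
            _check_folds(len(tr), inner_folds)
            inner = KFold(n_splits=inner_folds, shuffle=True, random_state=inner_state)
            inner_fits = [_FoldFit(X[tr], itr, ite) for itr, ite in inner.split(X[tr])]
            self.outer.append((_FoldFit(X, tr, te), inner_fits))
        self.seed = seed

    def run_block(self, Y: np.ndarray, collect: bool = False
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Double-CV for each target column: (q2, chosen per fold, mean train R2Y)."""
        B = Y.shape[1]
        K = self.max_ortho
        press_tot = np.zeros(B)
        ss_tot = np.zeros(B)
        chosen = np.empty((len(self.outer), B), dtype=int)
        r2y_sum = np.zeros(B)
        for f, (fold, inner_fits) in enumerate(self.outer):
            ytr = Y[fold.tr]
            press_k = np.zeros((K + 1, B))
            ss_k = np.zeros(B)
            for ifold in inner_fits:
                p, s = ifold.press_by_level(ytr, K)
                press_k += p
                ss_k += s
            q2_inner = 1.0 - press_k / ss_k                  # (K+1, B)
            best = q2_inner.max(axis=0)
            k_sel = (q2_inner >= best - 1e-12).argmax(axis=0)  # smallest index at max
            chosen[f] = k_sel
            train_resid = np.empty((K + 1, B)) if collect else None
            press_lvls, ss = fold.press_by_level(Y, K, train_resid)
            cols = np.arange(B)
            press_tot += press_lvls[k_sel, cols]
            ss_tot += ss
            if collect:
                r2y_sum += 1.0 - train_resid[k_sel, cols]
        q2 = 1.0 - press_tot / ss_tot
        return q2, chosen, r2y_sum / len(self.outer)

    def run(self, y: np.ndarray, collect: bool = False) -> CvResult:
        q2, chosen, r2y = self.run_block(y[:, None], collect=collect)
        # re-derive pooled PRESS/SS for the scalar report
        press_tot, ss_tot = self._pooled(y, chosen[:, 0])
        return CvResult(q2=float(q2[0]),
                        r2y_train_mean=float(r2y[0]) if collect else float("nan"),
                        chosen_n_ortho=chosen[:, 0].tolist(),
                        press=press_tot, ss=ss_tot, seed=self.seed)

    def _pooled(self, y: np.ndarray, chosen: np.ndarray) -> tuple[float, float]:
        press_tot = 0.0
        ss_tot = 0.0
        for f, (fold, _) in enumerate(self.outer):
            press_lvls, ss = fold.press_by_level(y[:, None], self.max_ortho)
            press_tot += float(press_lvls[chosen[f], 0])
            ss_tot += float(ss[0])
        return press_tot, ss_tot


def _pick_n_ortho(q2_by_k: np.ndarray, tol: float = 1e-12) -> int:
    """Smallest component count within ``tol`` of the maximal inner Q2."""
    best = float(np.max(q2_by_k))
    return int(np.flatnonzero(q2_by_k >= best - tol)[0])


def select_n_ortho(X, y, inner_folds: int = 7, max_ortho: int = 5,
                   seed: int = 0) -> int:
    """Choose the orthogonal component count by inner cross-validation."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_folds(len(y), inner_folds)
    inner = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    press = np.zeros(max_ortho + 1)
    ss = 0.0
    for tr, te in inner.split(X):
        fold = _FoldFit(X, tr, te)
        p, s = fold.press_by_level(y[:, None], max_ortho)
        press += p[:, 0]
        ss += float(s[0])
    return _pick_n_ortho(1.0 - press / ss)


def double_cv(X, y, outer_folds: int = 10, inner_folds: int = 7,
              max_ortho: int = 5, seed: int = 0) -> CvResult:
    """Nested cross-validated Q2 of an OPLS model.

    The outer loop provides ``outer_folds`` held-out predictions; on each
    outer training set an inner ``inner_folds``-fold CV picks the number of
    orthogonal components (0..``max_ortho``) maximizing inner Q2, the outer
    test fold is predicted once with that choice, and Q2 pools PRESS and SS
    (about the training-fold mean of y) over the outer folds.
    Deterministic given ``seed``.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    plan = _CvPlan(X, outer_folds, inner_folds, max_ortho, seed)
    return plan.run(y, collect=True)


def permutation_test(X, y, n_perm: int = 1000, seed: int = 0,
                     outer_folds: int = 10, inner_folds: int = 7,
                     max_ortho: int = 5) -> PermutationResult:
    """Permutation test of the double-CV Q2.

    y is permuted uniformly ``n_perm`` times; each permuted Q2 is computed
    with the identical double-CV scheme and fold seed (permuting y and
    holding the partition fixed is exchangeable under the null and halves
    the Monte-Carlo variance).  p = (1 + #{permuted >= observed}) /
    (n_perm + 1), so 1/(n_perm+1) <= p <= 1.  Permuted targets are
    evaluated in memory-capped blocks.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    plan = _CvPlan(X, outer_folds, inner_folds, max_ortho, seed)
    observed = plan.run(y).q2
    rng = np.random.default_rng(seed)
    Yperm = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    block = max(1, int(_BATCH_BYTES / (3 * 8 * X.shape[0] * X.shape[1])))
    permuted = np.empty(n_perm)
    for start in range(0, n_perm, block):
        stop = min(start + block, n_perm)
        permuted[start:stop], _, _ = plan.run_block(Yperm[:, start:stop])
    p = (1.0 + float(np.sum(permuted >= observed))) / (n_perm + 1.0)
    logger.info("permutation test: observed Q2=%.4f, p=%.4g (n_perm=%d)",
                observed, p, n_perm)
    return PermutationResult(observed_q2=observed, permuted_q2=permuted,
                             p_value=p, n_perm=n_perm)
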