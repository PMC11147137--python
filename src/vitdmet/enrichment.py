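"""Sub-pathway over-representation analysis of a selected metabolite set.

A selection of metabolites (e.g. those with VIP > 2 toward the predictive
component of an OPLS model) is tested for over-representation in each
biochemical sub-pathway using the upper-tail hypergeometric distribution,
with Benjamini–Hochberg control of the false discovery rate across
sub-pathways.  The "enriched factor" reported per sub-pathway is the
observed/expected ratio (k/n)/(K/N) for a pathway with K members in a
universe of N metabolites, of which n were selected and k fall in the
pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["PathwayAnnotation", "enrich_subpathways", "bh_adjust",
           "hypergeom_tail"]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail over-representation probability P[X >= k].

    X ~ Hypergeom(N, K, n): the overlap between a uniformly drawn size-n
    selection from a universe of N and a fixed pathway of K members.
    """
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


@dataclass
class PathwayAnnotation:
    """Maps each metabolite to exactly one (super-pathway, sub-pathway) pair.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by metabolite id, with columns ``super_pathway`` and
        ``sub_pathway``.  Sub-pathway member sets partition the annotated
        universe.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"super_pathway", "sub_pathway"} - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate metabolite annotations: {dupes[:5]}")

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.table.index

    @property
    def sub_pathways(self) -> list[str]:
        return sorted(self.table["sub_pathway"].unique())

    def members(self, sub_pathway: str) -> list[str]:
        """Metabolite ids annotated to ``sub_pathway``."""
        mask = self.table["sub_pathway"] == sub_pathway
        return self.table.index[mask].tolist()

    def super_pathway_of(self, sub_pathway: str) -> str:
        rows = self.table.loc[self.table["sub_pathway"] == sub_pathway, "super_pathway"]
        if rows.empty:
            raise KeyError(f"unknown sub-pathway: {sub_pathway!r}")
        return rows.iloc[0]

    def subset(self, metabolite_ids: Iterable[str]) -> "PathwayAnnotation":
        """Annotation restricted to ``metabolite_ids`` (order preserved)."""
        ids = [m for m in metabolite_ids if m in self.table.index]
        return PathwayAnnotation(self.table.loc[ids])

    def __len__(self) -> int:
        return len(self.table)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, where p_(1) <= ... <=
    p_(m) are the sorted p-values.

    Raises
    ------
    ValueError
        If any p-value lies outside (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_subpathways(
    selected: Sequence[str],
    annotation: PathwayAnnotation,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` per sub-pathway.

    Parameters
    ----------
    selected : sequence of metabolite ids
        The selection (must be a subset of ``universe``).
    annotation : PathwayAnnotation
        Must annotate every id in ``universe``.
    universe : sequence of metabolite ids
        The background set — every metabolite the selection was drawn from
        (all metabolites surviving QC, not all annotated metabolites).

    Returns
    -------
    pandas.DataFrame
        One row per sub-pathway with at least one universe member, sorted by
        p-value, with columns ``sub_pathway``, ``super_pathway``,
        ``n_pathway`` (K), ``n_selected`` (k), ``enriched_factor``,
        ``log_enriched_factor``, ``p_value``, ``q_value``.  Only the one-sided
        over-representation tail P[X >= k] is tested; sub-pathways absent
        from the universe are excluded from testing and from the BH family.
    """
    universe = list(dict.fromkeys(universe))
    selected = list(dict.fromkeys(selected))
    sel_set = set(selected)
    uni_set = set(universe)
    if not sel_set <= uni_set:
        raise ValueError(f"selected ids outside universe: {sorted(sel_set - uni_set)[:5]}")
    unannotated = uni_set - set(annotation.metabolite_ids)
    if unannotated:
        raise ValueError(f"metabolites lacking annotation: {sorted(unannotated)[:5]}")
    n = len(selected)
    if n == 0:
        raise ValueError("empty selection: nothing to enrich")
    N = len(universe)

    sub_of = annotation.table["sub_pathway"]
    uni_sub = sub_of.loc[universe]
    sel_sub = sub_of.loc[selected]
    rows = []
    for sub, K in uni_sub.value_counts().items():
        k = int((sel_sub == sub).sum())
        ef = (k / n) / (K / N)
        rows.append(
            {
                "sub_pathway": sub,
                "super_pathway": annotation.super_pathway_of(sub),
                "n_pathway": int(K),
                "n_selected": k,
                "enriched_factor": ef,
                "log_enriched_factor": np.log(ef) if ef > 0 else -np.inf,
                "p_value": hypergeom_tail(N, int(K), n, k),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "sub_pathway"], kind="mergesort").reset_index(drop=True)
    logger.info(
        "enrichment: %d sub-pathways tested, %d selected of %d universe metabolites",
        len(out), n, N,
    )
    return out
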