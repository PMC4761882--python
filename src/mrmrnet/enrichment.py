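"""Hypergeometric category over-representation with -log10 P ranking.

Given a selected gene list and a GMT-style annotation collection, each
category is scored by the upper-tail hypergeometric probability of its
overlap with the list (optionally the more conservative EASE variant,
which decrements the overlap by one before testing).  Results carry the
DAVID-style columns: overlap count, percent of the mapped list,
p-value, -lg P (= -log10 p) and Benjamini-Hochberg FDR computed across
all tested categories before any filtering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationCollection, ValidationError

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # keeps -log10 finite for underflowed p-values


def hypergeom_p(overlap: int, list_size: int, category_size: int,
                universe_size: int, mode: str = "hypergeometric") -> float:
    """Upper-tail P(X >= overlap) for drawing list_size genes from a
    universe containing category_size category members.

    ``mode="EASE"`` applies DAVID's conservative variant, testing
    P(X >= overlap - 1) (floored at 0), so singleton overlaps are never
    significant.
    """
    if mode not in ("hypergeometric", "EASE"):
        raise ValidationError(f"unknown mode {mode!r}")
    if not (0 <= category_size <= universe_size and 0 <= list_size <= universe_size):
        raise ValidationError("sizes must satisfy 0 <= size <= universe_size")
    if not 0 <= overlap <= min(list_size, category_size):
        raise ValidationError(
            f"impossible overlap {overlap} for list {list_size}, "
            f"category {category_size}")
    k = overlap if mode == "hypergeometric" else max(overlap - 1, 0)
    # sf(k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, universe_size, category_size, list_size))


def enrich(gene_list, annotations: AnnotationCollection,
           neg_lg_p_cutoff: float = 0.0, top_k: int | None = None,
           mode: str = "hypergeometric") -> pd.DataFrame:
    """Rank categories by over-representation of *gene_list*.

    Genes outside the annotation universe are dropped (logged); one row
    per category with overlap >= 1, sorted by -lg P descending (ties keep
    collection order), filtered to -lg P > cutoff, truncated to top_k.
    BH FDR is computed over all tested categories before filtering.
    """
    gene_list = set(gene_list)
    if not gene_list:
        raise ValidationError("gene list is empty")
    mapped = gene_list & annotations.universe
    dropped = len(gene_list) - len(mapped)
    if dropped:
        logger.info("dropped %d gene(s) outside the annotation universe", dropped)
    if not mapped:
        raise ValidationError("no list gene maps to the annotation universe")

    universe_size = len(annotations.universe)
    rows = []
    for cid, (desc, members) in annotations.categories.items():
        count = len(mapped & members)
        if count == 0:
            continue
        p = hypergeom_p(count, len(mapped), len(members), universe_size, mode)
        rows.append((cid, desc, count, 100.0 * count / len(mapped),
                     p, -np.log10(max(p, _P_FLOOR))))
    if not rows:
        return pd.DataFrame(columns=["category", "description", "count",
                                     "percent", "p_value", "neg_lg_p", "fdr"])
    tbl = pd.DataFrame(rows, columns=["category", "description", "count",
                                      "percent", "p_value", "neg_lg_p"])
    tbl["fdr"] = multipletests(tbl["p_value"].to_numpy(), method="fdr_bh")[1]
    tbl = tbl.sort_values("neg_lg_p", ascending=False, kind="stable"
                          ).reset_index(drop=True)
    tbl = tbl[tbl["neg_lg_p"] > neg_lg_p_cutoff]
    if top_k is not None:
        tbl = tbl.head(top_k)
    return tbl.reset_index(drop=True)
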