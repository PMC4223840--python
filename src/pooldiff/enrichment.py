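"""Functional-category and GO-term over-representation tests.

Categories (or GO terms) are tested one at a time with a one-sided Fisher
exact test (hypergeometric upper tail) of the 2x2 table

    a = selected genes in the term        b = selected genes not in the term
    c = background genes in the term      d = background genes not in the term

where the background is the non-selected remainder of the universe (all
detected genes by default).  P-values are Benjamini-Hochberg corrected across
the terms of one selected set; terms with corrected p below ``alpha``
(default 0.05) are flagged enriched.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .expression import bh_adjust

__all__ = ["fisher_one_sided", "enrich", "burden_compare"]


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p-value for over-representation: the
    hypergeometric probability of drawing >= a term genes in a sample of
    a+b from a universe of a+b+c+d containing a+c term genes."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table counts must be non-negative")
    n_total = a + b + c + d
    n_term = a + c
    n_draw = a + b
    if n_term == 0 or n_draw == 0 or n_total == 0:
        warnings.warn("degenerate margin in Fisher table; p = 1")
        return 1.0
    return float(hypergeom.sf(a - 1, n_total, n_term, n_draw))


def enrich(selected, universe, mapping: pd.DataFrame,
           alpha: float = 0.05, term_col: str = "category") -> pd.DataFrame:
    """Over-representation of each term among ``selected`` genes relative to
    the ``universe`` (typically all detected genes).

    ``mapping`` has columns ``gene_id`` and ``term_col`` (one row per
    gene-term link; genes may carry several GO terms but exactly one
    category).  Returns one row per term with the 2x2 counts, raw and
    BH-adjusted p-values and the enrichment flag.
    """
    selected = set(selected)
    universe = set(universe)
    stray = selected - universe
    if stray:
        raise ValueError(
            f"selected genes outside the universe: {sorted(stray)[:10]}")
    if not selected:
        return pd.DataFrame(columns=["term", "a", "b", "c", "d",
                                     "p_raw", "p_adj", "enriched"])
    links = mapping[mapping["gene_id"].isin(universe)]
    rows = []
    for term, grp in links.groupby(term_col, sort=True):
        term_genes = set(grp["gene_id"])
        a = len(term_genes & selected)
        b = len(selected) - a
        c = len(term_genes) - a
        d = len(universe) - len(selected) - c
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d,
                     "p_raw": fisher_one_sided(a, b, c, d)})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["enriched"] = out["p_adj"] < alpha
    return out


def burden_compare(gene_table: pd.DataFrame, categories: pd.DataFrame,
                   candidate_label: str = "Candidate") -> dict:
    """Non-synonymous burden among qualifying SNPs: candidates vs all other
    affected genes.

    ``gene_table`` is the gene-level aggregate (columns ``gene_id``,
    ``n_differential``, ``n_nonsyn_differential``).  Builds the 2x2 table of
    qualifying SNPs (rows: candidate / non-candidate genes; columns:
    non-synonymous / other) and returns it with the one-sided Fisher p-value
    for excess non-synonymous burden in candidates.
    """
    cat = categories.set_index("gene_id")["category"]
    affected = gene_table[gene_table["n_differential"] > 0]
    is_cand = affected["gene_id"].map(cat).eq(candidate_label)
    ns_cand = int(affected.loc[is_cand, "n_nonsyn_differential"].sum())
    other_cand = int(affected.loc[is_cand, "n_differential"].sum()) - ns_cand
    ns_rest = int(affected.loc[~is_cand, "n_nonsyn_differential"].sum())
    other_rest = int(affected.loc[~is_cand, "n_differential"].sum()) - ns_rest
    if (ns_cand + other_cand) == 0 or (ns_rest + other_rest) == 0:
        warnings.warn("empty stratum in burden comparison; p = 1")
        p = 1.0
    elif ns_cand + ns_rest == 0:
        p = 1.0
    else:
        p = fisher_one_sided(ns_cand, other_cand, ns_rest, other_rest)
    return {"a": ns_cand, "b": other_cand, "c": ns_rest, "d": other_rest,
            "p_value": p}
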