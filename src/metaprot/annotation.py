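"""Taxonomic and functional composition of protein sets.

Covers the composition of significant-protein sets at a taxonomic rank,
log-ratio bias of eggNOG functional categories between enriched and
depleted sets, and hypergeometric term enrichment against a background
with Bonferroni correction (DAVID-style, with the EASE-score variant
available).
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from metaprot.io import terms_to_set

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


def _annotation_lookup(annotations: pd.DataFrame, column: str) -> pd.Series:
    s = annotations.set_index("protein_id")[column]
    s = s.where(s.astype(str).str.len() > 0, UNASSIGNED).fillna(UNASSIGNED)
    return s


def taxonomic_composition(
    protein_set,
    annotations: pd.DataFrame,
    rank: str = "taxon_order",
) -> pd.Series:
    """Proportions of a protein set per taxon at ``rank`` (default: order).

    Proteins without an assignment at the rank fall into an ``unassigned``
    bin; proportions sum to 1.  Raises on an empty set.
    """
    ids = list(protein_set)
    if not ids:
        raise ValueError("taxonomic_composition: empty protein set")
    lookup = _annotation_lookup(annotations, rank)
    labels = lookup.reindex(ids).fillna(UNASSIGNED)
    props = labels.value_counts(normalize=True).sort_values(ascending=False)
    props.name = "proportion"
    props.index.name = rank
    return props


def functional_bias(
    enriched,
    depleted,
    annotations: pd.DataFrame,
    min_count: int = 10,
    category_column: str = "eggnog_category",
) -> pd.DataFrame:
    """Per-category log-ratio of proportions between two protein sets.

    For each functional category, counts and within-set proportions are
    tabulated for the enriched (A) and depleted (B) sets and the log2 ratio
    of proportions is computed.  When either count is zero, 0.5 is added to
    both counts of that category (continuity correction; preserves
    antisymmetry).  Categories whose total count is <= ``min_count`` are
    flagged ``reported=False`` — suppressed from the headline report but
    kept in the table.
    """
    a_ids, b_ids = list(enriched), list(depleted)
    if not a_ids or not b_ids:
        raise ValueError("functional_bias: both protein sets must be non-empty")
    lookup = _annotation_lookup(annotations, category_column)
    la = lookup.reindex(a_ids).fillna(UNASSIGNED)
    lb = lookup.reindex(b_ids).fillna(UNASSIGNED)
    cats = sorted(set(la) | set(lb))
    count_a = la.value_counts().reindex(cats, fill_value=0)
    count_b = lb.value_counts().reindex(cats, fill_value=0)
    n_a, n_b = len(a_ids), len(b_ids)
    prop_a = count_a / n_a
    prop_b = count_b / n_b
    zero = (count_a == 0) | (count_b == 0)
    adj_a = count_a.astype(float) + 0.5 * zero
    adj_b = count_b.astype(float) + 0.5 * zero
    log2_ratio = np.log2((adj_a / n_a) / (adj_b / n_b))
    table = pd.DataFrame(
        {
            "count_a": count_a,
            "count_b": count_b,
            "prop_a": prop_a,
            "prop_b": prop_b,
            "log2_ratio": log2_ratio,
            "reported": (count_a + count_b) > min_count,
        }
    )
    table.index.name = category_column
    return table.sort_values("log2_ratio", ascending=False)


def _terms_by_protein(annotations: pd.DataFrame) -> pd.Series:
    return annotations.set_index("protein_id")["terms"].map(terms_to_set)


def term_enrichment(
    foreground,
    background,
    annotations: pd.DataFrame,
    correction: str = "bonferroni",
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of terms in a foreground set.

    For a term carried by K of the N background proteins and k of the n
    foreground proteins: fold = (k/n) / (K/N) and p is the upper
    hypergeometric tail P(X >= k).  With ``ease=True`` the EASE variant
    removes one foreground hit (p computed for k-1), the conservative
    score DAVID reports.  Bonferroni multiplies p by the number of terms
    tested, capped at 1.  Terms with k = 0 get fold 0 and p = 1.
    """
    fg = set(foreground)
    bg = list(dict.fromkeys(background))
    if not fg:
        raise ValueError("term_enrichment: empty foreground")
    if not fg <= set(bg):
        raise ValueError("term_enrichment: foreground must be a subset of background")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction: {correction!r}")
    term_sets = _terms_by_protein(annotations)
    missing = [p for p in bg if p not in term_sets.index]
    if missing:
        log.warning("term_enrichment: %d background protein(s) lack annotation rows", len(missing))
    N = len(bg)
    n = len(fg)
    term_members: dict[str, set[str]] = {}
    for pid in bg:
        for term in term_sets.get(pid, set()):
            term_members.setdefault(term, set()).add(pid)
    rows = []
    n_terms = len(term_members)
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = len(members & fg)
        if k == 0:
            fold, p = 0.0, 1.0
        else:
            fold = (k / n) / (K / N)
            k_eff = k - 1 if ease else k
            p = float(hypergeom.sf(k_eff - 1, N, K, n))
        p_adj = min(1.0, p * n_terms) if correction == "bonferroni" else p
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "fold_enrichment": fold, "p_value": p, "p_adjusted": p_adj}
        )
    table = pd.DataFrame(
        rows,
        columns=["term", "k", "n", "K", "N", "fold_enrichment", "p_value", "p_adjusted"],
    )
    return table.sort_values(["p_value", "term"]).reset_index(drop=True)


def count_annotation_subset(
    protein_set,
    annotations: pd.DataFrame,
    predicate: Callable[[pd.Series], bool],
) -> tuple[int, float]:
    """Count and proportion of a protein set matching an annotation predicate.

    ``predicate`` receives the annotation row of each protein (a Series
    with source, taxon_order, eggnog_category and terms fields).
    """
    ids = list(protein_set)
    if not ids:
        raise ValueError("count_annotation_subset: empty protein set")
    rows = annotations.set_index("protein_id").reindex(ids)
    matches = int(sum(bool(predicate(row)) for _, row in rows.iterrows()))
    return matches, matches / len(ids)
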