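"""Taxonomic composition, functional bias and term enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from metaprot.annotation import (
    count_annotation_subset,
    functional_bias,
    taxonomic_composition,
    term_enrichment,
)


def make_annotations(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("source", "microbial"),
        ("taxon_order", "unassigned"),
        ("eggnog_category", "unassigned"),
        ("terms", ""),
    ):
        if col not in df:
            df[col] = default
    return df.fillna({"taxon_order": "unassigned", "terms": ""})


def test_taxonomic_composition_proportions():
    ann = make_annotations(
        [{"protein_id": f"P{i}", "taxon_order": t}
         for i, t in enumerate(
             ["Clostridiales"] * 4 + ["Bacteroidales"] * 4 + ["Lactobacillales"] * 2)]
    )
    props = taxonomic_composition([f"P{i}" for i in range(10)], ann)
    assert props["Clostridiales"] == pytest.approx(0.4)
    assert props["Bacteroidales"] == pytest.approx(0.4)
    assert props["Lactobacillales"] == pytest.approx(0.2)
    assert props.sum() == pytest.approx(1.0, abs=1e-12)


def test_taxonomic_composition_unassigned_and_empty():
    ann = make_annotations([{"protein_id": "A"}, {"protein_id": "B"}])
    props = taxonomic_composition(["A", "B"], ann)
    assert props.to_dict() == {"unassigned": 1.0}
    with pytest.raises(ValueError):
        taxonomic_composition([], ann)


def test_functional_bias_log_ratio_example():
    # category M: 10/100 in A vs 2/40 in B -> proportion ratio 2, log2 = 1
    rows = []
    for i in range(100):
        rows.append({"protein_id": f"A{i}",
                     "eggnog_category": "M" if i < 10 else "other"})
    for i in range(40):
        rows.append({"protein_id": f"B{i}",
                     "eggnog_category": "M" if i < 2 else "other"})
    ann = make_annotations(rows)
    table = functional_bias(
        [f"A{i}" for i in range(100)], [f"B{i}" for i in range(40)], ann
    )
    assert table.loc["M", "log2_ratio"] == pytest.approx(1.0)
    assert bool(table.loc["M", "reported"])  # 12 > 10


def test_functional_bias_min_count_boundary():
    # exactly 10 proteins in total for the category -> suppressed (> 10 required)
    rows = [{"protein_id": f"A{i}", "eggnog_category": "M" if i < 5 else "x"}
            for i in range(50)]
    rows += [{"protein_id": f"B{i}", "eggnog_category": "M" if i < 5 else "x"}
             for i in range(50)]
    ann = make_annotations(rows)
    table = functional_bias([f"A{i}" for i in range(50)],
                            [f"B{i}" for i in range(50)], ann)
    assert not bool(table.loc["M", "reported"])
    assert "M" in table.index  # retained in the underlying table


def test_functional_bias_pseudocount_and_antisymmetry():
    rows = [{"protein_id": f"A{i}", "eggnog_category": "M" if i < 8 else "x"}
            for i in range(30)]
    rows += [{"protein_id": f"B{i}", "eggnog_category": "x"} for i in range(30)]
    ann = make_annotations(rows)
    a_ids = [f"A{i}" for i in range(30)]
    b_ids = [f"B{i}" for i in range(30)]
    fwd = functional_bias(a_ids, b_ids, ann)
    # brute force with +0.5 on the zero-count category
    expected = math.log2(((8 + 0.5) / 30) / ((0 + 0.5) / 30))
    assert fwd.loc["M", "log2_ratio"] == pytest.approx(expected)
    assert np.isfinite(fwd["log2_ratio"]).all()
    rev = functional_bias(b_ids, a_ids, ann)
    joined = fwd["log2_ratio"].sort_index() + rev["log2_ratio"].sort_index()
    assert np.allclose(joined, 0.0)
    with pytest.raises(ValueError):
        functional_bias([], b_ids, ann)


def hypergeom_tail(k, N, K, n):
    """Exact upper-tail P(X >= k) by combinatorial enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


def test_term_enrichment_exact_example():
    # k=5 of n=10 foreground, K=10 of N=100 background
    rows = [{"protein_id": f"P{i}", "terms": "T" if i < 10 else ""}
            for i in range(100)]
    ann = make_annotations(rows)
    fg = [f"P{i}" for i in range(5)] + [f"P{i}" for i in range(50, 55)]
    table = term_enrichment(fg, [f"P{i}" for i in range(100)], ann)
    row = table[table["term"] == "T"].iloc[0]
    assert row["fold_enrichment"] == pytest.approx(5.0)
    assert row["p_value"] == pytest.approx(hypergeom_tail(5, 100, 10, 10), rel=1e-12)


def test_term_enrichment_zero_hits_and_bonferroni():
    rows = [{"protein_id": f"P{i}",
             "terms": ";".join(t for t, keep in
                               [("A", i < 10), ("B", i % 7 == 0), ("C", i >= 95),
                                ("D", i % 2 == 0), ("E", i % 3 == 0)] if keep)}
            for i in range(100)]
    ann = make_annotations(rows)
    fg = [f"P{i}" for i in range(40, 50)]
    table = term_enrichment(fg, [f"P{i}" for i in range(100)], ann).set_index("term")
    assert table.loc["A", "k"] == 0
    assert table.loc["A", "fold_enrichment"] == 0.0
    assert table.loc["A", "p_value"] == 1.0
    n_terms = len(table)
    for term, row in table.iterrows():
        assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_value"] * n_terms))


def test_term_enrichment_ease_is_more_conservative():
    rows = [{"protein_id": f"P{i}", "terms": "T" if i < 20 else ""}
            for i in range(60)]
    ann = make_annotations(rows)
    fg = [f"P{i}" for i in range(10)]
    bg = [f"P{i}" for i in range(60)]
    plain = term_enrichment(fg, bg, ann).set_index("term").loc["T", "p_value"]
    ease = term_enrichment(fg, bg, ann, ease=True).set_index("term").loc["T", "p_value"]
    assert ease > plain
    assert ease == pytest.approx(hypergeom_tail(9, 60, 20, 10), rel=1e-12)


def test_term_enrichment_requires_subset():
    ann = make_annotations([{"protein_id": "A", "terms": "T"}])
    with pytest.raises(ValueError):
        term_enrichment(["A", "Z"], ["A"], ann)
    with pytest.raises(ValueError):
        term_enrichment([], ["A"], ann)


def test_count_annotation_subset():
    rows = [{"protein_id": f"P{i}",
             "terms": "immunoglobulin" if i < 40 else "other"} for i in range(109)]
    ann = make_annotations(rows)
    ids = [f"P{i}" for i in range(109)]
    count, prop = count_annotation_subset(
        ids, ann, lambda row: "immunoglobulin" in str(row["terms"])
    )
    assert count == 40
    assert prop == pytest.approx(40 / 109)
    count0, prop0 = count_annotation_subset(ids, ann, lambda row: False)
    assert (count0, prop0) == (0, 0.0)
    call, pall = count_annotation_subset(ids, ann, lambda row: True)
    assert (call, pall) == (109, 1.0)
    with pytest.raises(ValueError):
        count_annotation_subset([], ann, lambda row: True)
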