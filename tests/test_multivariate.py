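"""Bray-Curtis, PCoA, PERMANOVA and K-means clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from sklearn.metrics import adjusted_rand_score

from metaprot.datatypes import NORMALIZED_STAGE, AbundanceMatrix, ClusterSet
from metaprot.multivariate import (
    bray_curtis,
    cluster_bias,
    correlation_leaf_order,
    kmeans_proteins,
    pcoa,
    permanova,
)


def matrix_from_columns(cols: dict) -> AbundanceMatrix:
    df = pd.DataFrame(cols, dtype=float)
    df.index = [f"P{i}" for i in range(len(df))]
    return AbundanceMatrix(df, stage=NORMALIZED_STAGE)


def test_bray_curtis_examples():
    m = matrix_from_columns(
        {"u": [1, 1, 0], "v": [0, 1, 1], "w": [1, 1, 0], "x": [0, 0, 5]}
    )
    dm = bray_curtis(m)
    assert dm["u", "v"] == pytest.approx(0.5)  # 1 - 2*1/4
    assert dm["u", "w"] == 0.0  # identical composition
    assert dm["u", "x"] == pytest.approx(1.0)  # disjoint support
    assert np.allclose(np.diag(dm.data), 0.0)
    assert (dm.data >= 0).all() and (dm.data <= 1).all()


def test_bray_curtis_scaling_invariance_and_errors():
    rng = np.random.default_rng(0)
    base = rng.uniform(0, 5, (20, 4))
    m1 = matrix_from_columns({f"s{i}": base[:, i] for i in range(4)})
    m2 = matrix_from_columns({f"s{i}": base[:, i] * (i + 1) * 3 for i in range(4)})
    # with relative=True, per-sample loading cancels entirely
    assert np.allclose(bray_curtis(m1).data, bray_curtis(m2).data)
    bad = matrix_from_columns({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="all-zero"):
        bray_curtis(bad)


def test_pcoa_right_triangle_embedding():
    dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["A", "B", "C"])
    result = pcoa(dm)
    coords = result.coordinates.to_numpy()
    reproduced = squareform(pdist(coords))
    assert np.allclose(reproduced, dm.data, atol=1e-9)
    assert (np.diff(result.eigenvalues) <= 1e-12).all()
    assert result.proportion_explained.sum() <= 1 + 1e-12


def test_pcoa_euclidean_round_trip():
    rng = np.random.default_rng(3)
    points = rng.normal(size=(12, 2))
    dm = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(12)])
    result = pcoa(dm)
    reproduced = squareform(pdist(result.coordinates.to_numpy()))
    assert np.allclose(reproduced, dm.data, atol=1e-9)


def test_pcoa_coincident_points_and_truncation():
    dm = DistanceMatrix(
        [[0, 0, 1], [0, 0, 1], [1, 1, 0]], ids=["a", "b", "c"]
    )
    result = pcoa(dm)
    assert np.allclose(result.coordinates.loc["a"], result.coordinates.loc["b"])
    truncated = pcoa(dm, n_axes=5)  # more axes than positive eigenvalues
    assert truncated.coordinates.shape[1] <= 2


def test_permanova_matches_skbio_statistic():
    rng = np.random.default_rng(7)
    data = rng.uniform(0.5, 3, (30, 12))
    data[:, 6:] *= np.exp(rng.normal(0.4, 0.1, (30, 1)))
    m = matrix_from_columns({f"s{i}": data[:, i] for i in range(12)})
    dm = bray_curtis(m)
    groups = ["g1"] * 6 + ["g2"] * 6
    ours = permanova(dm, groups, n_permutations=99, seed=0)
    theirs = skbio_permanova(dm, grouping=groups, permutations=99)
    assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)
    # determinism given seed
    again = permanova(dm, groups, n_permutations=99, seed=0)
    assert again.p_value == ours.p_value
    assert ours.p_value >= 1 / 100


def test_permanova_separated_groups_minimum_p():
    # with g samples per group, a random shuffle recreates the separating
    # partition with probability 2/C(2g, g); the attainable floor reflects that
    rng = np.random.default_rng(5)
    a = rng.normal(0, 0.05, (40, 6)) + 1
    b = rng.normal(0, 0.05, (40, 6)) + 10
    m = matrix_from_columns(
        {f"a{i}": np.abs(a[:, i]) for i in range(6)}
        | {f"b{i}": np.abs(b[:, i]) for i in range(6)}
    )
    dm = bray_curtis(m, relative=False)
    result = permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=999, seed=1)
    assert result.p_value <= 0.01
    small = permanova(dm.filter([f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]),
                      ["a"] * 4 + ["b"] * 4, n_permutations=999, seed=1)
    assert small.p_value <= 0.06  # floor near 2/70 for a 4+4 design


def test_permanova_errors():
    dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
    with pytest.raises(ValueError):
        permanova(dm, ["g"] * 4)  # one group
    with pytest.raises(ValueError):
        permanova(dm, ["g1", "g1", "g1", "g2"])  # group of one
    with pytest.raises(ValueError):
        permanova(dm, ["g1", "g1", "g2", "g2"])  # constant distances


def planted_profiles(n_per=30, n_samples=10, seed=0):
    rng = np.random.default_rng(seed)
    shapes = [np.sin(np.linspace(0, 3, n_samples)),
              np.cos(np.linspace(0, 3, n_samples)),
              np.linspace(1, -1, n_samples)]
    rows, labels = [], []
    for g, shape in enumerate(shapes):
        for _ in range(n_per):
            rows.append(5 + 2 * shape + rng.normal(0, 0.05, n_samples))
            labels.append(g)
    df = pd.DataFrame(rows, columns=[f"s{i}" for i in range(n_samples)],
                      index=[f"P{i}" for i in range(len(rows))])
    return AbundanceMatrix(np.abs(df), stage=NORMALIZED_STAGE), labels


def test_kmeans_recovers_planted_profiles():
    matrix, labels = planted_profiles()
    clusters = kmeans_proteins(matrix, k=3, seed=0, n_restarts=5)
    assert adjusted_rand_score(labels, clusters.assignment) == 1.0
    # objective never increases along the winning run
    hist = clusters.objective_history
    assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))


def test_kmeans_determinism_and_k1():
    matrix, _ = planted_profiles(seed=2)
    a = kmeans_proteins(matrix, k=4, seed=9)
    b = kmeans_proteins(matrix, k=4, seed=9)
    pd.testing.assert_series_equal(a.assignment, b.assignment)
    one = kmeans_proteins(matrix, k=1, seed=0, n_restarts=1)
    X = matrix.values.to_numpy()
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    expected = float(((Z - Z.mean(axis=0)) ** 2).sum())
    assert one.wcss == pytest.approx(expected, rel=1e-9)
    with pytest.raises(ValueError):
        kmeans_proteins(matrix, k=10_000)


def test_cluster_bias_hypergeometric_oracle():
    from test_annotation import hypergeom_tail, make_annotations

    # cluster of 100 proteins with 90 Clostridiales; background 300 with 30%
    rows = []
    for i in range(300):
        if i < 90:  # cluster members dominated by the order
            taxon = "Clostridiales"
        elif i < 100:
            taxon = "Bacteroidales"
        else:
            taxon = "Clostridiales" if i % 20 == 0 else "Bacteroidales"
        rows.append({"protein_id": f"P{i}", "taxon_order": taxon})
    ann = make_annotations(rows)
    K_total = sum(r["taxon_order"] == "Clostridiales" for r in rows)
    assignment = pd.Series([0] * 100 + [1] * 200, index=[f"P{i}" for i in range(300)])
    clusters = ClusterSet(k=2, assignment=assignment, wcss=0.0, objective_history=[0.0])
    bias = cluster_bias(clusters, ann, columns=("taxon_order",))
    row = bias[(bias["cluster"] == 0) & (bias["label"] == "Clostridiales")].iloc[0]
    assert row["fold_enrichment"] == pytest.approx((90 / 100) / (K_total / 300))
    assert row["p_value"] == pytest.approx(
        hypergeom_tail(90, 300, K_total, 100), rel=1e-9
    )
    # a cluster matching the background composition exactly is unenriched
    rows_flat = [{"protein_id": f"Q{i}",
                  "taxon_order": "Clostridiales" if i % 10 < 3 else "Bacteroidales"}
                 for i in range(300)]
    flat = cluster_bias(
        ClusterSet(
            k=3,
            assignment=pd.Series([i // 100 for i in range(300)],
                                 index=[f"Q{i}" for i in range(300)]),
            wcss=0.0,
            objective_history=[0.0],
        ),
        make_annotations(rows_flat),
        columns=("taxon_order",),
    )
    row1 = flat[(flat["cluster"] == 0) & (flat["label"] == "Clostridiales")].iloc[0]
    assert row1["fold_enrichment"] == pytest.approx(1.0)
    assert row1["p_value"] > 0.05


def test_correlation_leaf_order_returns_permutation():
    matrix, _ = planted_profiles(seed=4)
    order = correlation_leaf_order(matrix)
    assert sorted(order) == sorted(matrix.sample_ids)
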