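"""Sample- and protein-level multivariate structure.

Samples: Bray-Curtis dissimilarities on relative abundances, classical
principal coordinates analysis, and one-way PERMANOVA with a seeded
permutation null.  Proteins: K-means clustering of z-scored abundance
profiles with per-cluster taxonomic/functional enrichment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import hypergeom
from skbio import DistanceMatrix
from sklearn.cluster import kmeans_plusplus

from metaprot.datatypes import (
    AbundanceMatrix,
    ClusterSet,
    OrdinationResult,
    PermanovaResult,
)

log = logging.getLogger(__name__)


def bray_curtis(matrix: AbundanceMatrix, relative: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    ``relative=True`` (default) converts each column to relative abundance
    first, so only composition — not loading — drives the distances.
    All-zero samples are rejected.
    """
    values = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(matrix.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    if relative:
        values = values / totals[:, None]
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=matrix.sample_ids)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling (principal coordinates) of a distance matrix.

    Eigendecomposes the double-centered squared-distance matrix
    ``-1/2 J D^2 J``; coordinates are eigenvectors scaled by the square
    root of their eigenvalues.  Axes with negative eigenvalues (the
    distance is then not Euclidean-realizable) are reported but dropped,
    uncorrected.  ``proportion_explained`` is relative to the sum of
    positive eigenvalues.
    """
    D = dm.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals.max()), 1.0))
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    pos_vals = eigvals[positive]
    n_pos = int(positive.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        log.warning(
            "pcoa: requested %d axes but only %d positive eigenvalues; truncating",
            n_axes,
            n_pos,
        )
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    total = pos_vals.sum() if n_pos else 1.0
    coordinates = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    return OrdinationResult(
        coordinates=coordinates,
        eigenvalues=pos_vals[:n_axes],
        proportion_explained=pos_vals[:n_axes] / total,
        negative_eigenvalues=negative,
    )


def _pseudo_f(sq: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way PERMANOVA pseudo-F from a squared-distance matrix."""
    n = sq.shape[0]
    ss_total = sq[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F with a label-permutation p-value.

    The p-value uses the +1 convention (observed statistic included in the
    null), so p >= 1/(n_permutations + 1) and is never zero.  Deterministic
    given ``seed``.
    """
    labels = pd.Series(list(grouping))
    codes, uniques = pd.factorize(labels)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("permanova needs >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniques[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) with < 2 samples: {small}")
    sq = dm.data.astype(float) ** 2
    if len(labels) != sq.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    if np.allclose(dm.data, 0):
        raise ValueError("constant (all-zero) distance matrix")

    f_obs = _pseudo_f(sq, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _pseudo_f(sq, perm, n_groups) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs), p_value=float(p), n_permutations=n_permutations, seed=seed
    )


def _standardize_rows(values: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "zscore":
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (values - mu) / sd
    if scaling == "minmax":
        lo = values.min(axis=1, keepdims=True)
        rng = values.max(axis=1, keepdims=True) - lo
        rng[rng == 0] = 1.0
        return (values - lo) / rng
    raise ValueError(f"unknown scaling: {scaling!r}")


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd iterations from a k-means++ start; returns labels, centers, WCSS trace."""
    centers, _ = kmeans_plusplus(
        X, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
    )
    history: list[float] = []
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, centers, metric="sqeuclidean")
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(len(X)), labels].sum())
        history.append(wcss)
        new_centers = centers.copy()
        for j in range(k):
            members = X[labels == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                new_centers[j] = X[d2.min(axis=1).argmax()]
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = d2.argmin(axis=1)
    history.append(float(d2[np.arange(len(X)), labels].sum()))
    return labels, centers, history


def kmeans_proteins(
    matrix: AbundanceMatrix,
    k: int = 6,
    seed: int | None = None,
    n_restarts: int = 10,
    scaling: str = "zscore",
    sample_ids: list[str] | None = None,
) -> ClusterSet:
    """K-means clustering of protein abundance profiles.

    Rows are z-score standardized (min-max scaling optional) so the
    clustering groups profile shapes, not abundance levels — mirroring a
    row-relative heatmap view.  Lloyd's algorithm with k-means++ starts,
    Euclidean distance, best of ``n_restarts`` by within-cluster sum of
    squares; the winning run's WCSS trace is retained (it is
    non-increasing).  Deterministic given ``seed``.
    """
    values = matrix.values if sample_ids is None else matrix.values[sample_ids]
    X = _standardize_rows(values.to_numpy(dtype=float), scaling)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the {len(X)} proteins available")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for _ in range(n_restarts):
        labels, centers, history = _lloyd(X, k, rng)
        if best is None or history[-1] < best[2][-1]:
            best = (labels, centers, history)
    labels, centers, history = best
    assignment = pd.Series(labels, index=values.index, name="cluster")
    return ClusterSet(
        k=k,
        assignment=assignment,
        wcss=history[-1],
        objective_history=history,
        centers=centers,
    )


def cluster_bias(
    clusters: ClusterSet,
    annotations: pd.DataFrame,
    columns: tuple[str, ...] = ("taxon_order", "eggnog_category"),
) -> pd.DataFrame:
    """Taxonomic/functional enrichment of each cluster vs all clustered proteins.

    For every cluster and annotation label: fold enrichment of the label in
    the cluster relative to the clustered background and the one-sided
    hypergeometric p-value.  Empty clusters are skipped with a warning;
    single-protein clusters are flagged ``low_n``.
    """
    ann = annotations.set_index("protein_id")
    background = list(clusters.assignment.index)
    N = len(background)
    rows = []
    for cluster_id in range(clusters.k):
        members = list(clusters.assignment.index[clusters.assignment == cluster_id])
        if not members:
            log.warning("cluster_bias: cluster %d is empty; skipped", cluster_id)
            continue
        n = len(members)
        for column in columns:
            labels = ann[column].reindex(background).fillna("unassigned")
            fg_labels = labels.loc[members]
            for label, K in labels.value_counts().items():
                k = int((fg_labels == label).sum())
                if k == 0:
                    continue
                fold = (k / n) / (K / N)
                p = float(hypergeom.sf(k - 1, N, int(K), n))
                rows.append(
                    {
                        "cluster": cluster_id,
                        "annotation": column,
                        "label": label,
                        "k": k,
                        "n": n,
                        "K": int(K),
                        "N": N,
                        "fold_enrichment": fold,
                        "p_value": p,
                        "low_n": n < 2,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "annotation", "label", "k", "n", "K", "N",
            "fold_enrichment", "p_value", "low_n",
        ],
    )


def correlation_leaf_order(matrix: AbundanceMatrix) -> list[str]:
    """Sample ordering from average-linkage clustering of 1 - Pearson r.

    A heatmap-export convenience only; not a studied output.
    """
    values = matrix.values.to_numpy(dtype=float).T
    d = pdist(values, metric="correlation")
    link = hierarchy.linkage(d, method="average")
    order = hierarchy.leaves_list(link)
    return [matrix.sample_ids[i] for i in order]
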