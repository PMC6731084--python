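"""Two-group differential abundance ranked by the pi-score.

The pi-score combines effect size and significance: log2 fold change
multiplied by -log10 of the t-test p-value.  Proteins with |pi| above a
cutoff (default 1, roughly alpha ~ 0.05 for moderate fold changes) are
called significant, with the sign giving the enrichment direction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from metaprot.datatypes import NORMALIZED_STAGE, AbundanceMatrix

log = logging.getLogger(__name__)

#: Contrast name -> ((group, timepoint) selector for side A, side B).
#: ``None`` matches any value.  Side A is the numerator of the fold change.
CONTRASTS: dict[str, tuple[tuple[str | None, str | None], tuple[str | None, str | None]]] = {
    "final-vs-initial": ((None, "final"), (None, "initial")),
    "high-vs-low@initial": (("high", "initial"), ("low", "initial")),
    "high-vs-low@final": (("high", "final"), ("low", "final")),
}

_P_FLOOR = float(np.finfo(float).tiny)


def pi_score(log2_fc, p_value):
    """pi = log2_fc * (-log10 p).  Odd in log2_fc, zero at p = 1.

    Accepts scalars or arrays; ``p_value`` must lie in (0, 1].
    """
    p = np.asarray(p_value, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p_value must lie in (0, 1]")
    result = np.asarray(log2_fc, dtype=float) * (-np.log10(p))
    if np.isscalar(log2_fc) and np.isscalar(p_value):
        return float(result)
    return result


def contrast_samples(
    metadata: pd.DataFrame, contrast: str
) -> tuple[list[str], list[str]]:
    """Sample ids of the two sides of a named contrast (bridges excluded)."""
    if contrast not in CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        )
    (ga, ta), (gb, tb) = CONTRASTS[contrast]
    bio = metadata[~metadata["is_bridge"]]

    def select(group, timepoint):
        mask = pd.Series(True, index=bio.index)
        if group is not None:
            mask &= bio["group"] == group
        if timepoint is not None:
            mask &= bio["timepoint"] == timepoint
        return list(bio.loc[mask, "sample_id"])

    return select(ga, ta), select(gb, tb)


def differential_test(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    contrast: str,
    threshold: float = 1.0,
    equal_var: bool = True,
    log2_input: bool = False,
) -> pd.DataFrame:
    """Per-protein two-group comparison for one contrast.

    Fold change is the ratio of group means on the normalized scale
    (log2-transformed input optional); the p-value is an unpaired
    two-tailed t-test (Student's by default, Welch with
    ``equal_var=False``); significance is ``|pi| > threshold``.

    When a group mean is zero, a pseudocount of half the smallest positive
    matrix value is added to *both* means, keeping the fold change finite
    and the contrast antisymmetric.  Proteins with zero mean on both sides
    are excluded with a log notice.  A zero-variance tie with unequal means
    yields a p-value floored at the smallest positive float, with a warning.
    """
    if matrix.stage != NORMALIZED_STAGE:
        raise ValueError("differential_test expects a normalized matrix")
    side_a, side_b = contrast_samples(metadata, contrast)
    if len(side_a) < 2 or len(side_b) < 2:
        raise ValueError(
            f"contrast {contrast!r} needs >=2 samples per side "
            f"(got {len(side_a)} vs {len(side_b)})"
        )
    values = matrix.values
    a = values[side_a].to_numpy(dtype=float)
    b = values[side_b].to_numpy(dtype=float)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    both_zero = (mean_a == 0) & (mean_b == 0)
    if both_zero.any():
        log.info(
            "differential_test(%s): excluding %d protein(s) with zero mean on both sides",
            contrast,
            int(both_zero.sum()),
        )

    positive = values.to_numpy()[values.to_numpy() > 0]
    eps = 0.5 * positive.min() if len(positive) else 0.5
    adj_a = mean_a.copy()
    adj_b = mean_b.copy()
    needs_eps = (mean_a == 0) | (mean_b == 0)
    adj_a[needs_eps] += eps
    adj_b[needs_eps] += eps
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(adj_a / adj_b)

    ta = np.log2(a + eps) if log2_input else a
    tb = np.log2(b + eps) if log2_input else b
    with warnings.catch_warnings():
        # zero-variance ties are caught and resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(ta, tb, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(mean_a, mean_b)
        p[degenerate & equal_means] = 1.0
        n_floored = int((degenerate & ~equal_means).sum())
        if n_floored:
            log.warning(
                "differential_test(%s): %d protein(s) with zero within-group "
                "variance and unequal means; p floored at %.3g",
                contrast,
                n_floored,
                _P_FLOOR,
            )
        p[degenerate & ~equal_means] = _P_FLOOR
    p = np.clip(p, _P_FLOOR, 1.0)

    pi = pi_score(log2_fc, p)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log2_fc,
            "p_value": p,
            "pi_score": pi,
            "significant": np.abs(pi) > threshold,
        },
        index=values.index,
    )
    table["direction"] = np.where(table["log2_fc"] >= 0, "enriched-in-A", "enriched-in-B")
    table = table.loc[~both_zero]
    table.attrs["contrast"] = contrast
    table.attrs["threshold"] = threshold
    return table


def volcano_table(diff: pd.DataFrame) -> pd.DataFrame:
    """Plotting-ready export: sorted by |pi| descending."""
    out = pd.DataFrame(
        {
            "log2_fc": diff["log2_fc"],
            "neg_log10_p": -np.log10(diff["p_value"]),
            "pi_score": diff["pi_score"],
            "significant": diff["significant"],
        },
        index=diff.index,
    )
    return out.reindex(out["pi_score"].abs().sort_values(ascending=False).index)


def significant_sets(diff: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(enriched-in-A, enriched-in-B) protein ids among significant calls."""
    sig = diff[diff["significant"]]
    enriched = list(sig.index[sig["pi_score"] > 0])
    depleted = list(sig.index[sig["pi_score"] < 0])
    return enriched, depleted
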