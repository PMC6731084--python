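"""Two-bridge-channel normalization of TMT summed signal-to-noise.

Every plex carries two pooled-standard (bridge) aliquots.  Each sample
value is first expressed as a ratio to each bridge for that protein,
rescaled by the median signal of that bridge column (restoring a common
signal scale across plexes), and the two bridge-derived values are
averaged.  A final median normalization corrects per-sample loading
differences so that every sample column has the same median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gmean, pearsonr

from metaprot.datatypes import (
    NORMALIZED_STAGE,
    AbundanceMatrix,
    NormalizationReport,
    SchemaError,
    bridge_samples,
    check_metadata,
    plex_samples,
)


def bridge_normalize(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    bridge_mean: str = "arithmetic",
    column_correction: str = "per_sample",
) -> AbundanceMatrix:
    """Normalize raw summed S/N to bridge channels, then correct loading.

    For each plex with bridges ``b`` and sample column ``s``::

        r_b(p, s) = value(p, s) / value(p, b)          # ratio to pooled standard
        v(p, s)   = mean_b( r_b(p, s) * median_p value(p, b) )

    ``bridge_mean`` selects the arithmetic (default) or geometric mean over
    the plex's bridges.  The loading correction then rescales so medians
    agree: with ``column_correction="per_sample"`` (default) every sample
    column is divided by its own median over proteins and multiplied by the
    grand median G of the column-normalized matrix, so every column ends
    with median G and the result is invariant to rescaling any single plex;
    ``"global"`` divides the whole matrix by its grand median instead.

    Zero sample values pass through the ratios as zeros; a zero bridge
    value for a retained protein is an error naming the protein.
    """
    check_metadata(metadata)
    if bridge_mean not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown bridge_mean: {bridge_mean!r}")
    if column_correction not in ("per_sample", "global"):
        raise ValueError(f"unknown column_correction: {column_correction!r}")
    values = matrix.values
    missing = set(metadata["sample_id"]) - set(values.columns)
    if missing:
        raise SchemaError(f"matrix lacks sample columns: {sorted(missing)}")
    if values.isna().any().any():
        raise ValueError(
            "raw matrix has plex-absent proteins; run intersect_plexes first"
        )

    v = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for plex in sorted(metadata["plex"].unique()):
        cols = plex_samples(metadata, plex)
        bridges = bridge_samples(metadata, plex)
        if not bridges:
            raise SchemaError(f"plex {plex!r} has no bridge sample")
        rescaled = []
        for b in bridges:
            bvals = values[b]
            zero = bvals[bvals <= 0]
            if len(zero):
                raise ValueError(
                    f"zero bridge value in {b!r} for protein(s) "
                    f"{list(zero.index[:5])}; cannot form bridge ratios"
                )
            r_b = values[cols].div(bvals, axis=0)
            rescaled.append(r_b * float(bvals.median()))
        stack = np.stack([r.to_numpy() for r in rescaled])
        if bridge_mean == "arithmetic":
            merged = stack.mean(axis=0)
        else:
            merged = gmean(stack, axis=0)
        v[cols] = merged

    if column_correction == "per_sample":
        u = v.div(v.median(axis=0), axis=1)
        grand = float(np.median(u.to_numpy()))
        out = u * grand
    else:
        out = v / float(np.median(v.to_numpy()))
    return AbundanceMatrix(out, stage=NORMALIZED_STAGE)


def _bridge_agreement(values: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Median per-protein ratio of mean bridge signal, each plex vs the first."""
    plexes = sorted(metadata["plex"].unique())
    ref = values[bridge_samples(metadata, plexes[0])].mean(axis=1)
    rows = []
    for plex in plexes[1:]:
        other = values[bridge_samples(metadata, plex)].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = float((other / ref).median())
        rows.append({"plex": plex, "reference_plex": plexes[0], "ratio": ratio})
    return pd.DataFrame(rows, columns=["plex", "reference_plex", "ratio"])


def normalization_report(
    before: AbundanceMatrix, after: AbundanceMatrix, metadata: pd.DataFrame
) -> NormalizationReport:
    """Diagnostics for a normalization run.

    Reports per-sample column medians before/after, the Pearson correlation
    between the two bridge columns of each plex, and the inter-plex bridge
    agreement ratio (median over proteins of the mean-bridge-signal ratio of
    each plex against the first) before/after.
    """
    if before.values.shape != after.values.shape or not before.values.columns.equals(
        after.values.columns
    ):
        raise ValueError("before/after matrices do not match")
    check_metadata(metadata)
    medians = pd.DataFrame(
        {
            "median_before": before.values.median(axis=0),
            "median_after": after.values.median(axis=0),
        }
    )
    corr_rows = []
    for plex in sorted(metadata["plex"].unique()):
        bridges = bridge_samples(metadata, plex)
        for stage, mat in (("before", before.values), ("after", after.values)):
            if (
                len(bridges) >= 2
                and mat[bridges[0]].nunique() > 1
                and mat[bridges[1]].nunique() > 1
            ):
                r = pearsonr(mat[bridges[0]], mat[bridges[1]]).statistic
            else:  # undefined for a constant bridge column
                r = np.nan
            corr_rows.append({"plex": plex, "stage": stage, "pearson_r": float(r)})
    agree_before = _bridge_agreement(before.values, metadata).rename(
        columns={"ratio": "ratio_before"}
    )
    agree_after = _bridge_agreement(after.values, metadata)
    agree = agree_before.assign(ratio_after=agree_after["ratio"].to_numpy())
    return NormalizationReport(
        column_medians=medians,
        bridge_correlation=pd.DataFrame(corr_rows),
        bridge_agreement=agree,
    )
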