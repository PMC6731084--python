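"""PSM quality filtering and protein-level aggregation.

Quantitation proceeds from peptide-spectrum matches: PSMs failing QC are
removed, surviving reporter signal-to-noise values are summed per protein
per channel, and the analysis set is restricted to proteins quantified in
every plex.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from metaprot.datatypes import (
    RAW_STAGE,
    AbundanceMatrix,
    FilterParams,
    SchemaError,
    check_metadata,
    plex_samples,
)

log = logging.getLogger(__name__)


class FilterResult(NamedTuple):
    psms: pd.DataFrame
    removal_counts: dict[str, int]


def _sn_columns(psms: pd.DataFrame) -> list[str]:
    return [c for c in psms.columns if c.startswith("sn_")]


def filter_psms(psms: pd.DataFrame, params: FilterParams | None = None) -> FilterResult:
    """Apply the stringent PSM-level QC filter.

    Retains exactly the PSMs that are high-confidence (when required), not
    ambiguous, with isolation interference <= ``max_interference`` and mean
    reporter S/N over the plex's channels >= ``min_avg_sn``.  Interference
    exactly at the threshold is kept (the rule removes strictly above it);
    mean S/N exactly at the threshold is kept (the rule removes strictly
    below it).  Low-confidence PSMs are removed whenever moderate ones are.

    Row order is preserved.  Per-rule removal counts (a PSM violating
    several rules is counted under each) are logged and returned.
    """
    if params is None:
        params = FilterParams()
    counts = {"confidence": 0, "ambiguous": 0, "interference": 0, "low_sn": 0}
    if len(psms) == 0:
        return FilterResult(psms.copy(), counts)

    keep = pd.Series(True, index=psms.index)
    if params.require_high_confidence:
        bad = psms["confidence"] != "high"
        counts["confidence"] = int(bad.sum())
        keep &= ~bad
    if params.drop_ambiguous:
        bad = psms["ambiguous"].astype(bool)
        counts["ambiguous"] = int(bad.sum())
        keep &= ~bad
    bad = psms["interference_pct"] > params.max_interference
    counts["interference"] = int(bad.sum())
    keep &= ~bad
    mean_sn = psms[_sn_columns(psms)].mean(axis=1)
    bad = mean_sn < params.min_avg_sn
    counts["low_sn"] = int(bad.sum())
    keep &= ~bad

    out = psms.loc[keep]
    log.info(
        "filter_psms: %d -> %d PSMs (removed per rule: %s)",
        len(psms),
        len(out),
        counts,
    )
    return FilterResult(out, counts)


def aggregate_proteins(psms: pd.DataFrame, metadata: pd.DataFrame) -> AbundanceMatrix:
    """Sum reporter S/N over each protein's PSMs, per sample channel.

    Each PSM contributes its ``sn_<channel>`` value to the sample occupying
    (its plex, that channel).  Proteins with no PSM in a plex carry NaN in
    that plex's sample columns — absence is explicit, never imputed.

    Raises :class:`SchemaError` if a PSM's plex/channel combination has no
    sample in the metadata.
    """
    check_metadata(metadata)
    sn_cols = _sn_columns(psms)
    channels = [c.removeprefix("sn_") for c in sn_cols]
    channel_map: dict[tuple[str, str], str] = {
        (row.plex, row.channel): row.sample_id for row in metadata.itertuples()
    }
    plexes = sorted(metadata["plex"].unique())
    sample_order = [s for p in plexes for s in plex_samples(metadata, p)]

    protein_ids = pd.unique(psms["protein_id"]) if len(psms) else np.array([], dtype=object)
    values = pd.DataFrame(np.nan, index=pd.Index(protein_ids, name="protein_id"),
                          columns=sample_order, dtype=float)
    for plex, sub in psms.groupby("plex", sort=False):
        if str(plex) not in plexes:
            raise SchemaError(f"PSM plex {plex!r} absent from metadata")
        try:
            samples = [channel_map[(str(plex), ch)] for ch in channels]
        except KeyError as exc:
            raise SchemaError(
                f"channel {exc.args[0][1]!r} of plex {plex!r} has no sample in metadata"
            ) from None
        summed = sub.groupby("protein_id", sort=False)[sn_cols].sum()
        summed.columns = samples
        values.loc[summed.index, samples] = summed

    return AbundanceMatrix(values, stage=RAW_STAGE)


def plex_presence(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Boolean proteins x plexes table: quantified (>=1 PSM) in that plex."""
    presence = {}
    for plex in sorted(metadata["plex"].unique()):
        cols = plex_samples(metadata, plex)
        presence[plex] = matrix.values[cols].notna().any(axis=1)
    return pd.DataFrame(presence)


def intersect_plexes(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> AbundanceMatrix:
    """Restrict to proteins quantified in every plex.

    Raises ``ValueError`` on single-plex input: there is nothing to
    intersect, skip this step.
    """
    plexes = sorted(metadata["plex"].unique())
    if len(plexes) < 2:
        raise ValueError("single-plex input: skip plex intersection")
    presence = plex_presence(matrix, metadata)
    keep = presence.all(axis=1)
    out = matrix.values.loc[keep]
    log.info(
        "intersect_plexes: retained %d of %d proteins (%d dropped)",
        int(keep.sum()),
        len(keep),
        int((~keep).sum()),
    )
    return AbundanceMatrix(out, stage=matrix.stage)
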