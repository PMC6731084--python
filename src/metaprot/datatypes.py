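"""Core containers and schemas shared across the pipeline stages.

Tables are plain :class:`pandas.DataFrame` objects with documented column
schemas; :class:`AbundanceMatrix` is a thin wrapper that carries the
processing stage alongside the proteins x samples values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reporter channels of a TMT 10-plex, in mass order.
TMT10_CHANNELS: tuple[str, ...] = (
    "126",
    "127N",
    "127C",
    "128N",
    "128C",
    "129N",
    "129C",
    "130N",
    "130C",
    "131",
)

#: Channels that carry the pooled standard in every plex.
DEFAULT_BRIDGE_CHANNELS: tuple[str, ...] = ("126", "131")

RAW_STAGE = "raw_summed_sn"
NORMALIZED_STAGE = "normalized"

#: Columns of a PSM table, followed by one ``sn_<channel>`` column per channel.
PSM_BASE_COLUMNS = (
    "peptide",
    "protein_id",
    "plex",
    "confidence",
    "ambiguous",
    "interference_pct",
)

#: Columns of the sample metadata table.
METADATA_COLUMNS = (
    "sample_id",
    "plex",
    "channel",
    "is_bridge",
    "group",
    "timepoint",
    "replicate",
)

#: Columns of the protein annotation table.
ANNOTATION_COLUMNS = (
    "protein_id",
    "source",
    "taxon_order",
    "eggnog_category",
    "terms",
)

CONFIDENCE_LEVELS = ("high", "moderate", "low")


class SchemaError(ValueError):
    """A table does not conform to its declared column schema."""


def sn_column(channel: str) -> str:
    """Column name holding the reporter signal-to-noise of ``channel``."""
    return f"sn_{channel}"


def psm_columns(channels: tuple[str, ...] = TMT10_CHANNELS) -> list[str]:
    return list(PSM_BASE_COLUMNS) + [sn_column(c) for c in channels]


@dataclass(frozen=True)
class FilterParams:
    """QC thresholds applied to peptide-spectrum matches.

    Defaults implement the stringent reporting filter used for MS3 TMT
    quantitation: only high-confidence, unambiguous PSMs with isolation
    interference of at most 25% and a mean reporter signal-to-noise of at
    least 10 across the plex's channels are retained.  Both thresholds are
    boundary-inclusive on the *keep* side: interference strictly above 25
    is removed, mean S/N strictly below 10 is removed.
    """

    max_interference: float = 25.0
    min_avg_sn: float = 10.0
    require_high_confidence: bool = True
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_interference <= 100.0:
            raise ValueError("max_interference must lie in [0, 100]")
        if self.min_avg_sn < 0:
            raise ValueError("min_avg_sn must be non-negative")


@dataclass
class AbundanceMatrix:
    """Proteins x samples quantitation with its processing stage.

    ``values`` is indexed by protein_id with one column per sample_id.
    At the raw summed-S/N stage a protein absent from a plex (no surviving
    PSM there) carries NaN in all of that plex's sample columns; absence is
    resolved by plex intersection, never imputed.  At the normalized stage
    no entry is missing.
    """

    values: pd.DataFrame
    stage: str = RAW_STAGE

    def __post_init__(self) -> None:
        if self.stage not in (RAW_STAGE, NORMALIZED_STAGE):
            raise ValueError(f"unknown stage: {self.stage!r}")
        arr = self.values.to_numpy(dtype=float)
        if self.stage == NORMALIZED_STAGE and np.isnan(arr).any():
            raise ValueError("normalized matrix must not contain missing entries")
        with np.errstate(invalid="ignore"):
            if (arr < 0).any():
                raise ValueError("abundance values must be non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.stage)


def check_metadata(metadata: pd.DataFrame) -> None:
    """Validate the sample metadata schema and its structural invariants."""
    missing = set(METADATA_COLUMNS) - set(metadata.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    if metadata["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in metadata")
    if metadata.duplicated(subset=["plex", "channel"]).any():
        raise SchemaError("duplicate (plex, channel) pair in metadata")
    for plex, sub in metadata.groupby("plex"):
        if not sub["is_bridge"].any():
            raise SchemaError(f"plex {plex!r} has no bridge sample")


def bridge_samples(metadata: pd.DataFrame, plex: str) -> list[str]:
    sub = metadata[(metadata["plex"] == plex) & metadata["is_bridge"]]
    return list(sub["sample_id"])


def plex_samples(metadata: pd.DataFrame, plex: str) -> list[str]:
    return list(metadata.loc[metadata["plex"] == plex, "sample_id"])


@dataclass
class NormalizationReport:
    """Diagnostics comparing a matrix before and after bridge normalization."""

    column_medians: pd.DataFrame
    bridge_correlation: pd.DataFrame
    bridge_agreement: pd.DataFrame


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding of a distance matrix."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class PermanovaResult:
    """One-way PERMANOVA statistic and permutation p-value."""

    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None = None


@dataclass
class ClusterSet:
    """K-means partition of proteins with the objective trace of the winner."""

    k: int
    assignment: pd.Series  # protein_id -> cluster label (0..k-1)
    wcss: float
    objective_history: list[float]
    centers: np.ndarray | None = None
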