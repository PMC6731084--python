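"""Tab-separated readers and writers for the pipeline's table formats.

All files are UTF-8 TSV with a header row:

* PSM table: ``peptide, protein_id, plex, confidence, ambiguous,
  interference_pct, sn_<channel> x 10``
* sample metadata: ``sample_id, plex, channel, is_bridge, group,
  timepoint, replicate``
* abundance matrix: ``protein_id`` + one column per sample_id
* annotations: ``protein_id, source, taxon_order, eggnog_category, terms``
  (terms semicolon-separated)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from metaprot.datatypes import (
    ANNOTATION_COLUMNS,
    METADATA_COLUMNS,
    PSM_BASE_COLUMNS,
    AbundanceMatrix,
    SchemaError,
    check_metadata,
)


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{what} missing columns: {sorted(missing)}")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plex": str})
    _require(df, PSM_BASE_COLUMNS, "PSM table")
    if not any(c.startswith("sn_") for c in df.columns):
        raise SchemaError("PSM table has no sn_<channel> columns")
    df["ambiguous"] = df["ambiguous"].astype(bool)
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plex": str, "channel": str})
    _require(df, METADATA_COLUMNS, "sample metadata")
    df["is_bridge"] = df["is_bridge"].astype(bool)
    check_metadata(df)
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, stage: str) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "protein_id":
        raise SchemaError("matrix TSV must start with a protein_id column")
    df = df.set_index("protein_id")
    return AbundanceMatrix(df, stage=stage)


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="protein_id")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require(df, ANNOTATION_COLUMNS, "annotation table")
    if df["protein_id"].duplicated().any():
        raise SchemaError("duplicate protein_id in annotation table")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def terms_to_set(terms_field: str) -> set[str]:
    """Parse the semicolon-separated ``terms`` field of an annotation row."""
    if not terms_field or pd.isna(terms_field):
        return set()
    return {t for t in str(terms_field).split(";") if t}
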