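import dataclasses

import numpy as np
import pandas as pd
import pytest

from metaprot.datatypes import TMT10_CHANNELS, sn_column
from metaprot.ingest import aggregate_proteins, filter_psms, intersect_plexes
from metaprot.normalization import bridge_normalize
from metaprot.synthetic import StudyConfig, generate_study


def make_psms(rows: list[dict]) -> pd.DataFrame:
    """Build a PSM table from partial row dicts; S/N defaults to 20 everywhere."""
    out = []
    for i, row in enumerate(rows):
        full = {
            "peptide": f"PEP{i}",
            "protein_id": "P1",
            "plex": "1",
            "confidence": "high",
            "ambiguous": False,
            "interference_pct": 5.0,
        }
        sn = row.pop("sn", 20.0)
        for c in TMT10_CHANNELS:
            full[sn_column(c)] = sn if np.isscalar(sn) else None
        if not np.isscalar(sn):
            for c, v in zip(TMT10_CHANNELS, sn):
                full[sn_column(c)] = v
        full.update(row)
        out.append(full)
    return pd.DataFrame(out)


def quantify(study):
    """Filter -> aggregate -> intersect -> normalize a synthetic study."""
    filtered, _ = filter_psms(study.psms)
    raw = aggregate_proteins(filtered, study.metadata)
    raw = intersect_plexes(raw, study.metadata)
    return bridge_normalize(raw, study.metadata)


def biological_matrix(matrix, metadata):
    """Drop bridge columns from an abundance matrix."""
    bio = list(metadata.loc[~metadata["is_bridge"], "sample_id"])
    return dataclasses.replace(matrix, values=matrix.values[bio])


@pytest.fixture(scope="session")
def small_study():
    return generate_study(StudyConfig(n_proteins=300, seed=11))


@pytest.fixture(scope="session")
def small_normalized(small_study):
    return quantify(small_study)
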