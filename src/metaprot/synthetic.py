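"""Synthetic two-plex TMT 10-plex metaproteome study generator.

Emulates the statistical structure of a diet-induced-obesity fecal
metaproteome experiment: 16 biological samples (4 high- and 4
low-responder mice at an initial and a final timepoint) split 8 + 8
across two TMT 10-plexes, each plex carrying two pooled-standard bridge
aliquots in channels 126 and 131.  Reporter signal-to-noise is
multiplicative log-normal around true abundance times a per-plex batch
factor; planted, annotation-linked group effects and a ground-truth
ledger make recovery measurable end to end.  A stated fraction of PSMs
is generated to violate each QC rule so filtering is exercised.

No spectrum-level quantities (m/z, ion series) are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from metaprot.datatypes import (
    DEFAULT_BRIDGE_CHANNELS,
    TMT10_CHANNELS,
    sn_column,
)
from metaprot import io

GROUPS = ("high", "low")
TIMEPOINTS = ("initial", "final")
MICE_PER_GROUP = 4

#: Host-protein functional terms used for enrichment exercises.
HOST_TERM_POOL = (
    "immunoglobulin",
    "protease",
    "antimicrobial peptide",
    "mucin",
    "complement",
    "lipid metabolism",
    "cytoskeleton",
    "enzyme inhibitor",
    "glycoprotein",
    "secreted",
)

DEFAULT_TAXA = {
    "Clostridiales": 0.40,
    "Bacteroidales": 0.25,
    "Lactobacillales": 0.15,
    "Erysipelotrichales": 0.07,
    "Campylobacterales": 0.05,
    "Verrucomicrobiales": 0.04,
    "unassigned": 0.04,
}

DEFAULT_EGGNOG = {
    "Carbohydrate transport and metabolism": 0.16,
    "Translation, ribosomal structure and biogenesis": 0.14,
    "Amino acid transport and metabolism": 0.12,
    "Energy production and conversion": 0.12,
    "Function unknown": 0.10,
    "Cell wall/membrane/envelope biogenesis": 0.08,
    "Posttranslational modification, protein turnover, chaperones": 0.08,
    "Cell motility": 0.05,
    "Lipid transport and metabolism": 0.05,
    "Nucleotide transport and metabolism": 0.05,
    "Inorganic ion transport and metabolism": 0.05,
}

CONTRAST_NAMES = ("diet", "responder-initial", "responder-final")


class ConfigurationError(ValueError):
    """Invalid synthetic-study configuration."""


@dataclass(frozen=True)
class PlantedEffect:
    """A group effect planted on an annotation-selected protein subset.

    ``contrast`` names where the effect acts: ``diet`` multiplies all
    final-timepoint samples by 2**log2_effect, ``responder-initial`` /
    ``responder-final`` multiply the high-responder samples of that
    timepoint.  The selector (taxon / category / source, all optional,
    conjunctive) restricts eligibility; ``fraction_affected`` of the
    eligible proteins are drawn and recorded in the ground-truth ledger.
    """

    contrast: str
    log2_effect: float
    fraction_affected: float
    taxon: str | None = None
    category: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.contrast not in CONTRAST_NAMES:
            raise ConfigurationError(
                f"unknown contrast {self.contrast!r}; expected one of {CONTRAST_NAMES}"
            )
        if not 0.0 < self.fraction_affected <= 1.0:
            raise ConfigurationError("fraction_affected must lie in (0, 1]")


def default_effects() -> list[PlantedEffect]:
    """Effect structure mirroring the study's qualitative findings:
    Lactobacillales rise and Clostridiales/Bacteroidales fall after the
    obesogenic diet, with responder-linked microbial and host effects."""
    return [
        PlantedEffect("diet", +2.0, 0.5, taxon="Lactobacillales"),
        PlantedEffect("diet", -1.5, 0.3, taxon="Clostridiales"),
        PlantedEffect("diet", -1.5, 0.25, taxon="Bacteroidales"),
        PlantedEffect("responder-initial", +2.0, 0.2, taxon="Bacteroidales"),
        PlantedEffect("responder-final", +2.0, 0.3, taxon="Lactobacillales"),
        PlantedEffect("responder-final", +1.5, 0.2, source="host"),
    ]


@dataclass
class StudyConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated design: 2,000 proteins, two 10-plexes
    of 8 biological samples + 2 bridges each, log-normal reporter noise
    with sigma 0.25 (natural-log scale, ~25% CV), distinct per-plex batch
    factors, and small planted fractions of QC-failing PSMs.
    """

    n_proteins: int = 2000
    frac_host: float = 0.15
    taxa: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TAXA))
    eggnog_categories: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EGGNOG)
    )
    n_plexes: int = 2
    channels_per_plex: int = 10
    bridge_channels: tuple[str, ...] = DEFAULT_BRIDGE_CHANNELS
    effect_ledger: list[PlantedEffect] = field(default_factory=default_effects)
    noise_sigma: float = 0.25
    plex_factors: tuple[float, ...] = (1.0, 1.6)
    psm_per_protein: float = 3.0
    # abundance model: protein baselines are log-normal on the S/N scale
    abundance_mu: float = 3.5
    abundance_sigma: float = 1.0
    # planted QC-violation fractions (relative to the clean PSM count)
    frac_moderate_confidence: float = 0.03
    frac_ambiguous: float = 0.02
    frac_high_interference: float = 0.03
    frac_low_sn: float = 0.03
    interference_tail_max: float = 80.0
    # good PSM rows are rescaled to at least this mean S/N so they pass QC
    sn_floor: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be positive")
        if not 0.0 <= self.frac_host <= 1.0:
            raise ConfigurationError("frac_host must lie in [0, 1]")
        for name, weights in (("taxa", self.taxa), ("eggnog_categories", self.eggnog_categories)):
            if not weights:
                raise ConfigurationError(f"{name} must be non-empty")
            if abs(sum(weights.values()) - 1.0) > 1e-8:
                raise ConfigurationError(f"{name} weights must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ConfigurationError(f"{name} weights must be non-negative")
        if self.channels_per_plex != len(TMT10_CHANNELS):
            raise ConfigurationError("only TMT 10-plex channel layouts are supported")
        if not set(self.bridge_channels) <= set(TMT10_CHANNELS):
            raise ConfigurationError("bridge_channels must be TMT 10-plex channel labels")
        n_samples = 2 * MICE_PER_GROUP * len(TIMEPOINTS)
        per_plex = self.channels_per_plex - len(self.bridge_channels)
        if self.n_plexes * per_plex != n_samples:
            raise ConfigurationError(
                f"{self.n_plexes} plexes x {per_plex} sample channels cannot hold "
                f"the {n_samples}-sample design"
            )
        if len(self.plex_factors) != self.n_plexes:
            raise ConfigurationError("plex_factors must have one entry per plex")
        if any(f <= 0 for f in self.plex_factors):
            raise ConfigurationError("plex_factors must be positive")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        if self.psm_per_protein < 1:
            raise ConfigurationError("psm_per_protein must be >= 1")
        for eff in self.effect_ledger:
            if not isinstance(eff, PlantedEffect):
                raise ConfigurationError("effect_ledger entries must be PlantedEffect")


@dataclass
class SyntheticStudy:
    """Bundle returned by :func:`generate_study`."""

    psms: pd.DataFrame
    metadata: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame  # columns: contrast, protein_id, log2_effect
    true_abundance: pd.DataFrame  # proteins x 16 biological samples
    qc_violations: pd.DataFrame  # columns: peptide, rule
    config: StudyConfig


def build_metadata(config: StudyConfig) -> pd.DataFrame:
    """Sample sheet for the design: plexes balanced over (group, timepoint).

    Replicates 1 and 2 of every cell go to plex 1; replicates 3 and 4 to
    plex 2.  Sample ids follow the H/L + I/F + replicate convention
    (e.g. ``HI1`` = high responder, initial timepoint, mouse 1).
    """
    rows = []
    sample_channels = [c for c in TMT10_CHANNELS if c not in config.bridge_channels]
    per_plex = len(sample_channels)
    bio = [
        (g, t, r)
        for g in GROUPS
        for t in TIMEPOINTS
        for r in range(1, MICE_PER_GROUP + 1)
    ]
    # replicate parity determines the plex: balanced 2-per-cell split
    by_plex: dict[int, list[tuple[str, str, int]]] = {
        p: [] for p in range(1, config.n_plexes + 1)
    }
    for g, t, r in bio:
        plex = 1 + (r - 1) * config.n_plexes // MICE_PER_GROUP
        by_plex[plex].append((g, t, r))
    for plex, members in by_plex.items():
        assert len(members) == per_plex
        for channel, (g, t, r) in zip(sample_channels, members):
            rows.append(
                {
                    "sample_id": f"{g[0].upper()}{t[0].upper()}{r}",
                    "plex": str(plex),
                    "channel": channel,
                    "is_bridge": False,
                    "group": g,
                    "timepoint": t,
                    "replicate": r,
                }
            )
        for i, channel in enumerate(config.bridge_channels):
            rows.append(
                {
                    "sample_id": f"pool{plex}{chr(ord('a') + i)}",
                    "plex": str(plex),
                    "channel": channel,
                    "is_bridge": True,
                    "group": "pooled",
                    "timepoint": "pooled",
                    "replicate": 0,
                }
            )
    return pd.DataFrame(rows, columns=list(io.METADATA_COLUMNS))


def _draw_annotations(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    protein_ids = [f"PROT{i:05d}" for i in range(n)]
    is_host = rng.random(n) < config.frac_host
    taxa = list(config.taxa)
    taxon_p = np.array([config.taxa[t] for t in taxa])
    cats = list(config.eggnog_categories)
    cat_p = np.array([config.eggnog_categories[c] for c in cats])
    taxon = rng.choice(taxa, size=n, p=taxon_p / taxon_p.sum())
    category = rng.choice(cats, size=n, p=cat_p / cat_p.sum())
    terms = []
    for host in is_host:
        if host:
            k = int(rng.integers(1, 4))
            picks = rng.choice(HOST_TERM_POOL, size=k, replace=False)
            terms.append(";".join(sorted(picks)))
        else:
            terms.append("")
    return pd.DataFrame(
        {
            "protein_id": protein_ids,
            "source": np.where(is_host, "host", "microbial"),
            "taxon_order": np.where(is_host, "unassigned", taxon),
            "eggnog_category": category,
            "terms": terms,
        },
        columns=list(io.ANNOTATION_COLUMNS),
    )


def _effect_targets(
    effect: PlantedEffect, annotations: pd.DataFrame, rng: np.random.Generator
) -> list[str]:
    mask = pd.Series(True, index=annotations.index)
    if effect.taxon is not None:
        mask &= annotations["taxon_order"] == effect.taxon
    if effect.category is not None:
        mask &= annotations["eggnog_category"] == effect.category
    if effect.source is not None:
        mask &= annotations["source"] == effect.source
    eligible = list(annotations.loc[mask, "protein_id"])
    n_affected = int(round(effect.fraction_affected * len(eligible)))
    if n_affected == 0:
        return []
    return sorted(rng.choice(eligible, size=n_affected, replace=False))


def _affected_samples(contrast: str, metadata: pd.DataFrame) -> list[str]:
    bio = metadata[~metadata["is_bridge"]]
    if contrast == "diet":
        sel = bio["timepoint"] == "final"
    elif contrast == "responder-initial":
        sel = (bio["group"] == "high") & (bio["timepoint"] == "initial")
    else:  # responder-final
        sel = (bio["group"] == "high") & (bio["timepoint"] == "final")
    return list(bio.loc[sel, "sample_id"])


def _true_abundance(
    config: StudyConfig,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    bio_samples = list(metadata.loc[~metadata["is_bridge"], "sample_id"])
    base = rng.lognormal(config.abundance_mu, config.abundance_sigma, config.n_proteins)
    true = pd.DataFrame(
        np.tile(base[:, None], (1, len(bio_samples))),
        index=pd.Index(annotations["protein_id"], name="protein_id"),
        columns=bio_samples,
    )
    truth_rows = []
    for effect in config.effect_ledger:
        targets = _effect_targets(effect, annotations, rng)
        samples = _affected_samples(effect.contrast, metadata)
        true.loc[targets, samples] *= 2.0**effect.log2_effect
        for pid in targets:
            truth_rows.append(
                {
                    "contrast": effect.contrast,
                    "protein_id": pid,
                    "log2_effect": effect.log2_effect,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["contrast", "protein_id", "log2_effect"])
    return true, truth


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate PSM tables, metadata, annotations and a ground-truth ledger.

    Deterministic given ``config.seed``.  Bridge channels carry the pooled
    mean of all 16 biological samples' true abundances (the same pool in
    every plex, times that plex's batch factor) plus independent noise per
    bridge.  Clean PSM rows are rescaled to pass the QC filters; planted
    violator PSMs (listed in ``qc_violations``) each fail exactly one rule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotations = _draw_annotations(config, rng)
    metadata = build_metadata(config)
    true, truth = _true_abundance(config, annotations, metadata, rng)
    bridge_true = true.mean(axis=1).to_numpy()

    plexes = sorted(metadata["plex"].unique())
    sn_cols = [sn_column(c) for c in TMT10_CHANNELS]
    blocks: list[pd.DataFrame] = []
    psm_counter = 0
    for plex, factor in zip(plexes, config.plex_factors):
        sub = metadata[metadata["plex"] == plex]
        channel_samples = dict(zip(sub["channel"], sub["sample_id"]))
        n_psm = 1 + rng.poisson(config.psm_per_protein - 1.0, config.n_proteins)
        rows = np.repeat(np.arange(config.n_proteins), n_psm)
        per_psm_scale = (factor / n_psm)[rows]
        sn = np.empty((len(rows), len(TMT10_CHANNELS)))
        for j, channel in enumerate(TMT10_CHANNELS):
            if channel in config.bridge_channels:
                base = bridge_true[rows]
            else:
                base = true[channel_samples[channel]].to_numpy()[rows]
            if config.noise_sigma > 0:
                noise = np.exp(rng.normal(0.0, config.noise_sigma, len(rows)))
            else:
                noise = 1.0
            sn[:, j] = base * per_psm_scale * noise
        # rescale weak rows up to the QC floor; a common row factor leaves
        # bridge ratios (hence everything downstream of normalization) intact
        mean_sn = sn.mean(axis=1)
        weak = mean_sn < config.sn_floor
        sn[weak] *= (config.sn_floor / mean_sn[weak])[:, None]
        block = pd.DataFrame(sn, columns=sn_cols)
        block.insert(0, "interference_pct", rng.uniform(0.0, 25.0, len(rows)))
        block.insert(0, "ambiguous", False)
        block.insert(0, "confidence", "high")
        block.insert(0, "plex", str(plex))
        block.insert(0, "protein_id", annotations["protein_id"].to_numpy()[rows])
        block.insert(
            0,
            "peptide",
            [f"PEP{psm_counter + i:07d}" for i in range(len(rows))],
        )
        psm_counter += len(rows)
        blocks.append(block)

    clean = pd.concat(blocks, ignore_index=True)
    n_clean = len(clean)

    # planted QC violators: each fails exactly one rule
    violation_fracs = {
        "confidence": config.frac_moderate_confidence,
        "ambiguous": config.frac_ambiguous,
        "interference": config.frac_high_interference,
        "low_sn": config.frac_low_sn,
    }
    bad_blocks = []
    violation_rows = []
    for rule, frac in violation_fracs.items():
        n_bad = int(round(frac * n_clean))
        if n_bad == 0:
            continue
        picks = rng.integers(0, n_clean, n_bad)
        bad = clean.iloc[picks].copy().reset_index(drop=True)
        bad["peptide"] = [f"PEP{psm_counter + i:07d}" for i in range(n_bad)]
        psm_counter += n_bad
        # distort the quantitation so unfiltered violators would bias results
        bad[sn_cols] = bad[sn_cols].to_numpy() * np.exp(
            rng.normal(0.0, 1.0, (n_bad, 1))
        )
        mean_sn = bad[sn_cols].mean(axis=1).to_numpy()
        if rule == "low_sn":
            target = rng.uniform(2.0, 9.5, n_bad)
        else:
            target = np.maximum(mean_sn, config.sn_floor)
        bad[sn_cols] = bad[sn_cols].to_numpy() * (target / mean_sn)[:, None]
        if rule == "confidence":
            bad["confidence"] = rng.choice(["moderate", "low"], size=n_bad, p=[0.8, 0.2])
        elif rule == "ambiguous":
            bad["ambiguous"] = True
        elif rule == "interference":
            bad["interference_pct"] = rng.uniform(
                25.0 + 1e-6, config.interference_tail_max, n_bad
            )
        bad_blocks.append(bad)
        violation_rows.extend({"peptide": p, "rule": rule} for p in bad["peptide"])

    psms = pd.concat([clean, *bad_blocks], ignore_index=True)
    order = rng.permutation(len(psms))
    psms = psms.iloc[order].reset_index(drop=True)
    qc_violations = pd.DataFrame(violation_rows, columns=["peptide", "rule"])
    return SyntheticStudy(
        psms=psms,
        metadata=metadata,
        annotations=annotations,
        truth=truth,
        true_abundance=true,
        qc_violations=qc_violations,
        config=config,
    )


def write_fixture(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as the pipeline's TSV formats; round-trips losslessly.

    Returns the mapping of table name to file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": directory / "psms.tsv",
        "metadata": directory / "metadata.tsv",
        "annotations": directory / "annotations.tsv",
        "truth": directory / "truth.tsv",
        "true_abundance": directory / "true_abundance.tsv",
        "qc_violations": directory / "qc_violations.tsv",
    }
    io.write_psm_table(study.psms, paths["psms"])
    io.write_sample_metadata(study.metadata, paths["metadata"])
    io.write_annotations(study.annotations, paths["annotations"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    study.true_abundance.to_csv(paths["true_abundance"], sep="\t", index_label="protein_id")
    study.qc_violations.to_csv(paths["qc_violations"], sep="\t", index=False)
    return paths
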