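"""End-to-end orchestration: ingest, normalize, test, annotate, ordinate.

A single YAML config drives the run.  It either names input TSVs
(``inputs: {psms, metadata, annotations}``) or carries a ``synthetic``
block with :class:`~metaprot.synthetic.StudyConfig` fields.  Every stage
writes its table into the run directory and the manifest records
parameters, seeds, per-stage row counts and SHA-256 hashes of all
outputs, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metaprot import io
from metaprot.annotation import functional_bias, taxonomic_composition, term_enrichment
from metaprot.datatypes import FilterParams, SchemaError, check_metadata
from metaprot.differential import differential_test, significant_sets, volcano_table
from metaprot.ingest import aggregate_proteins, filter_psms, intersect_plexes
from metaprot.multivariate import (
    bray_curtis,
    cluster_bias,
    kmeans_proteins,
    pcoa,
    permanova,
)
from metaprot.normalization import bridge_normalize, normalization_report
from metaprot.synthetic import PlantedEffect, StudyConfig, generate_study, write_fixture

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS = ("final-vs-initial", "high-vs-low@initial", "high-vs-low@final")


class ValidationError(ValueError):
    """Pipeline configuration or input validation failed."""

    def __init__(self, issues: list[str]):
        super().__init__("; ".join(issues))
        self.issues = issues


def load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise ValidationError(["config file does not hold a mapping"])
        return loaded
    return dict(config)


def study_config_from_dict(block: dict, seed: int | None = None) -> StudyConfig:
    """Build a StudyConfig from a flat config mapping."""
    block = dict(block)
    effects = block.pop("effect_ledger", None)
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(block) - valid
    if unknown:
        raise ValidationError([f"unknown synthetic config key(s): {sorted(unknown)}"])
    kwargs.update(block)
    for key in ("plex_factors", "bridge_channels"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if effects is not None:
        kwargs["effect_ledger"] = [
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e) for e in effects
        ]
    if seed is not None:
        kwargs["seed"] = seed
    cfg = StudyConfig(**kwargs)
    cfg.validate()
    return cfg


def derive_seeds(config: dict) -> dict[str, int]:
    """Generator / PERMANOVA / K-means seeds, derived from a master seed
    when not given explicitly."""
    master = int(config.get("seed", 0))
    seeds = dict(config.get("seeds", {}))
    derived = np.random.SeedSequence(master).generate_state(3)
    defaults = {
        "generator": int(derived[0] % 2**31),
        "permanova": int(derived[1] % 2**31),
        "kmeans": int(derived[2] % 2**31),
    }
    return {k: int(seeds.get(k, defaults[k])) for k in defaults}


def validate_inputs(config: str | Path | dict) -> list[str]:
    """Check the config and all referenced tables; returns the issue list."""
    issues: list[str] = []
    try:
        cfg = load_config(config)
    except ValidationError as exc:
        return list(exc.issues)
    has_inputs = "inputs" in cfg
    has_synth = "synthetic" in cfg
    if has_inputs == has_synth:
        issues.append("config must name exactly one of 'inputs' or 'synthetic'")
        return issues
    if has_synth:
        try:
            study_config_from_dict(cfg["synthetic"])
        except (ValidationError, ValueError, TypeError) as exc:
            issues.append(f"synthetic block invalid: {exc}")
        return issues

    inputs = cfg["inputs"]
    for key in ("psms", "metadata", "annotations"):
        if key not in inputs:
            issues.append(f"inputs missing {key!r}")
        elif not Path(inputs[key]).is_file():
            issues.append(f"input file not found: {inputs[key]}")
    if issues:
        return issues
    try:
        metadata = io.read_sample_metadata(inputs["metadata"])
    except (SchemaError, ValueError) as exc:
        issues.append(f"metadata: {exc}")
        return issues
    try:
        psms = io.read_psm_table(inputs["psms"])
    except (SchemaError, ValueError) as exc:
        issues.append(f"PSM table: {exc}")
        return issues
    try:
        io.read_annotations(inputs["annotations"])
    except (SchemaError, ValueError) as exc:
        issues.append(f"annotations: {exc}")
    known = set(zip(metadata["plex"], metadata["channel"]))
    psm_channels = [c.removeprefix("sn_") for c in psms.columns if c.startswith("sn_")]
    for plex in psms["plex"].unique():
        for channel in psm_channels:
            if (str(plex), channel) not in known:
                issues.append(f"plex {plex!r} channel {channel!r} has no metadata row")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label)


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Execute ingest -> normalize -> differential -> annotation -> multivariate.

    Returns the manifest (also written as ``manifest.json``).  On stage
    failure a ``FAILED`` marker naming the stage is left in the run
    directory alongside any partial outputs, and the error is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config)
    issues = validate_inputs(cfg)
    if issues:
        raise ValidationError(issues)
    seeds = derive_seeds(cfg)
    counts: dict[str, object] = {}
    stage = "setup"
    try:
        # --- ingest ---------------------------------------------------
        stage = "ingest"
        if "synthetic" in cfg:
            study_cfg = study_config_from_dict(
                cfg["synthetic"], seed=cfg["synthetic"].get("seed", seeds["generator"])
            )
            study = generate_study(study_cfg)
            write_fixture(study, out / "inputs")
            psms, metadata, annotations = study.psms, study.metadata, study.annotations
        else:
            psms = io.read_psm_table(cfg["inputs"]["psms"])
            metadata = io.read_sample_metadata(cfg["inputs"]["metadata"])
            annotations = io.read_annotations(cfg["inputs"]["annotations"])
        check_metadata(metadata)
        counts["psms_in"] = len(psms)

        stage = "filter"
        params = FilterParams(**cfg.get("filter", {}))
        filtered, removal = filter_psms(psms, params)
        counts["psms_removed_per_rule"] = removal
        counts["psms_retained"] = len(filtered)

        stage = "aggregate"
        raw = aggregate_proteins(filtered, metadata)
        counts["proteins_quantified"] = len(raw.protein_ids)
        io.write_matrix(raw, out / "raw_matrix.tsv")

        stage = "intersect"
        n_plexes = metadata["plex"].nunique()
        if n_plexes >= 2:
            raw = intersect_plexes(raw, metadata)
        counts["proteins_in_all_plexes"] = len(raw.protein_ids)
        io.write_matrix(raw, out / "intersected_matrix.tsv")

        # --- normalize ------------------------------------------------
        stage = "normalize"
        norm_cfg = cfg.get("normalization", {})
        normalized = bridge_normalize(
            raw,
            metadata,
            bridge_mean=norm_cfg.get("bridge_mean", "arithmetic"),
            column_correction=norm_cfg.get("column_correction", "per_sample"),
        )
        io.write_matrix(normalized, out / "normalized_matrix.tsv")
        report = normalization_report(raw, normalized, metadata)
        _write(report.column_medians, out / "normalization_column_medians.tsv",
               index=True, index_label="sample_id")
        _write(report.bridge_agreement, out / "normalization_bridge_agreement.tsv")

        # --- differential ---------------------------------------------
        stage = "differential"
        diff_cfg = cfg.get("differential", {})
        threshold = float(diff_cfg.get("threshold", 1.0))
        contrasts = list(diff_cfg.get("contrasts", DEFAULT_CONTRASTS))
        diff_tables: dict[str, pd.DataFrame] = {}
        sig_counts = {}
        for contrast in contrasts:
            diff = differential_test(
                normalized,
                metadata,
                contrast,
                threshold=threshold,
                equal_var=diff_cfg.get("equal_var", True),
                log2_input=diff_cfg.get("log2_input", False),
            )
            diff_tables[contrast] = diff
            safe = contrast.replace("@", "_at_")
            _write(diff, out / f"differential_{safe}.tsv", index=True,
                   index_label="protein_id")
            _write(volcano_table(diff), out / f"volcano_{safe}.tsv", index=True,
                   index_label="protein_id")
            sig_counts[contrast] = int(diff["significant"].sum())
        counts["significant_per_contrast"] = sig_counts

        # --- annotation stats -----------------------------------------
        stage = "annotation_stats"
        primary = contrasts[0]
        enriched, depleted = significant_sets(diff_tables[primary])
        if enriched and depleted:
            comp_e = taxonomic_composition(enriched, annotations)
            comp_d = taxonomic_composition(depleted, annotations)
            _write(comp_e.rename("proportion").reset_index(), out / "taxonomy_enriched.tsv")
            _write(comp_d.rename("proportion").reset_index(), out / "taxonomy_depleted.tsv")
            bias = functional_bias(enriched, depleted, annotations)
            _write(bias, out / "functional_bias.tsv", index=True)
        ann_idx = annotations.set_index("protein_id")
        host_bg = [
            p for p in normalized.protein_ids
            if p in ann_idx.index and ann_idx.loc[p, "source"] == "host"
        ]
        host_fg = [p for p in enriched + depleted if p in set(host_bg)]
        counts["host_background"] = len(host_bg)
        counts["host_significant"] = len(host_fg)
        if host_fg:
            enr = term_enrichment(host_fg, host_bg, annotations)
            _write(enr, out / "host_term_enrichment.tsv")

        # --- multivariate ---------------------------------------------
        stage = "multivariate"
        mv_cfg = cfg.get("multivariate", {})
        bio_samples = list(metadata.loc[~metadata["is_bridge"], "sample_id"])
        bio_matrix = dataclasses.replace(
            normalized, values=normalized.values[bio_samples]
        )
        dm = bray_curtis(bio_matrix)
        _write(pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
               out / "bray_curtis.tsv", index=True, index_label="sample_id")
        ordination = pcoa(dm, n_axes=mv_cfg.get("n_axes"))
        _write(ordination.coordinates, out / "pcoa_coordinates.tsv", index=True,
               index_label="sample_id")
        grouping_col = mv_cfg.get("permanova_grouping", "timepoint")
        grouping = (
            metadata.set_index("sample_id").loc[bio_samples, grouping_col].tolist()
        )
        perm = permanova(
            dm,
            grouping,
            n_permutations=int(mv_cfg.get("permutations", 999)),
            seed=seeds["permanova"],
        )
        counts["permanova"] = {
            "grouping": grouping_col,
            "pseudo_F": perm.pseudo_F,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations,
        }
        clusters = kmeans_proteins(
            bio_matrix,
            k=int(mv_cfg.get("k", 6)),
            seed=seeds["kmeans"],
            n_restarts=int(mv_cfg.get("n_restarts", 10)),
        )
        _write(clusters.assignment.reset_index(), out / "kmeans_assignment.tsv")
        counts["kmeans_wcss"] = clusters.wcss
        bias_table = cluster_bias(clusters, annotations)
        _write(bias_table, out / "cluster_bias.tsv")
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n", encoding="utf-8")
        log.exception("pipeline failed at stage %s", stage)
        raise

    stage = "manifest"
    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": cfg,
        "seeds": seeds,
        "counts": counts,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
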