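"""Configuration-driven orchestration of the microarray, methylation and
single-cell analyses, with a run manifest for provenance."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from .cohort import correlation_matrix, median_split, quartile_split, wilcoxon_compare, p_stars
from .enrichment import (
    GeneSetCollection,
    differential_enrichment,
    filter_gene_set_names,
    gsva_scores,
    updown_summary,
)
from .matrix import SampleMatrix
from .quantification import aggregate_rte_scores, collapse_duplicate_features
from .signatures import read_gmt, score_all
from .single_cell import (
    CellAnnotation,
    celltype_contrast,
    combined_rpm,
    pseudo_bulk,
    pseudobulk_signature_scores,
    read_cell_counts_mtx,
)
from .taxonomy import DEFAULT_TAXONOMY

logger = logging.getLogger(__name__)

TOOL_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run; YAML-serialisable."""

    out_dir: str = "results"
    seed: int = 0
    level: str = "class"  # or "family"
    group_mode: str = "quartile"  # or "median"
    logfc_threshold: float = 0.1
    p_threshold: float = 0.05
    # annotation inputs
    repeats_path: str | None = None
    repeats_format: str = "bed"
    genes_path: str | None = None
    probes_path: str | None = None
    # cohort inputs
    expression_path: str | None = None
    methylation_path: str | None = None
    samples_path: str | None = None  # TSV with sample_id, age
    signatures_gmt: str | None = None
    enrichment_gmt: str | None = None
    enrichment_categories: str | None = None
    # single-cell inputs
    sc_mtx: str | None = None
    sc_features: str | None = None
    sc_barcodes: str | None = None
    sc_counts_tsv: str | None = None
    sc_annotation: str | None = None
    sc_grouping_signature: str = "SASP"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str = TOOL_VERSION
    config_hash: str = ""
    started: float = 0.0
    finished: float = 0.0
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, stage: str, rows_in: int, rows_out: int, warnings: list[str] | None = None) -> None:
        self.stages.append(
            {"stage": stage, "rows_in": rows_in, "rows_out": rows_out, "warnings": warnings or []}
        )
        logger.info("stage=%s rows_in=%d rows_out=%d", stage, rows_in, rows_out)

    def write(self, path: str | Path) -> None:
        """Atomic write: the manifest only appears once the run has ended."""
        self.finished = time.time()
        tmp = Path(str(path) + ".tmp")
        with open(tmp, "w") as fh:
            json.dump(
                {
                    "tool_version": self.tool_version,
                    "config_hash": self.config_hash,
                    "started": self.started,
                    "finished": self.finished,
                    "input_checksums": self.input_checksums,
                    "stages": self.stages,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        os.replace(tmp, path)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(config: PipelineConfig, *names: str) -> None:
    for name in names:
        value = getattr(config, name)
        if value is None:
            raise ValueError(f"pipeline config is missing required input {name!r}")
        if not Path(value).exists():
            raise FileNotFoundError(f"input {name} does not exist: {value}")


def _start_manifest(config: PipelineConfig, inputs: list[str]) -> RunManifest:
    manifest = RunManifest(config_hash=config.config_hash(), started=time.time())
    for name in inputs:
        value = getattr(config, name)
        if value is not None and Path(value).exists():
            manifest.input_checksums[name] = _checksum(value)
    return manifest


def _read_ages(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return pd.Series(df["age"].to_numpy(dtype=float), index=df["sample_id"], name="age")


def _assign(config: PipelineConfig):
    repeats = ann.parse_repeatmasker(config.repeats_path, format=config.repeats_format)
    genes = ann.read_gene_models(config.genes_path)
    probes = ann.read_probe_manifest(config.probes_path)
    probes = ann.annotate_probe_contexts(probes, genes)
    return ann.assign_probes_to_repeats(probes, repeats), probes


def _split_per_rte(scores, mode: str):
    split = quartile_split if mode == "quartile" else median_split
    groupings = {}
    for rte in scores.scores.index:
        groupings[rte] = split(scores.scores.loc[rte], basis=rte)
    return groupings


def run_microarray(config: PipelineConfig) -> dict[str, Path]:
    """Full microarray expression analysis on one cohort.

    Emits probe assignments, RTE class and family score matrices, signature
    scores, per-RTE-group stratifications, the all-pairs correlation table,
    GSVA enrichment scores with per-group differential calls and the
    up-minus-down radar table, plus a run manifest.
    """
    _require(config, "repeats_path", "genes_path", "probes_path", "expression_path",
             "samples_path", "signatures_gmt")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _start_manifest(
        config,
        ["repeats_path", "genes_path", "probes_path", "expression_path", "samples_path",
         "signatures_gmt", "enrichment_gmt", "enrichment_categories"],
    )
    outputs: dict[str, Path] = {}
    stage = "assign_probes"
    try:
        assignments, probes = _assign(config)
        manifest.add_stage(stage, len(probes), len(assignments))
        outputs["assignments"] = outdir / "probe_assignments.tsv"
        ann.write_assignments_tsv(assignments, outputs["assignments"])
        outputs["assigned_bed"] = outdir / "assigned_probes.bed"
        ann.write_assigned_probes_bed(assignments, outputs["assigned_bed"])

        stage = "expression_matrix"
        matrix = collapse_duplicate_features(
            SampleMatrix.from_tsv(config.expression_path, "log2_expression")
        )
        ages = _read_ages(config.samples_path)
        shared = [s for s in matrix.sample_ids if s in ages.index]
        dropped = len(matrix.sample_ids) - len(shared)
        if dropped:
            logger.warning("%d samples without age metadata dropped", dropped)
        matrix = SampleMatrix(matrix.data[shared], matrix.value_kind)
        ages = ages.loc[shared]
        manifest.add_stage(stage, len(matrix.feature_ids), len(shared))

        stage = "rte_scores"
        per_level = {}
        for level in ("class", "family"):
            scores = aggregate_rte_scores(matrix, assignments, level=level)
            per_level[level] = scores
            outputs[f"rte_scores_{level}"] = outdir / f"rte_scores_{level}.tsv"
            scores.to_tsv(outputs[f"rte_scores_{level}"])
        manifest.add_stage(stage, len(assignments),
                           sum(len(s.scores) for s in per_level.values()))

        stage = "signature_scores"
        signatures = read_gmt(config.signatures_gmt)
        sig_scores = score_all(matrix, signatures)
        outputs["signature_scores"] = outdir / "signature_scores.tsv"
        sig_scores.to_tsv(outputs["signature_scores"])
        outputs["missing_genes"] = outdir / "signature_missing_genes.tsv"
        sig_scores.missing_report().to_csv(outputs["missing_genes"], sep="\t", index=False)
        manifest.add_stage(stage, len(signatures), len(sig_scores.scores))

        stage = "stratification"
        level_scores = per_level[config.level]
        groupings = _split_per_rte(level_scores, config.group_mode)
        grouping_frames = [g.to_frame() for g in groupings.values()]
        outputs["groupings"] = outdir / "rte_groupings.tsv"
        pd.concat(grouping_frames).to_csv(outputs["groupings"], sep="\t", index=False)
        manifest.add_stage(stage, len(level_scores.scores), len(groupings))

        stage = "correlations"
        variables = pd.DataFrame({"age": ages})
        for rte in per_level["class"].scores.index:
            variables[f"{rte}_expression"] = per_level["class"].scores.loc[rte]
        for sig in sig_scores.scores.index:
            variables[str(sig)] = sig_scores.scores.loc[sig]
        corr = correlation_matrix(variables)
        outputs["correlations"] = outdir / "correlation_table.tsv"
        corr.to_csv(outputs["correlations"], sep="\t", index=False)
        manifest.add_stage(stage, variables.shape[1], len(corr))

        if config.enrichment_gmt:
            stage = "enrichment"
            coll = GeneSetCollection.from_gmt(config.enrichment_gmt, config.enrichment_categories)
            kept = set(filter_gene_set_names([s.name for s in coll.sets]))
            coll = GeneSetCollection([s for s in coll.sets if s.name in kept],
                                     {k: v for k, v in coll.categories.items() if k in kept})
            es = gsva_scores(matrix, coll)
            outputs["enrichment_scores"] = outdir / "enrichment_scores.tsv"
            es.to_csv(outputs["enrichment_scores"], sep="\t", index_label="set")
            diffs = {}
            for rte, grouping in groupings.items():
                diffs[rte] = differential_enrichment(
                    es, grouping, coll.categories,
                    logfc_threshold=config.logfc_threshold, p_threshold=config.p_threshold,
                )
                out = outdir / f"differential_enrichment_{rte}.tsv"
                outputs[f"differential_{rte}"] = out
                diffs[rte].to_tsv(out)
            radar = updown_summary(diffs)
            outputs["radar"] = outdir / "updown_radar.tsv"
            radar.to_csv(outputs["radar"], sep="\t", index=False)
            manifest.add_stage(stage, len(coll.sets), len(radar))
    except Exception as exc:
        raise RuntimeError(
            f"microarray pipeline failed at stage {stage!r}: {exc}"
        ) from exc
    finally:
        manifest.write(outdir / "run_manifest.json")
    outputs["manifest"] = outdir / "run_manifest.json"
    return outputs


def run_methylation(config: PipelineConfig) -> dict[str, Path]:
    """Methylation analysis: RTE beta scores, age correlations, and — when a
    matched expression matrix is supplied — methylation-by-expression-group
    rank-sum contrasts."""
    _require(config, "repeats_path", "genes_path", "probes_path", "methylation_path", "samples_path")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _start_manifest(
        config,
        ["repeats_path", "genes_path", "probes_path", "methylation_path",
         "expression_path", "samples_path"],
    )
    outputs: dict[str, Path] = {}
    stage = "assign_probes"
    try:
        assignments, probes = _assign(config)
        manifest.add_stage(stage, len(probes), len(assignments))

        stage = "methylation_matrix"
        betas = collapse_duplicate_features(
            SampleMatrix.from_tsv(config.methylation_path, "beta_methylation")
        )
        ages = _read_ages(config.samples_path)
        shared = [s for s in betas.sample_ids if s in ages.index]
        betas = SampleMatrix(betas.data[shared], "beta_methylation")
        ages = ages.loc[shared]
        manifest.add_stage(stage, len(betas.feature_ids), len(shared))

        stage = "rte_methylation_scores"
        per_level = {}
        for level in ("class", "family"):
            scores = aggregate_rte_scores(betas, assignments, level=level)
            per_level[level] = scores
            outputs[f"methylation_scores_{level}"] = outdir / f"methylation_scores_{level}.tsv"
            scores.to_tsv(outputs[f"methylation_scores_{level}"])
        manifest.add_stage(stage, len(assignments),
                           sum(len(s.scores) for s in per_level.values()))

        stage = "age_correlations"
        variables = pd.DataFrame({"age": ages})
        for level in ("class", "family"):
            for rte in per_level[level].scores.index:
                col = f"{rte}_methylation"
                if col not in variables:
                    variables[col] = per_level[level].scores.loc[rte]
        corr = correlation_matrix(variables)
        outputs["age_correlations"] = outdir / "methylation_age_correlations.tsv"
        corr.to_csv(outputs["age_correlations"], sep="\t", index=False)
        manifest.add_stage(stage, variables.shape[1], len(corr))

        if config.expression_path:
            stage = "expression_group_contrasts"
            expr = collapse_duplicate_features(
                SampleMatrix.from_tsv(config.expression_path, "log2_expression")
            )
            shared = [s for s in expr.sample_ids if s in betas.sample_ids]
            n_dropped = (len(expr.sample_ids) - len(shared)) + (len(betas.sample_ids) - len(shared))
            if n_dropped:
                logger.warning("%d unmatched samples dropped from the matched contrast", n_dropped)
            expr = SampleMatrix(expr.data[shared], "log2_expression")
            expr_scores = aggregate_rte_scores(expr, assignments, level=config.level)
            meth_scores = per_level[config.level]
            rows = []
            for rte in expr_scores.scores.index:
                if rte not in meth_scores.scores.index:
                    continue
                grouping = quartile_split(expr_scores.scores.loc[rte], basis=rte)
                meth = meth_scores.scores.loc[rte, shared]
                stat, p = wilcoxon_compare(
                    meth[grouping.samples("high")], meth[grouping.samples("low")]
                )
                rows.append({"rte_group": rte, "statistic": stat, "p": p, "stars": p_stars(p)})
            table = pd.DataFrame(rows, columns=["rte_group", "statistic", "p", "stars"])
            outputs["methylation_by_expression"] = outdir / "methylation_by_expression_group.tsv"
            table.to_csv(outputs["methylation_by_expression"], sep="\t", index=False)
            manifest.add_stage(stage, len(expr_scores.scores), len(table))
    except Exception as exc:
        raise RuntimeError(
            f"methylation pipeline failed at stage {stage!r}: {exc}"
        ) from exc
    finally:
        manifest.write(outdir / "methylation_run_manifest.json")
    outputs["manifest"] = outdir / "methylation_run_manifest.json"
    return outputs


def run_single_cell(config: PipelineConfig) -> dict[str, Path]:
    """Single-cell analysis: pseudo-bulk, combined-denominator RPM, sample-level
    signature scores, median grouping and per-cell-type RTE contrasts."""
    _require(config, "sc_annotation", "signatures_gmt")
    if config.sc_counts_tsv is None:
        _require(config, "sc_mtx", "sc_features", "sc_barcodes")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _start_manifest(
        config, ["sc_mtx", "sc_features", "sc_barcodes", "sc_counts_tsv", "sc_annotation",
                 "signatures_gmt"]
    )
    outputs: dict[str, Path] = {}
    stage = "read_counts"
    try:
        if config.sc_counts_tsv is not None:
            counts = pd.read_csv(config.sc_counts_tsv, sep="\t", index_col=0)
        else:
            counts = read_cell_counts_mtx(config.sc_mtx, config.sc_features, config.sc_barcodes)
        cells = CellAnnotation.from_tsv(config.sc_annotation)
        manifest.add_stage(stage, counts.shape[0], counts.shape[1])

        stage = "pseudo_bulk"
        pb = pseudo_bulk(counts, cells)
        outputs["pseudobulk_counts"] = outdir / "pseudobulk_counts.tsv"
        pb.to_tsv(outputs["pseudobulk_counts"])
        rpm = combined_rpm(pb)
        outputs["pseudobulk_rpm"] = outdir / "pseudobulk_rpm.tsv"
        rpm.to_tsv(outputs["pseudobulk_rpm"])
        manifest.add_stage(stage, counts.shape[1], pb.data.shape[1])

        stage = "signature_scores"
        signatures = read_gmt(config.signatures_gmt)
        sig_scores = pseudobulk_signature_scores(counts, cells, signatures)
        outputs["signature_scores"] = outdir / "sc_signature_scores.tsv"
        sig_scores.to_tsv(outputs["signature_scores"])
        manifest.add_stage(stage, len(signatures), len(sig_scores.scores))

        stage = "contrasts"
        basis = config.sc_grouping_signature
        if basis not in sig_scores.scores.index:
            raise ValueError(f"grouping signature {basis!r} not among scored signatures")
        grouping = median_split(sig_scores.scores.loc[basis], basis=basis)
        outputs["grouping"] = outdir / "sc_grouping.tsv"
        grouping.to_tsv(outputs["grouping"])
        contrasts = celltype_contrast(rpm, grouping)
        outputs["contrasts"] = outdir / "celltype_contrasts.tsv"
        contrasts.to_csv(outputs["contrasts"], sep="\t", index=False)
        manifest.add_stage(stage, rpm.data.shape[1], len(contrasts))
    except Exception as exc:
        raise RuntimeError(
            f"single-cell pipeline failed at stage {stage!r}: {exc}"
        ) from exc
    finally:
        manifest.write(outdir / "sc_run_manifest.json")
    outputs["manifest"] = outdir / "sc_run_manifest.json"
    return outputs
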