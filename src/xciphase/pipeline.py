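"""End-to-end pipeline: (simulate) -> filter -> phase -> classify -> escape -> dosage.

A single entry point wiring the stages together with provenance: every run
writes its outputs plus a machine-readable manifest (config echo, seed,
chosen coverage cutoff, stage list) sufficient to reproduce the run
byte-identically.  All stages are deterministic; the only randomness is the
simulator's, driven by the root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from xciphase.classification import (
    CellClassification,
    IterationConfig,
    iterate_cutoffs,
    score_against_truth,
)
from xciphase.core_matrix import BaseCountMatrix, build_allele_calls, read_matrix, write_matrix
from xciphase.dosage import dosage_summary, x_autosome_ratio
from xciphase.escape_inference import (
    EscapeConfig,
    GeneAnnotation,
    escape_calls_to_tsv,
    infer_escape_genes,
    infer_escape_sites,
)
from xciphase.linkage_phasing import (
    PhasingConfig,
    build_fragments,
    find_linkages,
    fragments_to_tsv,
)
from xciphase.simulator import SimConfig, SimTruth, simulate_matrix, write_truth
from xciphase.site_filtering import FilterConfig, filter_sites

logger = logging.getLogger(__name__)

_version = "0.1.0"

STAGES = ("simulate", "filter", "phase", "classify", "escape", "dosage", "evaluate")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``matrix_path`` or ``sim`` must be set; the simulator's
    seed is overridden by the run's root ``seed``.
    """

    out_dir: Path
    matrix_path: Optional[Path] = None
    matrix_format: str = "tsv-sparse"
    sim: Optional[SimConfig] = None
    reference_path: Optional[Path] = None
    annotation_path: Optional[Path] = None
    dosage_counts_path: Optional[Path] = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    phasing_cfg: PhasingConfig = field(default_factory=PhasingConfig)
    iter_cfg: IterationConfig = field(default_factory=IterationConfig)
    escape_cfg: EscapeConfig = field(default_factory=EscapeConfig)
    overlap_threshold: float = 0.5
    seed: int = 0
    stop_after: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.matrix_path is None) == (self.sim is None):
            raise ValueError("exactly one of matrix_path or sim must be given")
        if self.stop_after is not None and self.stop_after not in STAGES:
            raise ValueError(f"unknown stage {self.stop_after!r}")
        for attr in ("matrix_path", "reference_path", "annotation_path", "dosage_counts_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    matrix: BaseCountMatrix
    truth: Optional[SimTruth] = None
    classification: Optional[CellClassification] = None
    escape_calls: Optional[list] = None
    escape_genes: Optional[dict] = None
    accuracy: Optional[float] = None
    manifest: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_echo(cfg: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in vars(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    return encode(cfg)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the configured stages, writing outputs and a manifest to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "xciphase",
        "version": _version,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "stages_completed": [],
        "partial": False,
    }
    result = PipelineResult(out_dir=out, matrix=None, manifest=manifest)

    def done(stage: str) -> bool:
        manifest["stages_completed"].append(stage)
        if cfg.stop_after == stage:
            manifest["partial"] = True
            return True
        return False

    def finish() -> PipelineResult:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return result

    # --- simulate / load -------------------------------------------------
    truth: Optional[SimTruth] = None
    try:
        if cfg.sim is not None:
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            matrix, truth = simulate_matrix(sim_cfg)
            write_matrix(matrix, out / "matrix.tsv", "tsv-sparse")
            write_truth(truth, out)
        else:
            matrix = read_matrix(cfg.matrix_path, cfg.matrix_format)
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    result.matrix, result.truth = matrix, truth
    if cfg.sim is not None and done("simulate"):
        return finish()

    reference = None
    if cfg.reference_path is not None:
        from pyfaidx import Fasta

        reference = Fasta(str(cfg.reference_path))

    # --- filter (full-matrix pass; cutoff reruns refilter internally) ----
    try:
        _, all_sites = build_allele_calls(matrix)
        filtered, report = filter_sites(matrix, all_sites, reference, cfg.filter_cfg)
        write_matrix(filtered, out / "matrix.filtered.tsv", "tsv-sparse")
        report.to_tsv(out / "filter_report.tsv")
        manifest["filter_summary"] = report.summary()
    except Exception as exc:
        raise StageError("filter", exc) from exc
    if done("filter"):
        return finish()

    # --- phase -----------------------------------------------------------
    try:
        calls, _ = build_allele_calls(filtered)
        allele_map = {sa.position: (sa.a1, sa.a2) for sa in calls.sites}
        linkages = find_linkages(calls, cfg.phasing_cfg)
        fragments = build_fragments(linkages, cfg.phasing_cfg, site_alleles=allele_map)
        linkages.to_tsv(out / "linkages.tsv")
        fragments_to_tsv(fragments, out / "fragments.tsv")
        manifest["n_linkages"] = len(linkages)
        manifest["n_fragments"] = len(fragments)
    except Exception as exc:
        raise StageError("phase", exc) from exc
    if done("phase"):
        return finish()

    # --- classify (coverage-cutoff iteration) ----------------------------
    try:
        classification = iterate_cutoffs(
            matrix, cfg.filter_cfg, cfg.phasing_cfg, cfg.iter_cfg,
            reference, cfg.overlap_threshold,
        )
        classification.to_tsv(out / "classification.tsv")
        manifest["chosen_cutoff"] = classification.provenance.get("chosen_cutoff")
        manifest["assigned_fraction"] = classification.assigned_fraction
    except Exception as exc:
        raise StageError("classify", exc) from exc
    result.classification = classification
    if done("classify"):
        return finish()

    # --- escape ----------------------------------------------------------
    try:
        escape_calls = infer_escape_sites(calls, classification, cfg.escape_cfg)
        annotation: Optional[GeneAnnotation] = None
        if cfg.annotation_path is not None:
            path = Path(cfg.annotation_path)
            if path.suffix.lower() in (".gtf", ".gff"):
                annotation = GeneAnnotation.from_gtf(path)
            else:
                annotation = GeneAnnotation.from_bed(path)
        elif truth is not None:
            annotation = truth.gene_annotation()
        genes, unannotated = (
            infer_escape_genes(escape_calls, annotation)
            if annotation is not None
            else ({}, [c.position for c in escape_calls if c.escaping])
        )
        for call in escape_calls:
            if annotation is not None:
                hits = annotation.genes_at(call.position)
                call.gene = hits[0] if hits else None
        escape_calls_to_tsv(escape_calls, out / "escape_calls.tsv")
        with open(out / "escape_genes.tsv", "w") as fh:
            fh.write("gene\tn_escaping_sites\tpositions\n")
            for gene, positions in sorted(genes.items()):
                fh.write(f"{gene}\t{len(positions)}\t{','.join(map(str, positions))}\n")
        manifest["n_escaping_sites"] = sum(c.escaping for c in escape_calls)
        manifest["n_escaping_genes"] = len(genes)
        manifest["n_unannotated_escaping"] = len(unannotated)
    except Exception as exc:
        raise StageError("escape", exc) from exc
    result.escape_calls, result.escape_genes = escape_calls, genes
    if done("escape"):
        return finish()

    # --- dosage (optional) -----------------------------------------------
    if cfg.dosage_counts_path is not None:
        try:
            table = pd.read_csv(cfg.dosage_counts_path, sep="\t")
            ratios = x_autosome_ratio(table)
            group_by = "cell_type" if "cell_type" in ratios.columns else None
            ratios.to_csv(out / "dosage_ratios.tsv", sep="\t", index=False)
            if group_by:
                summary, deviations = dosage_summary(ratios, group_by)
                summary.to_csv(out / "dosage_summary.tsv", sep="\t", index=False)
                if deviations is not None:
                    deviations.to_csv(out / "dosage_deviations.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("dosage", exc) from exc
    if done("dosage"):
        return finish()

    # --- evaluate against truth (simulated runs) -------------------------
    if truth is not None:
        try:
            result.accuracy = score_against_truth(classification, truth)
            manifest["classification_accuracy"] = result.accuracy
        except Exception as exc:
            raise StageError("evaluate", exc) from exc
    done("evaluate")
    return finish()
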