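"""End-to-end orchestration: filter -> assign -> triage -> predict.

A single :class:`PipelineConfig` (constructible from a YAML document, with
every CLI flag overriding its key) drives the full chain and produces
per-stage artifacts plus a combined ``run_report.json``. Identical config
and inputs yield byte-identical data outputs; all floats in reports are
written with 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .errors import UsageError
from .candidate_triage import CandidateGene, tabulate, triage_with_report
from .effect_prediction import (
    DEFAULT_SCAN_THRESHOLD,
    DEFAULT_SPLICE_DELTA_THRESHOLD,
    SpliceWindows,
    VariantEffect,
    effects_to_records,
    predict_all,
    read_motifs,
)
from .exclusivity_filter import FilterReport, FilterThresholds, apply_filters
from .gene_assignment import (
    DEFAULT_MAX_ASSIGN_DISTANCE,
    VariantAnnotation,
    annotate_all,
    annotations_to_frame,
    summarize_classes,
)
from .io_formats import (
    VariantSet,
    read_bed,
    read_expression,
    read_fasta,
    read_gff3,
    read_gmt,
    read_vcf_with_report,
    validate_regions,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf_a: str = ""
    vcf_b: str = ""
    fasta: str = ""
    gff3: str = ""
    bed: str = ""
    gmt: str = ""
    expression: str = ""
    motifs: str = ""
    motif_dialect: str = "jaspar"
    outdir: str = "pipeline_out"
    line_a: str = "lineA"
    line_b: str = "lineB"
    min_qual: float = 100.0
    min_alt_depth: int = 10
    min_gap: int = 10
    exclusivity_against: str = "raw"
    spacing_mode: str = "drop-all"
    max_assign_distance: int = DEFAULT_MAX_ASSIGN_DISTANCE
    expr_threshold: float = 120.0
    populations: tuple[str, ...] = ("B.Fo", "B.GC")
    no_expression_filter: bool = False
    scan_threshold: float = DEFAULT_SCAN_THRESHOLD
    splice_delta_threshold: float = DEFAULT_SPLICE_DELTA_THRESHOLD
    splice_windows: SpliceWindows = field(default_factory=SpliceWindows)
    seed: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise UsageError(f"{path}: config must be a YAML mapping")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dc_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise UsageError(f"{path}: unknown config keys {sorted(unknown)}")
        if "populations" in doc and isinstance(doc["populations"], str):
            doc["populations"] = tuple(doc["populations"].split(","))
        elif "populations" in doc:
            doc["populations"] = tuple(doc["populations"])
        if "splice_windows" in doc and isinstance(doc["splice_windows"], dict):
            doc["splice_windows"] = SpliceWindows(**doc["splice_windows"])
        return cls(**doc)

    def validate_inputs(self) -> None:
        for key in ("vcf_a", "vcf_b", "fasta", "gff3", "bed", "gmt",
                    "expression", "motifs"):
            p = getattr(self, key)
            if not p:
                raise UsageError(f"config key {key!r} is required")
            if not Path(p).exists():
                raise UsageError(f"config key {key!r}: no such file {p!r}")
        if self.exclusivity_against not in {"raw", "filtered"}:
            raise UsageError("exclusivity_against must be 'raw' or 'filtered'")
        if self.spacing_mode not in {"drop-all", "keep-first"}:
            raise UsageError("spacing_mode must be 'drop-all' or 'keep-first'")

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, SpliceWindows):
                v = {
                    "donor_exonic": v.donor_exonic,
                    "donor_intronic": v.donor_intronic,
                    "acceptor_intronic": v.acceptor_intronic,
                    "acceptor_exonic": v.acceptor_exonic,
                }
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out


@dataclass
class RunResult:
    config: PipelineConfig
    lines: tuple[str, str]
    stage_sets: dict[str, dict[str, VariantSet]]
    final: dict[str, VariantSet]
    filter_report: FilterReport
    annotations: dict[str, list[VariantAnnotation]]
    candidates: dict[str, list[CandidateGene]]
    effects: dict[str, list[VariantEffect]]
    report: dict


def _g6(x: float) -> float:
    return float(f"{x:.6g}")


def run_all(config: PipelineConfig, write_outputs: bool = True) -> RunResult:
    """Execute the full chain; returns in-memory results and stage report.

    Stage order (default): normalize -> exclusivity against the other
    line's raw set -> quality/depth -> spacing -> annotate -> triage ->
    effect prediction.
    """
    t0 = time.monotonic()
    config.validate_inputs()
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    partial = outdir / ".partial"
    if write_outputs:
        partial.write_text("running\n")

    try:
        vs_a, load_a = read_vcf_with_report(config.vcf_a, config.line_a, allow_empty=True)
        vs_b, load_b = read_vcf_with_report(config.vcf_b, config.line_b, allow_empty=True)
        genome = read_fasta(config.fasta)
        genes = read_gff3(config.gff3)
        regions = read_bed(config.bed)
        validate_regions(regions, genes)
        gene_sets = read_gmt(config.gmt)
        expression = read_expression(config.expression)
        pwms = read_motifs(config.motifs, config.motif_dialect)

        thresholds = FilterThresholds(
            min_qual_exclusive=config.min_qual,
            min_alt_depth_exclusive=config.min_alt_depth,
            min_gap_nt=config.min_gap,
        )
        final_a, final_b, filter_report, stage_sets = apply_filters(
            vs_a, vs_b, thresholds,
            exclusivity_against=config.exclusivity_against,
            spacing_mode=config.spacing_mode,
        )
        logger.info("filter: %s -> %d exclusive, %s -> %d exclusive",
                    config.line_a, len(final_a), config.line_b, len(final_b))

        annotations: dict[str, list[VariantAnnotation]] = {}
        candidates: dict[str, list[CandidateGene]] = {}
        effects: dict[str, list[VariantEffect]] = {}
        triage_reports = {}
        for line, final in ((config.line_a, final_a), (config.line_b, final_b)):
            anns = annotate_all(
                final, genes, regions,
                max_assign_distance=config.max_assign_distance,
                known_chroms=genome.keys(),
            )
            annotations[line] = anns
            cands, treport = triage_with_report(
                anns, gene_sets, expression,
                expr_threshold=config.expr_threshold,
                populations=config.populations,
                genes=genes,
                require_expression=not config.no_expression_filter,
            )
            candidates[line] = cands
            triage_reports[line] = treport
            effects[line] = predict_all(
                cands, genome, genes, pwms,
                threshold_rel=config.scan_threshold,
                splice_windows=config.splice_windows,
                splice_delta_threshold=config.splice_delta_threshold,
            )
            logger.info("line %s: %d annotated, %d candidates", line, len(anns), len(cands))

        report = {
            "version": __version__,
            "config": config.to_dict(),
            "load": {config.line_a: asdict(load_a), config.line_b: asdict(load_b)},
            "filter": filter_report.to_dict(),
            "region_class_counts": {
                line: summarize_classes(anns) for line, anns in annotations.items()
            },
            "candidates": {
                line: [c.gene_id for c in cands] for line, cands in candidates.items()
            },
            "triage": {
                line: {
                    "n_genes_with_variants": r.n_genes_with_variants,
                    "n_in_gene_sets": r.n_in_gene_sets,
                    "n_passing_expression": r.n_passing_expression,
                    "genes_missing_expression": sorted(r.genes_missing_expression),
                }
                for line, r in triage_reports.items()
            },
            "tfbs_deltas": {
                line: sum(len(e.tfbs) for e in effs) for line, effs in effects.items()
            },
        }

        if write_outputs:
            contigs = {c: len(s) for c, s in genome.items()}
            write_vcf(final_a, outdir / f"exclusive_{config.line_a}.vcf", contigs)
            write_vcf(final_b, outdir / f"exclusive_{config.line_b}.vcf", contigs)
            with open(outdir / "filter_report.json", "w") as fh:
                json.dump(filter_report.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            for line in (config.line_a, config.line_b):
                annotations_to_frame(annotations[line]).to_csv(
                    outdir / f"annotations_{line}.tsv", sep="\t", index=False
                )
                tabulate(candidates[line]).to_csv(
                    outdir / f"candidates_{line}.tsv", sep="\t", index=False
                )
                with open(outdir / f"effects_{line}.json", "w") as fh:
                    json.dump(effects_to_records(effects[line]), fh, indent=2, sort_keys=True)
                    fh.write("\n")
            report["wall_time_s"] = _g6(time.monotonic() - t0)
            with open(outdir / "run_report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            partial.unlink(missing_ok=True)
    except Exception:
        # leave the .partial marker in place so interrupted runs are visible
        raise

    # load report dataclasses use __slots__; normalize for JSON use
    return RunResult(
        config=config,
        lines=(config.line_a, config.line_b),
        stage_sets=stage_sets,
        final={config.line_a: final_a, config.line_b: final_b},
        filter_report=filter_report,
        annotations=annotations,
        candidates=candidates,
        effects=effects,
        report=report,
    )
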