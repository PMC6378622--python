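"""Candidate-gene triage.

Annotated line-exclusive variants are reduced to a candidate table by two
conjunctive filters: the assigned gene must belong to at least one of the
supplied gene sets (pathway / ontology lists standing in for curated
class-switch-recombination regulators), and it must be expressed — value
strictly above a configurable threshold — in at least one designated cell
population. "Expressed" is a presence check, not a differential test.
Genes reachable only through nearest-gene intergenic assignment are
triaged exactly like genic hits, keeping their intergenic class in the
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import ExpressionTable, GeneModel, GeneSetCollection
from .gene_assignment import VariantAnnotation

DEFAULT_EXPR_THRESHOLD = 120.0


@dataclass(frozen=True, slots=True)
class CandidateGene:
    gene_id: str
    name: str
    annotations: tuple[VariantAnnotation, ...]
    gene_sets: tuple[str, ...]
    expression: Mapping[str, float]  # designated population -> value (where known)
    passes_expression: bool
    region_classes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.annotations:
            raise ValueError(f"candidate {self.gene_id} has no variants")


@dataclass(slots=True)
class TriageReport:
    n_genes_with_variants: int = 0
    n_in_gene_sets: int = 0
    n_passing_expression: int = 0
    genes_missing_expression: list[str] = field(default_factory=list)


def triage_with_report(
    annotations: Sequence[VariantAnnotation],
    gene_sets: GeneSetCollection,
    expr: ExpressionTable,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    populations: Sequence[str] = (),
    genes: Mapping[str, GeneModel] | None = None,
    require_expression: bool = True,
) -> tuple[list[CandidateGene], TriageReport]:
    """Group annotations by gene and apply set-membership + expression filters.

    A gene absent from the expression table fails the expression filter
    (counted in the report, not an error). Output order is gene_id, so the
    result is invariant to the order of the input annotations.
    """
    report = TriageReport()
    pops = tuple(populations) if populations else expr.populations
    by_gene: dict[str, list[VariantAnnotation]] = {}
    for a in annotations:
        if a.gene_id is not None:
            by_gene.setdefault(a.gene_id, []).append(a)
    report.n_genes_with_variants = len(by_gene)

    candidates: list[CandidateGene] = []
    for gene_id in sorted(by_gene):
        matched = gene_sets.sets_containing(gene_id)
        if not matched:
            continue
        report.n_in_gene_sets += 1
        values = {p: expr.get(gene_id, p) for p in pops}
        known = {p: v for p, v in values.items() if v is not None}
        if not expr.has_gene(gene_id):
            report.genes_missing_expression.append(gene_id)
        passes = any(v > expr_threshold for v in known.values())
        if passes:
            report.n_passing_expression += 1
        if require_expression and not passes:
            continue
        anns = sorted(by_gene[gene_id], key=lambda a: a.variant.key)
        name = genes[gene_id].name if genes and gene_id in genes else gene_id
        candidates.append(
            CandidateGene(
                gene_id=gene_id,
                name=name,
                annotations=tuple(anns),
                gene_sets=matched,
                expression=known,
                passes_expression=passes,
                region_classes=frozenset(a.region_class.value for a in anns),
            )
        )
    return candidates, report


def triage(
    annotations: Sequence[VariantAnnotation],
    gene_sets: GeneSetCollection,
    expr: ExpressionTable,
    expr_threshold: float = DEFAULT_EXPR_THRESHOLD,
    populations: Sequence[str] = (),
    genes: Mapping[str, GeneModel] | None = None,
    require_expression: bool = True,
) -> list[CandidateGene]:
    return triage_with_report(
        annotations, gene_sets, expr, expr_threshold, populations, genes,
        require_expression,
    )[0]


def tabulate(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """One row per (gene, variant), with the CDS/nCDS/RR-style class column."""
    rows = []
    for c in candidates:
        for a in c.annotations:
            v = a.variant
            rows.append(
                {
                    "gene_id": c.gene_id,
                    "gene_name": c.name,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "line": v.line,
                    "vclass": v.vclass,
                    "region_class": a.region_class.value,
                    "sub_context": a.sub_context,
                    "distance": a.distance_to_gene if a.distance_to_gene is not None else "",
                    "gene_sets": ";".join(c.gene_sets),
                    "max_expression": max(c.expression.values()) if c.expression else "",
                }
            )
    cols = [
        "gene_id", "gene_name", "chrom", "pos", "ref", "alt", "line", "vclass",
        "region_class", "sub_context", "distance", "gene_sets", "max_expression",
    ]
    return pd.DataFrame(rows, columns=cols)
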