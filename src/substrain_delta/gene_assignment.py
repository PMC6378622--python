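"""Variant-to-gene assignment and region classification.

Each line-exclusive variant is placed into exactly one of four region
classes with a fixed priority ladder — coding sequence (CDS), non-coding
genic sequence (nCDS: UTRs, introns, non-coding exons), regulatory region
(RR), intergenic — and assigned a gene: its host gene when genic, or its
nearest gene within a distance cap when regulatory/intergenic. Overlap is
evaluated on the variant's affected reference span
``[pos, pos + len(ref) - 1]`` so deletions are handled deterministically.
Strand never affects class or distance, only the UTR5/UTR3 labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .errors import AnnotationMismatchError
from .io_formats import GeneModel, RegulatoryRegion, Variant, VariantSet

DEFAULT_MAX_ASSIGN_DISTANCE = 100_000


class RegionClass(str, Enum):
    CDS = "CDS"
    NCDS = "nCDS"
    RR = "RR"
    INTERGENIC = "intergenic"


SUB_CONTEXTS = ("exonic_CDS", "UTR5", "UTR3", "intronic", "noncoding_exon", "regulatory", "none")


@dataclass(frozen=True, slots=True)
class VariantAnnotation:
    variant: Variant
    region_class: RegionClass
    sub_context: str
    gene_id: str | None
    distance_to_gene: int | None  # 0 when inside the gene span; None when unassigned

    def __post_init__(self) -> None:
        if self.sub_context not in SUB_CONTEXTS:
            raise ValueError(f"unknown sub_context {self.sub_context!r}")


def _span_overlaps(span: tuple[int, int], iv: tuple[int, int]) -> bool:
    return span[0] <= iv[1] and iv[0] <= span[1]


def _span_gene_distance(span: tuple[int, int], gene: GeneModel) -> int:
    """0 if the span overlaps the gene span, else the gap in nt."""
    if _span_overlaps(span, (gene.span_start, gene.span_end)):
        return 0
    if span[1] < gene.span_start:
        return gene.span_start - span[1]
    return span[0] - gene.span_end


class AnnotationIndex:
    """Interval-tree indices over genes and regulatory regions, per chromosome.

    Built once and shared across all variants of a run; classification
    results are independent of the order genes and regions were supplied.
    """

    def __init__(
        self,
        genes: Mapping[str, GeneModel],
        regions: Sequence[RegulatoryRegion],
        known_chroms: Iterable[str] = (),
    ) -> None:
        self.genes = dict(genes)
        self.regions = tuple(regions)
        self.known_chroms = (
            set(known_chroms)
            | {g.chrom for g in genes.values()}
            | {r.chrom for r in regions}
        )
        self._gene_spans: dict[str, IntervalTree] = {}
        self._cds: dict[str, IntervalTree] = {}
        self._rr: dict[str, IntervalTree] = {}
        self._genes_by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes.values():
            self._gene_spans.setdefault(g.chrom, IntervalTree()).addi(
                g.span_start, g.span_end + 1, g.gene_id
            )
            self._genes_by_chrom.setdefault(g.chrom, []).append(g)
            for s, e in g.cds:
                self._cds.setdefault(g.chrom, IntervalTree()).addi(s, e + 1, g.gene_id)
        for r in regions:
            self._rr.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
        for chrom in self._genes_by_chrom:
            self._genes_by_chrom[chrom].sort(key=lambda g: (g.span_start, g.gene_id))

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return self._genes_by_chrom.get(chrom, [])

    def overlapping_gene_ids(self, chrom: str, span: tuple[int, int], tree_kind: str) -> list[str]:
        tree = (self._gene_spans if tree_kind == "span" else self._cds).get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(span[0], span[1] + 1)})

    def overlapping_regions(self, chrom: str, span: tuple[int, int]) -> list[RegulatoryRegion]:
        tree = self._rr.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(span[0], span[1] + 1)]
        return sorted(hits, key=lambda r: (r.start, r.end))


def _pick_gene(index: AnnotationIndex, gene_ids: list[str]) -> GeneModel:
    """Deterministic tie-break: smaller span_start, then lexicographic id."""
    genes = [index.genes[g] for g in gene_ids]
    genes.sort(key=lambda g: (g.span_start, g.gene_id))
    return genes[0]


def _ncds_sub_context(gene: GeneModel, span: tuple[int, int]) -> str:
    """Finest non-coding context inside a gene span: UTR / intron / nc exon."""
    in_exon = any(_span_overlaps(span, iv) for iv in gene.exons)
    if not in_exon:
        return "intronic"
    extent = gene.cds_extent
    if extent is None:
        return "noncoding_exon"
    cds_min, cds_max = extent
    mid = (span[0] + span[1]) // 2
    if mid < cds_min:
        return "UTR5" if gene.strand == "+" else "UTR3"
    if mid > cds_max:
        return "UTR3" if gene.strand == "+" else "UTR5"
    # exonic base inside the CDS extent but not in CDS (isoform-union edge)
    return "noncoding_exon"


def classify_variant(
    v: Variant, index: AnnotationIndex
) -> tuple[RegionClass, str, str | None]:
    """Classify one variant; returns (class, sub_context, host_gene_id|None).

    Priority ladder: CDS > nCDS > RR > intergenic. The host gene is only
    set for genic classes; RR/intergenic gene assignment is a separate,
    distance-based step.
    """
    if v.chrom not in index.known_chroms:
        raise AnnotationMismatchError(
            f"variant chromosome {v.chrom!r} absent from annotation"
        )
    span = v.span
    cds_genes = index.overlapping_gene_ids(v.chrom, span, "cds")
    if cds_genes:
        return RegionClass.CDS, "exonic_CDS", _pick_gene(index, cds_genes).gene_id
    span_genes = index.overlapping_gene_ids(v.chrom, span, "span")
    if span_genes:
        gene = _pick_gene(index, span_genes)
        return RegionClass.NCDS, _ncds_sub_context(gene, span), gene.gene_id
    if index.overlapping_regions(v.chrom, span):
        return RegionClass.RR, "regulatory", None
    return RegionClass.INTERGENIC, "none", None


def assign_nearest_gene(
    v: Variant,
    index: AnnotationIndex,
    max_assign_distance: int = DEFAULT_MAX_ASSIGN_DISTANCE,
) -> tuple[str | None, int | None]:
    """Nearest gene (same chromosome) to the variant's affected span.

    Ties are broken by smaller span_start, then lexicographic gene id;
    genes further than ``max_assign_distance`` yield (None, None).
    """
    span = v.span
    best: tuple[int, int, str] | None = None  # (distance, span_start, gene_id)
    for g in index.genes_on(v.chrom):
        d = _span_gene_distance(span, g)
        cand = (d, g.span_start, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None or best[0] > max_assign_distance:
        return None, None
    return best[2], best[0]


def annotate_all(
    excl: VariantSet,
    genes: Mapping[str, GeneModel],
    regions: Sequence[RegulatoryRegion],
    max_assign_distance: int = DEFAULT_MAX_ASSIGN_DISTANCE,
    known_chroms: Iterable[str] = (),
    index: AnnotationIndex | None = None,
) -> list[VariantAnnotation]:
    """Annotate every variant of a filtered exclusive set, in input order."""
    if index is None:
        index = AnnotationIndex(genes, regions, known_chroms=known_chroms)
    out: list[VariantAnnotation] = []
    for v in excl:
        region_class, sub_context, gene_id = classify_variant(v, index)
        if region_class in (RegionClass.CDS, RegionClass.NCDS):
            distance: int | None = 0
        else:
            gene_id, distance = assign_nearest_gene(v, index, max_assign_distance)
        out.append(
            VariantAnnotation(
                variant=v,
                region_class=region_class,
                sub_context=sub_context,
                gene_id=gene_id,
                distance_to_gene=distance,
            )
        )
    return out


def summarize_classes(annotations: Sequence[VariantAnnotation]) -> dict[str, int]:
    counts = {rc.value: 0 for rc in RegionClass}
    for a in annotations:
        counts[a.region_class.value] += 1
    return counts


def annotations_to_frame(annotations: Sequence[VariantAnnotation]):
    """Render annotations as the pipeline's TSV-ready table."""
    import pandas as pd

    rows = [
        {
            "chrom": a.variant.chrom,
            "pos": a.variant.pos,
            "ref": a.variant.ref,
            "alt": a.variant.alt,
            "line": a.variant.line,
            "vclass": a.variant.vclass,
            "region_class": a.region_class.value,
            "sub_context": a.sub_context,
            "gene_id": a.gene_id if a.gene_id is not None else "",
            "distance": a.distance_to_gene if a.distance_to_gene is not None else "",
        }
        for a in annotations
    ]
    cols = [
        "chrom", "pos", "ref", "alt", "line", "vclass",
        "region_class", "sub_context", "gene_id", "distance",
    ]
    return pd.DataFrame(rows, columns=cols)
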