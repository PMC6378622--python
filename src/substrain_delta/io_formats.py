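"""Domain model and format I/O.

Every external format the pipeline touches is read and written here, with
one coordinate convention everywhere inside the package: **1-based,
inclusive** positions, matching VCF and GFF3. BED's 0-based half-open
coordinates are converted exactly once, at the format boundary.

Variants are stored normalized: multi-allelic records are split into one
``Variant`` per alternate allele, and each (ref, alt) pair is reduced to its
minimal representation (shared trailing bases trimmed, then shared leading
bases trimmed while keeping the single VCF anchor base for indels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, FormatError, IntegrityError, UsageError

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce (pos, ref, alt) to minimal representation.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing ``pos``), always keeping at least one base on each side —
    the single anchor base VCF requires for indels. Idempotent.

    >>> normalize_allele(101, "ATG", "AG")
    (101, 'AT', 'A')
    >>> normalize_allele(101, "CAT", "CGT")
    (102, 'A', 'G')
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_class(ref: str, alt: str) -> str:
    """SNP / MNP / INS / DEL from allele lengths of a normalized pair."""
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True, slots=True)
class Variant:
    """A single called difference from the reference, 1-based.

    ``qual`` is the variant caller's quality score (VCF QUAL); ``alt_depth``
    is the number of reads supporting the alternate allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    alt_depth: int
    line: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise IntegrityError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _BASES:
                raise IntegrityError(f"{name} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise IntegrityError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if len(self.ref) > 1 and len(self.alt) > 1 and (
            self.ref[0] == self.alt[0] or self.ref[-1] == self.alt[-1]
        ):
            raise IntegrityError(
                f"variant {self.chrom}:{self.pos} {self.ref}>{self.alt} is not minimal"
            )
        if self.qual < 0:
            raise IntegrityError("qual must be non-negative")
        if self.alt_depth < 0:
            raise IntegrityError("alt_depth must be non-negative")

    @property
    def vclass(self) -> str:
        return variant_class(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-aware identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference interval [pos, pos + len(ref) - 1], inclusive."""
        return (self.pos, self.pos + len(self.ref) - 1)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True, slots=True)
class VariantSet:
    """Sorted, duplicate-free collection of variants from one line."""

    line: str
    variants: tuple[Variant, ...]

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if keys != sorted(keys):
            raise IntegrityError(f"VariantSet for line {self.line!r} is not sorted")
        if len(set(keys)) != len(keys):
            raise IntegrityError(f"VariantSet for line {self.line!r} has duplicate keys")
        for v in self.variants:
            if v.line != self.line:
                raise IntegrityError(
                    f"variant {v.key} labeled {v.line!r} inside set for {self.line!r}"
                )

    @classmethod
    def build(cls, line: str, variants: Iterable[Variant], dedupe: bool = False) -> "VariantSet":
        """Sort (and optionally dedupe, keeping the first seen) into a set."""
        relabeled = [v if v.line == line else replace(v, line=line) for v in variants]
        relabeled.sort(key=lambda v: v.key)
        if dedupe:
            out: list[Variant] = []
            seen: set[tuple] = set()
            for v in relabeled:
                if v.key not in seen:
                    seen.add(v.key)
                    out.append(v)
            relabeled = out
        return cls(line=line, variants=tuple(relabeled))

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


@dataclass(slots=True)
class VcfLoadReport:
    """Counts of records seen / dropped while loading a VCF."""

    n_records: int = 0
    n_variants: int = 0
    n_dropped_missing_qual: int = 0
    n_dropped_missing_depth: int = 0
    n_dropped_non_acgt: int = 0
    n_deduplicated: int = 0


def _alt_depth_from_record(rec, alt_index: int) -> int | None:
    """Alt-allele depth: FORMAT/AD of the first sample, else INFO/DP4.

    AD lists ref depth followed by one depth per alt allele; DP4 is
    (ref-fwd, ref-rev, alt-fwd, alt-rev), so the alt depth is the sum of
    the last two fields.
    """
    if rec.samples:
        sample = rec.samples[next(iter(rec.samples))]
        ad = sample.get("AD")
        if ad is not None and len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
            return int(ad[alt_index + 1])
    dp4 = rec.info.get("DP4") if rec.info else None
    if dp4 is not None and len(dp4) == 4 and None not in dp4:
        return int(dp4[2]) + int(dp4[3])
    return None


def read_vcf_with_report(
    path: str | Path, line_label: str, allow_empty: bool = False
) -> tuple[VariantSet, VcfLoadReport]:
    """Load a VCF 4.x file into a normalized :class:`VariantSet`.

    Multi-allelic records are split per alternate allele before anything
    else, so every downstream filter is allele-aware. Records without a
    QUAL or without a recoverable alt depth are dropped and counted.
    """
    report = VcfLoadReport()
    variants: list[Variant] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    with vcf:
        rec_no = 0
        try:
            for rec in vcf:
                rec_no += 1
                report.n_records += 1
                if rec.qual is None:
                    report.n_dropped_missing_qual += 1
                    continue
                alts = rec.alts or ()
                for i, alt in enumerate(alts):
                    if alt is None or not set(alt.upper()) <= _BASES or not set(
                        rec.ref.upper()
                    ) <= _BASES:
                        report.n_dropped_non_acgt += 1
                        continue
                    depth = _alt_depth_from_record(rec, i)
                    if depth is None:
                        report.n_dropped_missing_depth += 1
                        continue
                    pos, ref, alt_n = normalize_allele(rec.pos, rec.ref, alt)
                    variants.append(
                        Variant(
                            chrom=rec.chrom,
                            pos=pos,
                            ref=ref,
                            alt=alt_n,
                            qual=float(rec.qual),
                            alt_depth=depth,
                            line=line_label,
                        )
                    )
        except (ValueError, OSError) as exc:
            raise FormatError(f"{path}: malformed record near record #{rec_no + 1}: {exc}") from exc
    n_raw = len(variants)
    vs = VariantSet.build(line_label, variants, dedupe=True)
    report.n_deduplicated = n_raw - len(vs)
    report.n_variants = len(vs)
    if report.n_records == 0 or (len(vs) == 0 and not allow_empty):
        if not allow_empty:
            raise EmptyInputError(f"{path}: no parseable variant records")
    return vs, report


def read_vcf(path: str | Path, line_label: str, allow_empty: bool = False) -> VariantSet:
    """:func:`read_vcf_with_report` without the report."""
    return read_vcf_with_report(path, line_label, allow_empty=allow_empty)[0]


def write_vcf(vs: VariantSet, path: str | Path, contigs: Mapping[str, int]) -> None:
    """Write a VariantSet as uncompressed VCF 4.2 with a single sample.

    Alt depth is stored in FORMAT/AD as (ref_depth, alt_depth); the ref
    depth is synthesized as 0 since the model does not track it.
    """
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(vs.line)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in vs:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            rec.samples[vs.line]["GT"] = (1, 1)
            rec.samples[vs.line]["AD"] = (0, v.alt_depth)
            out.write(rec)


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of 1-based inclusive intervals; adjacent intervals coalesce."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s > e:
            raise FormatError(f"interval start {s} > end {e}")
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _covers(outer: Sequence[tuple[int, int]], inner: Sequence[tuple[int, int]]) -> bool:
    """True if every base of ``inner`` lies inside some ``outer`` interval."""
    for s, e in inner:
        if not any(os <= s and e <= oe for os, oe in outer):
            # a merged inner interval could straddle two outer intervals only
            # if the outer tier had a gap, which would be a real violation
            return False
    return True


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with isoform-union exon and CDS intervals (1-based inclusive)."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise IntegrityError(f"gene {self.gene_id}: strand must be + or -")
        if self.span_start > self.span_end:
            raise IntegrityError(f"gene {self.gene_id}: span start > end")
        object.__setattr__(self, "exons", merge_intervals(self.exons))
        object.__setattr__(self, "cds", merge_intervals(self.cds))
        if not _covers(((self.span_start, self.span_end),), self.exons):
            raise IntegrityError(f"gene {self.gene_id}: exons outside span")
        if not _covers(self.exons, self.cds):
            raise IntegrityError(f"gene {self.gene_id}: CDS outside exons")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive merged exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def cds_extent(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return (self.cds[0][0], self.cds[-1][1])


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GFF3 gene/mRNA/exon/CDS hierarchy into gene-level models.

    Exon and CDS intervals are unioned across isoforms: the pipeline
    assigns variants at gene level. Child features that cannot be traced
    to a gene parent are skipped with a warning.
    """
    import gffutils

    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted types on empty/odd input
        logger.warning("%s: no parseable GFF3 features (%s)", path, exc)
        return {}

    genes: dict[str, GeneModel] = {}
    gene_ids = {g.id for g in db.features_of_type("gene")}

    def _gene_ancestor(feat) -> str | None:
        seen = set()
        frontier = [feat]
        while frontier:
            f = frontier.pop()
            for pid in f.attributes.get("Parent", []):
                if pid in gene_ids:
                    return pid
                if pid not in seen:
                    seen.add(pid)
                    try:
                        frontier.append(db[pid])
                    except Exception:
                        logger.warning("feature %s: unresolvable parent %s; skipped", f.id, pid)
        return None

    exon_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    cds_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    for ftype, store in (("exon", exon_by_gene), ("CDS", cds_by_gene)):
        for feat in db.features_of_type(ftype):
            gid = _gene_ancestor(feat)
            if gid is None:
                logger.warning("%s feature %s has no gene ancestor; skipped", ftype, feat.id)
                continue
            store[gid].append((feat.start, feat.end))

    for g in db.features_of_type("gene"):
        exons = exon_by_gene[g.id] or [(g.start, g.end)]
        name = g.attributes.get("Name", [g.id])[0]
        biotype = g.attributes.get(
            "biotype", g.attributes.get("gene_biotype", ["protein_coding"])
        )[0]
        genes[g.id] = GeneModel(
            gene_id=g.id,
            name=name,
            chrom=g.seqid,
            strand=g.strand if g.strand in "+-" else "+",
            span_start=g.start,
            span_end=g.end,
            exons=tuple(exons),
            cds=tuple(cds_by_gene[g.id]),
            biotype=biotype,
        )
    if not genes:
        logger.warning("%s: file contained no gene features", path)
    return genes


def write_gff3(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 with one synthetic transcript per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            g = genes[gid]
            attrs = f"ID={g.gene_id};Name={g.name};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.span_start}\t{g.span_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.span_start}\t{g.span_end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={tid}.cds{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# Regulatory regions (BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class RegulatoryRegion:
    """A regulatory interval, stored 1-based inclusive after BED ingestion."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    target_gene_id: str | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IntegrityError(f"regulatory region {self.chrom}:{self.start}-{self.end} empty")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def read_bed(path: str | Path, source_label: str | None = None) -> tuple[RegulatoryRegion, ...]:
    """Read BED3/BED6 regulatory regions (0-based half-open on disk).

    The BED name column, when present and not '.', is interpreted as the
    region's target gene id.
    """
    path = Path(path)
    label = source_label if source_label is not None else path.stem
    regions: list[RegulatoryRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if start0 >= end0:
                raise FormatError(f"{path}:{lineno}: BED start must be < end")
            target = cols[3] if len(cols) > 3 and cols[3] not in {".", ""} else None
            regions.append(
                RegulatoryRegion(
                    chrom=cols[0], start=start0 + 1, end=end0,
                    target_gene_id=target, source_label=label,
                )
            )
    return tuple(regions)


def write_bed(regions: Sequence[RegulatoryRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            name = r.target_gene_id if r.target_gene_id else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def validate_regions(
    regions: Sequence[RegulatoryRegion], genes: Mapping[str, GeneModel]
) -> None:
    """Ensure every declared target gene exists in the annotation."""
    for r in regions:
        if r.target_gene_id is not None and r.target_gene_id not in genes:
            raise IntegrityError(
                f"regulatory region {r.chrom}:{r.start}-{r.end} targets unknown "
                f"gene {r.target_gene_id!r}"
            )


# ---------------------------------------------------------------------------
# Gene sets (GMT), expression (TSV), genome (FASTA)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GeneSetCollection:
    """Named gene sets with per-set provenance strings."""

    sets: Mapping[str, frozenset[str]]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise IntegrityError(f"gene set {name!r} is empty")

    def sets_containing(self, gene_id: str) -> tuple[str, ...]:
        return tuple(sorted(n for n, m in self.sets.items() if gene_id in m))

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-separated gene sets: name, description, members..."""
    sets: dict[str, frozenset[str]] = {}
    prov: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[cols[0]] = frozenset(g for g in cols[2:] if g)
            prov[cols[0]] = cols[1]
    return GeneSetCollection(sets=sets, provenance=prov)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.provenance.get(name, "na")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


@dataclass(frozen=True, slots=True)
class ExpressionTable:
    """Expression values keyed by (gene_id, population)."""

    values: Mapping[tuple[str, str], float]
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        import math

        for (g, p), v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise IntegrityError(f"expression for ({g}, {p}) is {v}: must be finite, >= 0")

    def get(self, gene_id: str, population: str) -> float | None:
        return self.values.get((gene_id, population))

    def has_gene(self, gene_id: str) -> bool:
        return any(g == gene_id for g, _ in self.values)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a long-format TSV with columns gene_id, population, value."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "population": str})
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    required = {"gene_id", "population", "value"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: expression TSV must have columns {sorted(required)}")
    values = {
        (row.gene_id, row.population): float(row.value) for row in df.itertuples(index=False)
    }
    pops = tuple(sorted(df["population"].unique()))
    return ExpressionTable(values=values, populations=pops)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "population": p, "value": v}
        for (g, p), v in sorted(table.values.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "population", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into {name: uppercase sequence}; duplicate names error."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def check_line_labels(vs_a: VariantSet, vs_b: VariantSet) -> None:
    if vs_a.line == vs_b.line:
        raise UsageError(f"both variant sets carry the same line label {vs_a.line!r}")
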