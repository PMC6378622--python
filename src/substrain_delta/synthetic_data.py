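"""Self-contained synthetic two-line study with a ground-truth ledger.

``simulate`` builds everything the pipeline consumes — genome FASTA, gene
annotation GFF3, regulatory-region BED, gene-set GMT, expression TSV, one
VCF per line, a motif file — plus a per-variant truth ledger recording
what the pipeline *should* find: line exclusivity, the expected fate at
each filter stage, the true region class and nearest gene, any planted
motif gain/loss, and the planted candidate genes.

The emulated structure mirrors a paired-substrain design: two lines share
a reference, carry shared variants (identical allele keys in both VCFs)
and line-private variants; quality and alt-depth values are drawn from
two-component distributions straddling the >100 / >10 filter thresholds
so every branch is exercised; clustered variant pairs are planted at
gaps of 1..10 nt; and motif instances are planted in regulatory regions
so that a multi-nt deletion removes a binding site and an insertion
completes one. Every planted motif effect is verified at generation time
with a brute-force scanner independent of the pipeline's own scan, with
local background re-rolled on spurious hits.

Background sequence is i.i.d. uniform ACGT — no isochores, repeats,
mutational spectra or linkage; what passes here demonstrates correctness
of the bookkeeping and the scanning logic, not performance on real
genomes.
"""

from __future__ import annotations

import json
from bisect import insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, IntegrityError
from .io_formats import (
    ExpressionTable,
    GeneModel,
    GeneSetCollection,
    RegulatoryRegion,
    Variant,
    VariantSet,
    write_bed,
    write_expression,
    write_fasta,
    write_gff3,
    write_gmt,
    write_vcf,
)
from .effect_prediction import PWM, reverse_complement, write_motifs_jaspar

MIN_SITE_SEPARATION = 25  # nt between distinct planted variant anchors

ZONE_KINDS = ("cds", "intron", "utr_left", "utr_right", "rr", "intergenic")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic paired-line design.

    Defaults define the reference toy study: one 200 kb chromosome with
    30 genes, 40 shared + 30 private variants per line, 6 clustered
    pairs, 3 planted motif disruptions and 1 motif creation, seed 7.
    """

    seed: int = 7
    n_chroms: int = 1
    chrom_length: int = 200_000
    n_genes: int = 30
    gene_length: tuple[int, int] = (3000, 3000)
    n_shared_variants: int = 40
    n_private_variants: int | tuple[int, int] = 30  # per line; (a, b) for asymmetry
    fraction_indel: float = 0.25
    qual_pass: tuple[float, float] = (101, 500)
    qual_fail: tuple[float, float] = (20, 100)
    depth_pass: tuple[int, int] = (11, 60)
    depth_fail: tuple[int, int] = (1, 10)
    p_qual_pass: float = 0.5
    p_depth_pass: float = 0.5
    n_clustered_pairs: int = 6
    cluster_gap_range: tuple[int, int] = (1, 10)
    n_motif_disruptions: int = 3
    n_motif_creations: int = 1
    scan_threshold: float = 0.80
    expr_threshold: float = 120.0
    populations: tuple[str, ...] = ("B.Fo", "B.GC")
    line_a: str = "lineA"
    line_b: str = "lineB"
    max_tries: int = 50

    @property
    def private_a(self) -> int:
        n = self.n_private_variants
        return n[0] if isinstance(n, tuple) else n

    @property
    def private_b(self) -> int:
        n = self.n_private_variants
        return n[1] if isinstance(n, tuple) else n

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.chrom_length, self.n_genes, self.n_shared_variants,
            self.private_a, self.private_b, self.n_clustered_pairs,
            self.n_motif_disruptions, self.n_motif_creations,
        )
        if any(c < 0 for c in counts) or self.n_chroms < 1 or self.n_genes < 1:
            raise ConfigurationError("all simulation counts must be non-negative")
        n_motif_genes = self.n_motif_disruptions + self.n_motif_creations
        if self.n_genes < n_motif_genes + 2:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {n_motif_genes} motif genes"
            )
        block = self.chrom_length // max(1, -(-self.n_genes // self.n_chroms))
        if block < self.gene_length[1] + 2600:
            raise ConfigurationError(
                "chrom_length too small: each gene needs its span plus regulatory "
                "and intergenic room"
            )
        pairs_a = -(-self.n_clustered_pairs // 2)
        need_a = self.n_motif_disruptions + self.n_motif_creations + 2 * pairs_a
        need_b = 2 * (self.n_clustered_pairs // 2)
        if self.private_a < need_a or self.private_b < need_b:
            raise ConfigurationError(
                "n_private_variants too small for planted motif variants and "
                "clustered pairs"
            )
        if self.line_a == self.line_b:
            raise ConfigurationError("line labels must differ")


def default_sim_motifs() -> dict[str, tuple[str, np.ndarray]]:
    """Three sharp 8-mer count matrices (97:1:1:1 per position).

    Consensus words are chosen non-palindromic so a planted instance
    yields exactly one forward-strand hit.
    """
    words = {"SIM001": ("TFA", "AAACGGTC"), "SIM002": ("TFB", "CCTTAGAG"),
             "SIM003": ("TFC", "TGGATCTC")}
    base_idx = {b: i for i, b in enumerate("ACGT")}
    out: dict[str, tuple[str, np.ndarray]] = {}
    for motif_id, (tf, word) in words.items():
        counts = np.ones((len(word), 4), dtype=int)
        for i, b in enumerate(word):
            counts[i, base_idx[b]] = 97
        out[motif_id] = (tf, counts)
    return out


def _motif_pwms(motifs: Mapping[str, tuple[str, np.ndarray]]) -> list[PWM]:
    return [PWM.from_counts(mid, tf, counts) for mid, (tf, counts) in motifs.items()]


# ---------------------------------------------------------------------------
# Independent brute-force scanning oracle (used to verify planted truth)
# ---------------------------------------------------------------------------

def oracle_scan_hits(seq: str, pwm: PWM, threshold: float) -> list[tuple[int, str]]:
    """(0-based offset, strand) of every hit, by per-offset rescoring."""
    lom = pwm.log_odds
    w = pwm.width
    span = pwm.max_score - pwm.min_score
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for off in range(len(seq) - w + 1):
        window = seq[off : off + w]
        for strand, word in (("+", window), ("-", reverse_complement(window))):
            raw = sum(lom[i, idx.get(b, 4)] for i, b in enumerate(word))
            if (raw - pwm.min_score) / span >= threshold:
                hits.append((off, strand))
    return hits


def oracle_delta_counts(
    genome: Mapping[str, str], v: Variant, pwms: Sequence[PWM], threshold: float
) -> dict[tuple[str, str], int]:
    """{(motif_id, status): count} by brute-force scanning both alleles."""
    chrom_seq = genome[v.chrom]
    w_max = max(p.width for p in pwms)
    win_start = max(1, v.pos - (w_max - 1))
    win_end = min(len(chrom_seq), v.pos + len(v.ref) - 1 + (w_max - 1))
    ref_window = chrom_seq[win_start - 1 : win_end]
    lo = v.pos - win_start
    alt_window = ref_window[:lo] + v.alt + ref_window[lo + len(v.ref):]
    counts: dict[tuple[str, str], int] = {}
    for pwm in pwms:
        for strand in "+-":
            n_side = {}
            for side, window, allele in (("ref", ref_window, v.ref), ("alt", alt_window, v.alt)):
                span = (lo, lo + len(allele) - 1)
                n = sum(
                    1
                    for off, s in oracle_scan_hits(window, pwm, threshold)
                    if s == strand and off <= span[1] and span[0] <= off + pwm.width - 1
                )
                n_side[side] = n
            lost = max(n_side["ref"] - n_side["alt"], 0)
            gained = max(n_side["alt"] - n_side["ref"], 0)
            if lost:
                counts[(pwm.motif_id, "lost")] = counts.get((pwm.motif_id, "lost"), 0) + lost
            if gained:
                counts[(pwm.motif_id, "gained")] = counts.get((pwm.motif_id, "gained"), 0) + gained
    return counts


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class TruthRecord:
    line: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    alt_depth: int
    exclusivity: str  # "shared" | "private"
    fate: str  # "pass" | "fail_qual" | "fail_depth" | "fail_spacing"
    region_class: str
    sub_context: str
    gene_id: str  # "" when unassigned
    distance: int
    motif_effect: str  # "none" | "lost:<id>" | "gained:<id>"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GroundTruth:
    records: tuple[TruthRecord, ...]
    candidates: Mapping[str, frozenset[str]]  # line -> candidate gene ids
    lines: tuple[str, str]
    expr_threshold: float
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            k = (r.line, r.key)
            if k in seen:
                raise IntegrityError(f"duplicate truth record {k}")
            seen.add(k)
            if r.fate == "fail_qual" and r.qual > 100:
                raise IntegrityError(f"{k}: fail_qual with qual {r.qual}")
            if r.fate == "fail_depth" and (r.qual <= 100 or r.alt_depth > 10):
                raise IntegrityError(f"{k}: inconsistent fail_depth record")

    def by_line(self, line: str) -> list[TruthRecord]:
        return [r for r in self.records if r.line == line]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for line in self.lines:
                fh.write(f"#candidates\t{line}\t{','.join(sorted(self.candidates[line]))}\n")
            fh.write(f"#expr_threshold\t{self.expr_threshold:g}\n")
            fh.write(f"#populations\t{','.join(self.populations)}\n")
            cols = [
                "line", "chrom", "pos", "ref", "alt", "qual", "alt_depth",
                "exclusivity", "fate", "region_class", "sub_context",
                "gene_id", "distance", "motif_effect",
            ]
            fh.write("\t".join(cols) + "\n")
            for r in sorted(self.records, key=lambda r: (r.line, r.key)):
                fh.write(
                    f"{r.line}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.qual:g}\t"
                    f"{r.alt_depth}\t{r.exclusivity}\t{r.fate}\t{r.region_class}\t"
                    f"{r.sub_context}\t{r.gene_id}\t{r.distance}\t{r.motif_effect}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        candidates: dict[str, frozenset[str]] = {}
        expr_threshold = 0.0
        populations: tuple[str, ...] = ()
        records: list[TruthRecord] = []
        header: list[str] | None = None
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if line.startswith("#candidates\t"):
                    _, lab, genes = line.split("\t")
                    candidates[lab] = frozenset(g for g in genes.split(",") if g)
                    continue
                if line.startswith("#expr_threshold\t"):
                    expr_threshold = float(line.split("\t")[1])
                    continue
                if line.startswith("#populations\t"):
                    populations = tuple(line.split("\t")[1].split(","))
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                f = dict(zip(header, line.split("\t")))
                records.append(
                    TruthRecord(
                        line=f["line"], chrom=f["chrom"], pos=int(f["pos"]),
                        ref=f["ref"], alt=f["alt"], qual=float(f["qual"]),
                        alt_depth=int(f["alt_depth"]), exclusivity=f["exclusivity"],
                        fate=f["fate"], region_class=f["region_class"],
                        sub_context=f["sub_context"], gene_id=f["gene_id"],
                        distance=int(f["distance"]), motif_effect=f["motif_effect"],
                    )
                )
        lines = tuple(candidates)
        return cls(tuple(records), candidates, (lines[0], lines[1]),
                   expr_threshold, populations)


# ---------------------------------------------------------------------------
# Brute-force truth classifier (independent of gene_assignment)
# ---------------------------------------------------------------------------

def _true_annotation(
    chrom: str,
    span: tuple[int, int],
    genes: Mapping[str, GeneModel],
    regions: Sequence[RegulatoryRegion],
    max_distance: int = 100_000,
) -> tuple[str, str, str, int]:
    """(region_class, sub_context, gene_id, distance) by per-base membership."""
    bases = range(span[0], span[1] + 1)

    def order(g: GeneModel) -> tuple[int, str]:
        return (g.span_start, g.gene_id)

    cds_genes = [
        g for g in genes.values()
        if g.chrom == chrom and any(any(s <= b <= e for s, e in g.cds) for b in bases)
    ]
    if cds_genes:
        g = min(cds_genes, key=order)
        return ("CDS", "exonic_CDS", g.gene_id, 0)
    host_genes = [
        g for g in genes.values()
        if g.chrom == chrom and any(g.span_start <= b <= g.span_end for b in bases)
    ]
    if host_genes:
        g = min(host_genes, key=order)
        in_exon = any(any(s <= b <= e for s, e in g.exons) for b in bases)
        if not in_exon:
            return ("nCDS", "intronic", g.gene_id, 0)
        extent = g.cds_extent
        if extent is None:
            return ("nCDS", "noncoding_exon", g.gene_id, 0)
        mid = (span[0] + span[1]) // 2
        if mid < extent[0]:
            sub = "UTR5" if g.strand == "+" else "UTR3"
        elif mid > extent[1]:
            sub = "UTR3" if g.strand == "+" else "UTR5"
        else:
            sub = "noncoding_exon"
        return ("nCDS", sub, g.gene_id, 0)
    in_rr = any(
        r.chrom == chrom and any(r.start <= b <= r.end for b in bases) for r in regions
    )
    region_class = "RR" if in_rr else "intergenic"
    best: tuple[int, int, str] | None = None
    for g in genes.values():
        if g.chrom != chrom:
            continue
        if span[1] < g.span_start:
            d = g.span_start - span[1]
        elif span[0] > g.span_end:
            d = span[0] - g.span_end
        else:
            d = 0
        cand = (d, g.span_start, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None or best[0] > max_distance:
        return (region_class, "regulatory" if in_rr else "none", "", -1)
    return (region_class, "regulatory" if in_rr else "none", best[2], best[0])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    regions: tuple[RegulatoryRegion, ...]
    gene_sets: GeneSetCollection
    expression: ExpressionTable
    vcf_a: VariantSet
    vcf_b: VariantSet
    pwms: list[PWM]
    truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


@dataclass
class _Site:
    line: str | None  # None => shared
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    depth: int
    fate: str
    motif_effect: str = "none"


class _Layout:
    """Deterministic gene/zone geometry over the simulated chromosomes."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
        genes_per_chrom = -(-cfg.n_genes // cfg.n_chroms)
        self.block = cfg.chrom_length // genes_per_chrom
        self.genes: dict[str, GeneModel] = {}
        self.regions: list[RegulatoryRegion] = []
        self.zones: list[dict] = []  # per gene: {kind: (lo, hi)} in genomic coords
        for i in range(cfg.n_genes):
            chrom = self.chroms[i % cfg.n_chroms]
            block_idx = i // cfg.n_chroms
            b0 = block_idx * self.block + 1  # 1-based block start
            span_len = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
            s = b0 + 700
            e = s + span_len - 1
            intron_total = span_len - 900
            i1 = int(round(intron_total * 0.6))
            exon1 = (s, s + 299)
            exon2 = (s + 300 + i1, s + 300 + i1 + 299)
            exon3 = (e - 299, e)
            strand = "+" if i % 2 == 0 else "-"
            gid = f"gene{i + 1:04d}"
            cds_lo, cds_hi = s + 100, e - 100
            cds = []
            for xs, xe in (exon1, exon2, exon3):
                lo, hi = max(xs, cds_lo), min(xe, cds_hi)
                if lo <= hi:
                    cds.append((lo, hi))
            gene = GeneModel(
                gene_id=gid, name=f"Sim{i + 1}", chrom=chrom, strand=strand,
                span_start=s, span_end=e, exons=(exon1, exon2, exon3), cds=tuple(cds),
            )
            rr = RegulatoryRegion(
                chrom=chrom, start=b0 + 99, end=b0 + 298, target_gene_id=gid,
                source_label="sim_regulatory",
            )
            self.genes[gid] = gene
            self.regions.append(rr)
            intron1 = (s + 300, exon2[0] - 1)
            self.zones.append(
                {
                    "gene_id": gid,
                    "cds": (exon2[0] + 10, exon2[1] - 10),
                    "intron": (intron1[0] + 120, intron1[1] - 120),
                    "utr_left": (s + 5, s + 94),
                    "utr_right": (e - 94, e - 5),
                    "rr": (rr.start + 10, rr.end - 10),
                    "intergenic": (e + 200, b0 + self.block - 1700),
                    "rr_region": rr,
                }
            )
            if self.zones[-1]["intergenic"][0] >= self.zones[-1]["intergenic"][1]:
                raise ConfigurationError("block too small for an intergenic zone")


def _draw_qual_depth(cfg: SimConfig, rng: np.random.Generator, forced_pass: bool):
    if forced_pass:
        q_pass, d_pass = True, True
    else:
        q_pass = rng.random() < cfg.p_qual_pass
        d_pass = rng.random() < cfg.p_depth_pass
    q_rng = cfg.qual_pass if q_pass else cfg.qual_fail
    d_rng = cfg.depth_pass if d_pass else cfg.depth_fail
    qual = float(rng.integers(int(q_rng[0]), int(q_rng[1]) + 1))
    depth = int(rng.integers(d_rng[0], d_rng[1] + 1))
    if not q_pass:
        fate = "fail_qual"
    elif not d_pass:
        fate = "fail_depth"
    else:
        fate = "pass"
    return qual, depth, fate


class _Simulator:
    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.motifs = default_sim_motifs()
        self.pwms = _motif_pwms(self.motifs)
        self.w_max = max(p.width for p in self.pwms)
        self.used: dict[str, list[int]] = {}

    # -- position bookkeeping ------------------------------------------------
    def _is_free(self, chrom: str, pos: int, sep: int = MIN_SITE_SEPARATION) -> bool:
        return all(abs(pos - p) >= sep for p in self.used.get(chrom, []))

    def _claim(self, chrom: str, pos: int) -> None:
        insort(self.used.setdefault(chrom, []), pos)

    def _pick_position(self, chrom: str, lo: int, hi: int, room: int = 0) -> int:
        for _ in range(self.cfg.max_tries * 4):
            pos = int(self.rng.integers(lo, hi + 1 - room))
            if self._is_free(chrom, pos):
                return pos
        raise ConfigurationError(
            f"could not place a variant in zone {chrom}:{lo}-{hi} after bounded retries"
        )

    # -- genome --------------------------------------------------------------
    def _make_genome(self, layout: _Layout) -> dict[str, list[str]]:
        return {
            c: list("".join(self.rng.choice(list("ACGT"), size=self.cfg.chrom_length)))
            for c in layout.chroms
        }

    def _plant_word(self, seq: list[str], start: int, word: str) -> None:
        seq[start - 1 : start - 1 + len(word)] = list(word)

    def _reroll_window(self, seq: list[str], lo: int, hi: int, protected: set[int]) -> None:
        """Redraw background bases in [lo, hi] (1-based) outside protected."""
        for p in range(max(1, lo), min(len(seq), hi) + 1):
            if p not in protected:
                seq[p - 1] = str(self.rng.choice(list("ACGT")))

    # -- variant factories ---------------------------------------------------
    def _generic_variant(self, chrom: str, seqs, zone: tuple[int, int], forced_pass: bool,
                         line: str | None, snp_only: bool = False):
        cfg = self.cfg
        seq = seqs[chrom]
        is_indel = (not snp_only) and self.rng.random() < cfg.fraction_indel
        room = 6 if is_indel else 0
        pos = self._pick_position(chrom, zone[0], zone[1], room=room)
        ref_base = seq[pos - 1]
        if not is_indel:
            alt = str(self.rng.choice([b for b in "ACGT" if b != ref_base]))
            ref = ref_base
        elif self.rng.random() < 0.5:  # insertion
            n = int(self.rng.integers(1, 6))
            ref = ref_base
            alt = ref_base + "".join(self.rng.choice(list("ACGT"), size=n))
        else:  # deletion
            n = int(self.rng.integers(1, 6))
            ref = "".join(seq[pos - 1 : pos - 1 + n + 1])
            alt = ref_base
        qual, depth, fate = _draw_qual_depth(cfg, self.rng, forced_pass)
        self._claim(chrom, pos)
        return _Site(line=line, chrom=chrom, pos=pos, ref=ref, alt=alt,
                     qual=qual, depth=depth, fate=fate)

    def _ensure_clean_delta(self, genome: dict[str, str], seqs, site: _Site,
                            expected: dict[tuple[str, str], int],
                            protected: set[int]) -> bool:
        """Re-roll local background until the oracle delta equals ``expected``."""
        v = _site_to_variant(site, site.line or self.cfg.line_a)
        for attempt in range(self.cfg.max_tries):
            genome[site.chrom] = "".join(seqs[site.chrom])
            got = oracle_delta_counts(genome, v, self.pwms, self.cfg.scan_threshold)
            if got == expected:
                return True
            lo = site.pos - (self.w_max - 1) - 1
            hi = site.pos + len(site.ref) - 1 + (self.w_max - 1) + 1
            self._reroll_window(seqs[site.chrom], lo, hi, protected)
            # the ref allele may have changed under the re-roll
            seq = seqs[site.chrom]
            if len(site.ref) == 1 and len(site.alt) == 1:
                site.ref = seq[site.pos - 1]
                choices = [b for b in "ACGT" if b != site.ref]
                site.alt = str(self.rng.choice(choices))
            elif len(site.alt) > len(site.ref):
                site.ref = seq[site.pos - 1]
                site.alt = site.ref + site.alt[1:]
            else:
                site.ref = "".join(seq[site.pos - 1 : site.pos - 1 + len(site.ref)])
                site.alt = site.ref[0]
            v = _site_to_variant(site, site.line or self.cfg.line_a)
        return False

    # -- main ----------------------------------------------------------------
    def run(self) -> SimResult:
        cfg = self.cfg
        layout = _Layout(cfg, self.rng)
        seqs = self._make_genome(layout)
        gene_list = sorted(layout.genes.values(), key=lambda g: g.gene_id)

        n_motif_genes = cfg.n_motif_disruptions + cfg.n_motif_creations
        motif_gene_zones = layout.zones[:n_motif_genes]
        generic_zones = layout.zones[n_motif_genes:]
        motif_ids = list(self.motifs)

        # plant motif words and build the motif variants (all line A)
        protected_words: dict[str, set[int]] = {c: set() for c in layout.chroms}
        motif_sites: list[tuple[_Site, dict]] = []
        for k in range(cfg.n_motif_disruptions):
            zone = motif_gene_zones[k]
            rr: RegulatoryRegion = zone["rr_region"]
            motif_id = motif_ids[k % len(motif_ids)]
            word = self.pwms[motif_ids.index(motif_id)].consensus
            w0 = rr.start + 50
            self._plant_word(seqs[rr.chrom], w0, word)
            word_span = set(range(w0, w0 + len(word)))
            protected_words[rr.chrom] |= word_span
            pos = w0 + 2  # anchor at motif index 2; delete indices 3..5
            seq = seqs[rr.chrom]
            ref = "".join(seq[pos - 1 : pos - 1 + 4])
            site = _Site(line=cfg.line_a, chrom=rr.chrom, pos=pos, ref=ref, alt=ref[0],
                         qual=0, depth=0, fate="pass",
                         motif_effect=f"lost:{motif_id}")
            site.qual, site.depth, _ = _draw_qual_depth(cfg, self.rng, forced_pass=True)
            self._claim(rr.chrom, pos)
            motif_sites.append((site, {(motif_id, "lost"): 1}))
        for k in range(cfg.n_motif_creations):
            zone = motif_gene_zones[cfg.n_motif_disruptions + k]
            rr = zone["rr_region"]
            motif_id = motif_ids[k % len(motif_ids)]
            word = self.pwms[motif_ids.index(motif_id)].consensus
            partial = word[:4] + word[5:]  # word with index 4 missing
            w0 = rr.start + 50
            self._plant_word(seqs[rr.chrom], w0, partial)
            word_span = set(range(w0, w0 + len(partial)))
            protected_words[rr.chrom] |= word_span
            pos = w0 + 3  # anchor at motif index 3; insert the missing base
            site = _Site(line=cfg.line_a, chrom=rr.chrom, pos=pos, ref=word[3],
                         alt=word[3] + word[4], qual=0, depth=0, fate="pass",
                         motif_effect=f"gained:{motif_id}")
            site.qual, site.depth, _ = _draw_qual_depth(cfg, self.rng, forced_pass=True)
            self._claim(rr.chrom, pos)
            motif_sites.append((site, {(motif_id, "gained"): 1}))

        genome = {c: "".join(s) for c, s in seqs.items()}
        for site, expected in motif_sites:
            prot = protected_words[site.chrom] | set(
                range(site.pos, site.pos + len(site.ref))
            )
            if not self._ensure_clean_delta(genome, seqs, site, expected, prot):
                raise ConfigurationError(
                    f"could not plant motif effect at {site.chrom}:{site.pos} cleanly"
                )

        # clustered pairs: SNPs 1..10 nt apart, forced through quality/depth
        pairs_a = -(-cfg.n_clustered_pairs // 2)
        cluster_sites: list[_Site] = []
        for k in range(cfg.n_clustered_pairs):
            line = cfg.line_a if k < pairs_a else cfg.line_b
            zone = generic_zones[k % len(generic_zones)]
            lo, hi = zone["intergenic"]
            gap = int(self.rng.integers(cfg.cluster_gap_range[0], cfg.cluster_gap_range[1] + 1))
            chrom = layout.genes[zone["gene_id"]].chrom
            for _ in range(cfg.max_tries * 4):
                p = int(self.rng.integers(lo, hi - gap))
                if self._is_free(chrom, p, sep=MIN_SITE_SEPARATION + 10):
                    break
            else:
                raise ConfigurationError("could not place a clustered pair")
            for pp in (p, p + gap):
                seq = seqs[chrom]
                ref = seq[pp - 1]
                alt = str(self.rng.choice([b for b in "ACGT" if b != ref]))
                qual, depth, _ = _draw_qual_depth(cfg, self.rng, forced_pass=True)
                cluster_sites.append(
                    _Site(line=line, chrom=chrom, pos=pp, ref=ref, alt=alt,
                          qual=qual, depth=depth, fate="fail_spacing")
                )
                self._claim(chrom, pp)

        # generic shared and private variants, cycling zones over genes
        counter = {"j": 0}

        def make_generic(n: int, line: str | None, forced_pass: bool) -> list[_Site]:
            out = []
            for _ in range(n):
                j = counter["j"]
                counter["j"] += 1
                zone = generic_zones[j % len(generic_zones)]
                kind = ZONE_KINDS[j % len(ZONE_KINDS)]
                if kind == "rr" and zone["gene_id"] in {
                    z["gene_id"] for z in motif_gene_zones
                }:
                    kind = "intergenic"
                chrom = layout.genes[zone["gene_id"]].chrom
                out.append(
                    self._generic_variant(chrom, seqs, zone[kind], forced_pass, line)
                )
            return out

        n_generic_a = cfg.private_a - len([s for s, _ in motif_sites]) - 2 * pairs_a
        n_generic_b = cfg.private_b - 2 * (cfg.n_clustered_pairs // 2)
        generic_a = make_generic(n_generic_a, cfg.line_a, forced_pass=False)
        generic_b = make_generic(n_generic_b, cfg.line_b, forced_pass=False)
        shared = make_generic(cfg.n_shared_variants, None, forced_pass=True)

        genome = {c: "".join(s) for c, s in seqs.items()}

        # keep TFBS truth clean: passing private RR/intergenic variants must
        # produce no spurious motif delta
        all_private = [s for s, _ in motif_sites] + cluster_sites + generic_a + generic_b
        for site in generic_a + generic_b:
            if site.fate != "pass":
                continue
            rc = _true_annotation(site.chrom, (site.pos, site.pos + len(site.ref) - 1),
                                  layout.genes, layout.regions)[0]
            if rc not in ("RR", "intergenic"):
                continue
            prot = protected_words[site.chrom] | set(
                range(site.pos, site.pos + len(site.ref))
            )
            if not self._ensure_clean_delta(genome, seqs, site, {}, prot):
                raise ConfigurationError(
                    f"could not keep background motif-free near {site.chrom}:{site.pos}"
                )
        genome = {c: "".join(s) for c, s in seqs.items()}

        # refresh ref alleles against the final genome (re-rolls above may
        # have touched neighbouring background)
        for site in all_private + shared:
            seq = genome[site.chrom]
            actual = seq[site.pos - 1 : site.pos - 1 + len(site.ref)]
            if actual != site.ref:
                if len(site.ref) == len(site.alt) == 1:
                    site.ref = actual
                    site.alt = str(self.rng.choice([b for b in "ACGT" if b != actual]))
                elif len(site.alt) > len(site.ref):
                    site.ref = actual
                    site.alt = actual + site.alt[1:]
                else:
                    site.ref = actual
                    site.alt = actual[0]

        # assemble variant sets
        var_a = [_site_to_variant(s, cfg.line_a) for s in all_private if s.line == cfg.line_a]
        var_b = [_site_to_variant(s, cfg.line_b) for s in all_private if s.line == cfg.line_b]
        for s in shared:
            var_a.append(_site_to_variant(s, cfg.line_a))
            var_b.append(_site_to_variant(s, cfg.line_b))
        vcf_a = VariantSet.build(cfg.line_a, var_a)
        vcf_b = VariantSet.build(cfg.line_b, var_b)

        # truth records
        records: list[TruthRecord] = []
        for site in all_private + shared:
            rc, sub, gid, dist = _true_annotation(
                site.chrom, (site.pos, site.pos + len(site.ref) - 1),
                layout.genes, layout.regions,
            )
            lines = [site.line] if site.line else [cfg.line_a, cfg.line_b]
            for line in lines:
                records.append(
                    TruthRecord(
                        line=line, chrom=site.chrom, pos=site.pos, ref=site.ref,
                        alt=site.alt, qual=site.qual, alt_depth=site.depth,
                        exclusivity="private" if site.line else "shared",
                        fate=site.fate, region_class=rc, sub_context=sub,
                        gene_id=gid, distance=dist, motif_effect=site.motif_effect,
                    )
                )

        # candidate planting: gene sets + expression chosen so that the
        # motif-effect genes plus a few extra passing genes are candidates,
        # with decoys exercising every rejection path
        pass_genes: dict[str, list[str]] = {cfg.line_a: [], cfg.line_b: []}
        rr_pass_genes: dict[str, list[str]] = {cfg.line_a: [], cfg.line_b: []}
        intronic_pass_genes: dict[str, list[str]] = {cfg.line_a: [], cfg.line_b: []}
        for r in records:
            if r.exclusivity == "private" and r.fate == "pass" and r.gene_id:
                if r.gene_id not in pass_genes[r.line]:
                    pass_genes[r.line].append(r.gene_id)
                if r.region_class in ("RR", "intergenic") and r.gene_id not in rr_pass_genes[r.line]:
                    rr_pass_genes[r.line].append(r.gene_id)
                if r.sub_context == "intronic" and r.gene_id not in intronic_pass_genes[r.line]:
                    intronic_pass_genes[r.line].append(r.gene_id)

        motif_gene_ids = [z["gene_id"] for z in motif_gene_zones]
        cand_a = list(dict.fromkeys(motif_gene_ids))
        # one extra RR/intergenic gene (TFBS-scan negative) and one intronic
        # gene (splice-assessment path), when the draws produced them
        extra_a = [g for g in sorted(rr_pass_genes[cfg.line_a]) if g not in cand_a]
        if not extra_a:
            extra_a = [g for g in sorted(pass_genes[cfg.line_a]) if g not in cand_a]
        cand_a += extra_a[:1]
        cand_a += [g for g in sorted(intronic_pass_genes[cfg.line_a])
                   if g not in cand_a][:1]
        cand_b = [g for g in sorted(pass_genes[cfg.line_b]) if g not in cand_a][:2]

        chosen = set(cand_a) | set(cand_b)
        leftovers = [
            g for g in sorted(set(pass_genes[cfg.line_a]) | set(pass_genes[cfg.line_b]))
            if g not in chosen
        ]
        low_expr_decoy = leftovers[0] if leftovers else None
        no_variant_decoy = next(
            (g.gene_id for g in gene_list
             if g.gene_id not in chosen and g.gene_id != low_expr_decoy
             and g.gene_id not in {r.gene_id for r in records}),
            None,
        )

        core = set(cand_a) | set(cand_b)
        if low_expr_decoy:
            core.add(low_expr_decoy)
        if no_variant_decoy:
            core.add(no_variant_decoy)
        sets = {"CSR_core": frozenset(core)}
        if motif_gene_ids:
            sets["CSR_tfbs"] = frozenset(motif_gene_ids)
        gene_sets = GeneSetCollection(
            sets=sets,
            provenance={"CSR_core": "simulated pathway list",
                        "CSR_tfbs": "simulated ontology list"},
        )

        all_pops = tuple(cfg.populations) + ("T.CD4",)
        expr_values: dict[tuple[str, str], float] = {}
        for g in gene_list:
            for p in all_pops:
                expr_values[(g.gene_id, p)] = round(float(self.rng.uniform(0, 100)), 1)
        for gid in sorted(set(cand_a) | set(cand_b) | ({no_variant_decoy} - {None})):
            for p in cfg.populations:
                expr_values[(gid, p)] = round(float(self.rng.uniform(200, 800)), 1)
        if low_expr_decoy:
            for p in cfg.populations:
                expr_values[(low_expr_decoy, p)] = round(float(self.rng.uniform(1, 50)), 1)
        expression = ExpressionTable(values=expr_values, populations=all_pops)

        # derive the candidate truth brute-force from what was planted
        def is_candidate(gid: str) -> bool:
            in_set = any(gid in members for members in gene_sets.sets.values())
            expressed = any(
                expr_values.get((gid, p), 0.0) > cfg.expr_threshold
                for p in cfg.populations
            )
            return in_set and expressed

        candidates = {
            line: frozenset(g for g in pass_genes[line] if is_candidate(g))
            for line in (cfg.line_a, cfg.line_b)
        }

        truth = GroundTruth(
            records=tuple(sorted(records, key=lambda r: (r.line, r.key))),
            candidates=candidates,
            lines=(cfg.line_a, cfg.line_b),
            expr_threshold=cfg.expr_threshold,
            populations=tuple(cfg.populations),
        )
        return SimResult(
            config=cfg, genome=genome, genes=layout.genes,
            regions=tuple(layout.regions), gene_sets=gene_sets,
            expression=expression, vcf_a=vcf_a, vcf_b=vcf_b,
            pwms=self.pwms, truth=truth,
        )


def _site_to_variant(site: _Site, line: str) -> Variant:
    return Variant(chrom=site.chrom, pos=site.pos, ref=site.ref, alt=site.alt,
                   qual=site.qual, alt_depth=site.depth, line=line)


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate the full synthetic study; optionally write all artifacts.

    Deterministic given ``config.seed``: the same configuration always
    produces byte-identical files.
    """
    result = _Simulator(config).run()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contigs = {c: len(s) for c, s in result.genome.items()}
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "bed": outdir / "regions.bed",
            "gmt": outdir / "gene_sets.gmt",
            "expression": outdir / "expression.tsv",
            "vcf_a": outdir / f"{config.line_a}.vcf",
            "vcf_b": outdir / f"{config.line_b}.vcf",
            "motifs": outdir / "motifs.jaspar",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(result.genome, paths["fasta"])
        write_gff3(result.genes, paths["gff3"])
        write_bed(result.regions, paths["bed"])
        write_gmt(result.gene_sets, paths["gmt"])
        write_expression(result.expression, paths["expression"])
        write_vcf(result.vcf_a, paths["vcf_a"], contigs)
        write_vcf(result.vcf_b, paths["vcf_b"], contigs)
        write_motifs_jaspar(default_sim_motifs(), paths["motifs"])
        result.truth.write_tsv(paths["truth"])
        result.paths = paths
    return result


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class StageMetrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 1.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": round(self.sensitivity, 6),
            "specificity": round(self.specificity, 6),
        }


def truth_report(truth: GroundTruth, run) -> dict:
    """Compare a pipeline run against the planted truth, stage by stage.

    ``run`` is a pipeline RunResult (duck-typed): it must expose
    ``stage_sets`` (stage -> line -> VariantSet), ``annotations``
    (line -> [VariantAnnotation]), ``candidates`` (line -> [CandidateGene])
    and ``effects`` (line -> [VariantEffect]).

    Filter stages report true sensitivity/specificity over planted
    positives and negatives. The annotation stage is a labeling task with
    no natural true-negative cell, so exact-match accuracy of
    (region_class, gene) is reported in both slots.
    """
    metrics: dict[str, StageMetrics] = {
        s: StageMetrics() for s in
        ("exclusivity", "quality_depth", "spacing", "final", "annotation",
         "candidates", "tfbs")
    }
    final_sets = run.stage_sets["spacing"] if "spacing" in run.stage_sets else {}
    # determine the final per-line sets from the last stage present
    order = [s for s in ("exclusivity", "quality_depth", "spacing") if s in run.stage_sets]
    final_sets = run.stage_sets[order[-1]]

    for line in truth.lines:
        recs = truth.by_line(line)
        rec_keys = {r.key for r in recs}
        excl_keys = run.stage_sets["exclusivity"][line].keys()
        qd_keys = run.stage_sets["quality_depth"][line].keys()
        final_keys = final_sets[line].keys()
        if not rec_keys >= final_keys:
            raise IntegrityError(
                f"line {line}: pipeline emitted variant keys absent from the truth ledger"
            )

        m = metrics["exclusivity"]
        for r in recs:
            pred = r.key in excl_keys
            if r.exclusivity == "private":
                m.tp += pred
                m.fn += not pred
            else:
                m.fp += pred
                m.tn += not pred

        m = metrics["quality_depth"]
        for r in recs:
            if r.exclusivity != "private":
                continue
            pred = r.key in qd_keys
            if r.fate in ("pass", "fail_spacing"):
                m.tp += pred
                m.fn += not pred
            else:
                m.fp += pred
                m.tn += not pred

        m = metrics["spacing"]
        for r in recs:
            if r.exclusivity != "private" or r.fate in ("fail_qual", "fail_depth"):
                continue
            pred = r.key in final_keys
            if r.fate == "pass":
                m.tp += pred
                m.fn += not pred
            else:
                m.fp += pred
                m.tn += not pred

        m = metrics["final"]
        for r in recs:
            pred = r.key in final_keys
            truth_pass = r.exclusivity == "private" and r.fate == "pass"
            if truth_pass:
                m.tp += pred
                m.fn += not pred
            else:
                m.fp += pred
                m.tn += not pred

        # annotation accuracy over the truth-final variants
        ann_by_key = {a.variant.key: a for a in run.annotations.get(line, [])}
        m = metrics["annotation"]
        for r in recs:
            if not (r.exclusivity == "private" and r.fate == "pass"):
                continue
            a = ann_by_key.get(r.key)
            ok = (
                a is not None
                and a.region_class.value == r.region_class
                and (a.gene_id or "") == r.gene_id
            )
            m.tp += ok
            m.fn += not ok
            m.tn += ok
            m.fp += not ok

        m = metrics["candidates"]
        truth_cands = truth.candidates[line]
        pred_cands = {c.gene_id for c in run.candidates.get(line, [])}
        variant_genes = {
            r.gene_id for r in recs
            if r.exclusivity == "private" and r.fate == "pass" and r.gene_id
        }
        for gid in sorted(variant_genes):
            pred = gid in pred_cands
            if gid in truth_cands:
                m.tp += pred
                m.fn += not pred
            else:
                m.fp += pred
                m.tn += not pred

        m = metrics["tfbs"]
        planted = {}
        for r in recs:
            if r.motif_effect != "none" and r.fate == "pass":
                status, motif_id = r.motif_effect.split(":")
                planted[(r.key, motif_id, status)] = 1
        predicted: dict[tuple, int] = {}
        scanned_keys = set()
        for e in run.effects.get(line, []):
            if e.region_class in ("RR", "intergenic"):
                scanned_keys.add(e.variant_key)
                for d in e.tfbs:
                    predicted[(e.variant_key, d.motif_id, d.status)] = d.count
        for entry, count in planted.items():
            if predicted.get(entry) == count:
                m.tp += 1
            else:
                m.fn += 1
        for entry in predicted:
            if entry not in planted:
                m.fp += 1
        planted_keys = {k for k, _, _ in planted}
        for k in scanned_keys:
            if k not in planted_keys and not any(pk == k for pk, _, _ in predicted):
                m.tn += 1

    report = {name: m.to_dict() for name, m in metrics.items()}
    report["exact_recovery"] = all(
        m.sensitivity == 1.0 and m.specificity == 1.0 for m in metrics.values()
    )
    return report


def write_truth_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
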