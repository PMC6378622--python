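"""Region classification and nearest-gene assignment vs per-base oracles."""

import numpy as np
import pytest

from substrain_delta.errors import AnnotationMismatchError
from substrain_delta.gene_assignment import (
    AnnotationIndex,
    RegionClass,
    annotate_all,
    assign_nearest_gene,
    classify_variant,
    summarize_classes,
)
from substrain_delta.io_formats import GeneModel, RegulatoryRegion, VariantSet

from conftest import make_variant


def classify_oracle(v, genes, regions):
    """Per-base brute-force: CDS > nCDS > RR > intergenic."""
    bases = range(v.pos, v.pos + len(v.ref))

    def order(g):
        return (g.span_start, g.gene_id)

    cds = [g for g in genes.values()
           if g.chrom == v.chrom
           and any(any(s <= b <= e for s, e in g.cds) for b in bases)]
    if cds:
        return RegionClass.CDS, min(cds, key=order).gene_id
    host = [g for g in genes.values()
            if g.chrom == v.chrom
            and any(g.span_start <= b <= g.span_end for b in bases)]
    if host:
        return RegionClass.NCDS, min(host, key=order).gene_id
    if any(r.chrom == v.chrom and any(r.start <= b <= r.end for b in bases)
           for r in regions):
        return RegionClass.RR, None
    return RegionClass.INTERGENIC, None


def nearest_oracle(v, genes, cap):
    span = (v.pos, v.pos + len(v.ref) - 1)
    best = None
    for g in genes.values():
        if g.chrom != v.chrom:
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
    if best is None or best[0] > cap:
        return None, None
    return best[2], best[0]


def random_annotation(rng, chrom_len=3000, n_genes=4, n_regions=3):
    genes = {}
    for i in range(n_genes):
        s = int(rng.integers(1, chrom_len - 400))
        e = s + int(rng.integers(100, 400))
        n_ex = int(rng.integers(1, 4))
        cuts = sorted(rng.integers(s, e + 1, size=2 * n_ex))
        exons = [(int(cuts[2 * k]), int(cuts[2 * k + 1])) for k in range(n_ex)]
        exons = [(a, b) for a, b in exons if a <= b] or [(s, e)]
        cds = []
        if rng.random() < 0.8:
            for a, b in exons:
                if b - a >= 2 and rng.random() < 0.7:
                    cds.append((a + 1, b - 1))
        gid = f"g{i}"
        genes[gid] = GeneModel(
            gene_id=gid, name=gid, chrom="chr1",
            strand="+" if rng.random() < 0.5 else "-",
            span_start=s, span_end=e, exons=tuple(exons), cds=tuple(cds),
        )
    regions = tuple(
        RegulatoryRegion("chr1", int(s), int(s) + int(rng.integers(10, 100)))
        for s in rng.integers(1, chrom_len - 110, size=n_regions)
    )
    return genes, regions


class TestClassification:
    def test_cds_beats_regulatory_region(self):
        genes = {"g1": GeneModel("g1", "g1", "chr1", "+", 100, 500,
                                 ((100, 500),), ((150, 450),))}
        regions = (RegulatoryRegion("chr1", 100, 500),)
        index = AnnotationIndex(genes, regions)
        rc, sub, gid = classify_variant(make_variant(pos=200), index)
        assert rc == RegionClass.CDS and sub == "exonic_CDS" and gid == "g1"

    def test_intronic_context(self):
        genes = {"g1": GeneModel("g1", "g1", "chr1", "+", 100, 500,
                                 ((100, 200), (400, 500)), ((150, 200), (400, 450)))}
        index = AnnotationIndex(genes, ())
        rc, sub, gid = classify_variant(make_variant(pos=300), index)
        assert rc == RegionClass.NCDS and sub == "intronic"

    def test_utr_labels_are_strand_aware(self):
        plus = {"g1": GeneModel("g1", "g1", "chr1", "+", 100, 500,
                                ((100, 500),), ((200, 400),))}
        minus = {"g1": GeneModel("g1", "g1", "chr1", "-", 100, 500,
                                 ((100, 500),), ((200, 400),))}
        v = make_variant(pos=150)
        assert classify_variant(v, AnnotationIndex(plus, ()))[1] == "UTR5"
        assert classify_variant(v, AnnotationIndex(minus, ()))[1] == "UTR3"

    def test_unknown_chromosome_errors(self):
        index = AnnotationIndex({}, (), known_chroms={"chr1"})
        with pytest.raises(AnnotationMismatchError):
            classify_variant(make_variant(chrom="chrX"), index)

    def test_matches_per_base_oracle_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            genes, regions = random_annotation(rng)
            index = AnnotationIndex(genes, regions)
            for _ in range(25):
                pos = int(rng.integers(1, 2900))
                ref = "A" * int(rng.integers(1, 5))
                v = make_variant(pos=pos, ref=ref, alt="G" if ref == "A" else "G")
                rc, _, gid = classify_variant(v, index)
                orc, ogid = classify_oracle(v, genes, regions)
                assert rc == orc
                if orc in (RegionClass.CDS, RegionClass.NCDS):
                    assert gid == ogid

    def test_order_invariance_and_strand_invariance(self):
        rng = np.random.default_rng(12)
        genes, regions = random_annotation(rng)
        flipped = {
            gid: GeneModel(g.gene_id, g.name, g.chrom,
                           "-" if g.strand == "+" else "+",
                           g.span_start, g.span_end, g.exons, g.cds)
            for gid, g in genes.items()
        }
        shuffled = dict(reversed(list(genes.items())))
        i1 = AnnotationIndex(genes, regions)
        i2 = AnnotationIndex(shuffled, tuple(reversed(regions)))
        i3 = AnnotationIndex(flipped, regions)
        for _ in range(50):
            v = make_variant(pos=int(rng.integers(1, 2900)))
            c1, c2, c3 = (classify_variant(v, i) for i in (i1, i2, i3))
            assert c1[0] == c2[0] == c3[0]
            assert c1[2] == c2[2] == c3[2]


class TestNearestGene:
    def test_minimization_and_tie_break(self):
        genes = {
            "gX": GeneModel("gX", "gX", "chr1", "+", 1000, 2000, ((1000, 2000),), ()),
            "gY": GeneModel("gY", "gY", "chr1", "+", 4500, 5000, ((4500, 5000),), ()),
        }
        index = AnnotationIndex(genes, ())
        assert assign_nearest_gene(make_variant(pos=2500), index) == ("gX", 500)
        # equidistant: 3250 is 1250 from both span edges -> smaller span_start
        assert assign_nearest_gene(make_variant(pos=3250), index)[0] == "gX"

    def test_cap_yields_none(self):
        genes = {"gX": GeneModel("gX", "gX", "chr1", "+", 1, 10, ((1, 10),), ())}
        index = AnnotationIndex(genes, ())
        assert assign_nearest_gene(make_variant(pos=5000), index,
                                   max_assign_distance=100) == (None, None)

    def test_matches_exhaustive_oracle_randomized(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            genes, _ = random_annotation(rng)
            index = AnnotationIndex(genes, ())
            for _ in range(20):
                v = make_variant(pos=int(rng.integers(1, 3000)))
                assert assign_nearest_gene(v, index, 500) == nearest_oracle(v, genes, 500)


class TestAnnotateAll:
    def test_empty_set(self):
        vs = VariantSet.build("lineA", [])
        assert annotate_all(vs, {}, (), known_chroms={"chr1"}) == []

    def test_geneless_genome_is_all_intergenic(self):
        vs = VariantSet.build("lineA", [make_variant(pos=p) for p in (10, 1000)])
        anns = annotate_all(vs, {}, (), known_chroms={"chr1"})
        assert all(a.region_class == RegionClass.INTERGENIC and a.gene_id is None
                   for a in anns)

    def test_recovers_simulated_truth_classes(self, sim, pipeline_run):
        for line in sim.truth.lines:
            truth = {r.key: (r.region_class, r.gene_id)
                     for r in sim.truth.by_line(line)
                     if r.exclusivity == "private" and r.fate == "pass"}
            got = {a.variant.key: (a.region_class.value, a.gene_id or "")
                   for a in pipeline_run.annotations[line]}
            assert got == truth

    def test_summary_counts_total(self, pipeline_run):
        for line, anns in pipeline_run.annotations.items():
            counts = summarize_classes(anns)
            assert sum(counts.values()) == len(anns)
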