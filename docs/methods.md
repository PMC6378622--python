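# Methods

## Scope and model

The package compares two inbred-line variant call sets against a shared
reference and carries the result through to regulatory effect predictions.
It deliberately starts *after* read mapping and variant calling: its inputs
are VCF 4.x files plus the reference FASTA, a GFF3 gene annotation, a BED
file of regulatory regions, GMT gene sets and a long-format expression
table. Nothing upstream (trimming, alignment, genotyping) and nothing
downstream of prediction (wet-lab validation, enrichment statistics) is in
scope.

All internal coordinates are 1-based inclusive, matching VCF and GFF3; the
only conversion happens once when BED (0-based half-open) is read. Variants
are normalized at the VCF boundary: multi-allelic records are split into
one record per alternate allele *before* any filter, so every comparison is
allele-aware, and each (ref, alt) pair is reduced to its minimal
representation (shared trailing bases trimmed, then shared leading bases,
keeping the single anchor base for indels). Reference-based left-alignment
of indels is not performed — the reader operates on the VCF alone — so
call sets produced by different non-left-aligning callers should be
normalized externally first.

## Exclusivity filter

Four conditions define a line-exclusive variant, all thresholds strict:

- call quality `QUAL > 100`;
- alternate-allele depth `> 10` reads, taken from `FORMAT/AD` of the first
  sample (second field onward) or, failing that, `INFO/DP4` (sum of the
  last two values); records with neither are dropped and counted;
- distance `> 10` nt between anchor positions of same-chromosome,
  same-line variants. Because a close pair of calls is mutually suspect
  (typically alignment noise around an indel), the default `drop-all` mode
  removes *both* members of any pair at distance ≤ 10 — equivalently, any
  variant with some neighbour that close, which a sorted adjacent-pair
  sweep computes exactly as the all-pairs definition does. A keep-first
  greedy mode is available (`--spacing-mode keep-first`);
- absence of the variant's full `(chrom, pos, ref, alt)` key from the
  other line's call set. By default exclusivity is keyed against the other
  line's **unfiltered** normalized set: "not present in the other line" is
  read conservatively as "not called there at all, even weakly". Keying
  against the other line's filtered set is available
  (`--exclusivity-against filtered`), as is position-only matching through
  the library API. Stage order is exclusivity → quality/depth → spacing
  in the default mode.

The stage report telescopes (output of stage *k* is the input of stage
*k* + 1) and ends in per-line SNP and indel counts of the exclusive sets;
a 1:1 single-base substitution counts as a SNP, everything else as indel.

## Gene assignment

Each variant's affected reference span `[pos, pos + len(ref) − 1]` is
tested against interval indices with fixed priority
`CDS > nCDS > RR > intergenic`. Gene models are gene-level isoform unions:
exon and CDS intervals are merged across transcripts, because assignment
and triage operate on genes, not transcripts. Inside a gene span the
finest non-coding context is reported (intron, 5′/3′ UTR by strand-aware
position relative to the CDS extent, or non-coding exon). Regulatory and
intergenic variants are assigned the nearest gene on the chromosome —
distance from the affected span to the gene span, 0 when overlapping, ties
broken by smaller gene start then lexicographic id — up to
`max_assign_distance` (default 100,000 nt; a cap is required for a defined
contract since "neighbouring gene" is otherwise unbounded). Strand never
affects class or distance, only the UTR5/UTR3 label. Classification is a
total function and independent of input file order.

## Candidate triage

A candidate gene must (i) carry ≥ 1 exclusive-variant annotation,
(ii) belong to ≥ 1 supplied gene set, and (iii) have expression strictly
above `expr_threshold` in ≥ 1 designated population. The expression test
is a presence check, not a differential one; a gene absent from the table
fails it (counted, not an error). There is no principled universal cutoff
for "expressed" in arbitrary units, so the threshold is explicit
configuration (default 120, chosen once for the bundled synthetic units
where planted candidates sit in the hundreds and background below 100).
Genes reached only via nearest-gene intergenic assignment are triaged
identically, keeping `intergenic` in the output table. Triage is monotone:
adding gene sets never removes a candidate, raising the expression
threshold never adds one.

## PWM scanning and TFBS deltas

A motif is a position probability matrix; counts are converted with a
pseudocount ε = 0.01 per cell, `p = (c + ε) / (N + 4ε)`. Scores are summed
log₂ odds against a background distribution (uniform by default), and each
matrix's attainable extremes map a raw score to a relative score in
[0, 1]. The default reporting threshold is relative ≥ 0.80 — a
conventional stand-in for curated per-matrix cutoffs, configurable. Both
strands are scanned; a minus-strand site is scored on the reverse
complement of its window position-by-position in motif order, which makes
strand symmetry exact to the last bit (and lets the test suite demand
bit-identical agreement with a per-offset brute-force oracle). Ambiguous
(N) bases contribute their expected log-odds under the background,
`Σ_b q(b) log₂(p(b,i)/q(b))`, which is bounded by the per-position
extremes, so relative scores stay in [0, 1] even at window edges.

For a variant, the scan window is the reference interval
`[pos − (Wmax−1), pos + len(ref) − 1 + (Wmax−1)]` (Wmax = widest motif),
clipped to the chromosome; the alternate window substitutes the alt
allele. A site belongs to the edit when its interval overlaps the edited
span. Because indels shift coordinates, sites are not paired by exact
position: for each (motif, strand) the counts of span-overlapping sites on
the two sides are compared, `lost = max(n_ref − n_alt, 0)` and
`gained = max(n_alt − n_ref, 0)`. This reduces to a simple
present/absent call when at most one site is involved, handles multiple
overlapping placements of one motif coherently, and is exactly symmetric
under allele swap (ref↔alt exchanges lost↔gained). A mismatch between the
variant's REF and the genome is a hard error.

## Splice-window assessment

Intronic variants are checked against fixed windows at each intron
boundary of their host gene, strand-aware: donor = last 3 exonic + first
6 intronic nt (9-mer, GT at +1/+2), acceptor = last 14 intronic + first
exonic nt (15-mer, AG at −2/−1). The bundled donor/acceptor matrices are
consensus frequency tables of approximate mammalian splice-site
composition — a deliberately simple surrogate for dedicated splice
predictors, not a reimplementation of any of them. A variant inside a
window is scored as the alt − ref change in window score, the alternate
window re-extracted from the edited chromosome anchored at the
exon-boundary side (so indels shift the intron side, not the conserved
boundary). Verdict: `possible_effect` iff inside a window and
|Δ| > `splice_delta_threshold` (default 2.0 bits); anything deep intronic
is `no_predicted_effect` by construction.

## Synthetic study and what it shows

The simulator emits a complete study whose defaults are the package's
reference conditions: 1 chromosome × 200 kb of i.i.d. uniform ACGT
background, 30 genes (3 exons each, 100-nt UTRs, upstream 200-nt
regulatory region per gene), 40 shared variants, 30 private variants per
line, quality and depth drawn from two-component distributions straddling
the >100 / >10 cutoffs (pass components: qual 101–500, depth 11–60; fail
components: 20–100 and 1–10; component probability 0.5 each) so every
filter branch is exercised, 6 clustered pairs at gaps of 1–10 nt, indels
1–5 nt with correct anchor bases, and 4 planted motif effects in
regulatory regions: 3 deletions each destroying an exact 8-mer motif
instance and 1 insertion completing a partial instance. Deletions and an
insertion were chosen for the planted effects because a single-base
substitution in a sharp 8-mer still scores ≈ 0.87 relative — above the
0.80 reporting threshold — so point mutations do not cleanly delete a
site at default settings; multi-base edits model the effect class
directly. Planted motif variants and clustered pairs are forced into the
passing quality/depth components so each stage's truth stays independent.

Every planted motif effect is verified at generation time by an
independent brute-force scanner, with local background re-rolled (bounded
retries) if a spurious hit appears near a planted site or under a
passing regulatory/intergenic variant's scan window; distinct variant
anchors are kept ≥ 25 nt apart so only the planted pairs trip the spacing
filter. Gene sets and expression are constructed so the motif-effect
genes, one extra regulatory/intergenic-hit gene, one intronic-hit gene and
two line-B genes are candidates, with decoys exercising every rejection
path (gene in no set; gene in a set with low expression; expressed set
member without variants). The ground truth itself is derived by an
independent per-base classifier over the emitted annotation, not by
trusting the placement bookkeeping.

`truth_report` scores a pipeline run per stage: sensitivity and
specificity over planted positives/negatives for the filter stages,
candidate recovery over genes with passing variants, and exact
(variant, motif, status, count) matching for TFBS deltas. The annotation
stage is a labeling task with no natural true-negative cell, so
exact-match accuracy of (class, gene) fills both slots. Everything is
deterministic given the seed, to the byte.

What passing shows — and what it does not: the synthetic background has
no repeats, GC structure, mutational spectrum, linkage or alignment
artifacts, and the planted expression units are arbitrary. Exact recovery
demonstrates that the bookkeeping, coordinate handling, filter logic and
scanning are correct, not that the thresholds are optimal for real
genomes.

## Numerical and design choices

- Strict inequalities throughout the filter, as specified by the cutoffs
  (>100, >10, >10 nt).
- Scan scores in float64; oracle equivalence is bit-exact because window
  scores are accumulated in motif-position order.
- Reports print floats with 6 significant digits; reruns with the same
  config are byte-identical apart from the wall-time entry.
- `simulate` seeds a single `numpy` generator; all placement, allele,
  quality and expression draws flow from it in a fixed order.
- Problem sizes in tests (sequences of tens of nt, genomes of a few kb for
  oracle comparisons, the 200 kb default study) are chosen so the whole
  suite and the acceptance script run in seconds while still covering
  hundreds of randomized instances per property.

## Known limitations

- No reference-based left-alignment of indels; differently normalized
  inputs can defeat key-based exclusivity.
- Gene-level assignment only: no transcript consequences (missense/
  synonymous calling is out of scope).
- The splice surrogate scores fixed consensus windows; branch points,
  exonic enhancers/silencers and cryptic sites are not modelled.
- TFBS predictions are threshold-dependent motif matches, not binding
  measurements; counts of overlapping placements of one motif depend on
  the overlap-based correspondence rule described above.
- Expression triage is a presence filter in the units of the supplied
  table; it performs no normalization.
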