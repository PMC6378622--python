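# substrain-delta

Substrain-exclusive variant filtering and regulatory effect prediction for
paired inbred-line genomes.

## The problem

Inbred mouse lines obtained from different vendors drift apart: after enough
generations of separate breeding, each substrain carries fixed private
mutations the other lacks. When two such lines differ in a quantitative
immune phenotype — for example, the efficiency of antibody class-switch
recombination (CSR) in germinal-center B cells — those line-private variants
are a natural candidate pool for the causal regulators. This package
implements the downstream genomic arm of such a comparison, for
bioinformaticians starting from per-line variant calls (VCF) against a
shared reference:

1. **Line-exclusive filtering.** From two call sets *A* and *B*, keep
   variants with call quality `QUAL > 100`, alternate-allele read depth
   `> 10`, more than `10` nt from any same-line neighbour, and absent — by
   full `(chrom, pos, ref, alt)` key — from the other line. Both cutoffs are
   strict; both members of a close pair are dropped.
2. **Gene assignment.** Each exclusive variant gets exactly one region class
   with priority `CDS > nCDS > RR > intergenic` (coding sequence; non-coding
   genic: UTR/intron/non-coding exon; regulatory region; intergenic), and a
   gene: its host gene when genic, otherwise the nearest gene within a
   distance cap (default 100 kb).
3. **Candidate triage.** A gene is a candidate when it carries at least one
   exclusive variant, belongs to at least one supplied gene set (pathway /
   ontology lists of known CSR mediators, in GMT format), and is expressed —
   value above a threshold — in at least one designated B-cell population.
4. **Effect prediction.** Regulatory-region and intergenic candidate
   variants are scanned allele-aware with position-weight matrices (PWMs):
   a window around the variant is scored on both strands for reference and
   alternate alleles with the log-odds score
   `S = Σᵢ log₂ p(bᵢ, i) / q(bᵢ)`, normalized to a relative score
   `(S − Smin)/(Smax − Smin) ∈ [0, 1]`; sites present on one side only, at
   the edited span, are reported as **lost** or **gained** binding sites.
   Intronic variants get a donor/acceptor splice-window assessment
   (consensus-PWM surrogate), and UTR variants a location flag.

A bundled simulator (`substrain_delta.simulate`) generates complete
self-contained toy studies — genome, annotation, regulatory regions, gene
sets, expression table, two VCFs and motif matrices — with a per-variant
ground-truth ledger, so every stage of the pipeline can be scored for exact
recovery.

## Worked example

`examples/02_tfbs_gain_loss.py` plants an exact instance of an 8-mer motif
(consensus `AAACGGTC`) in random background and assesses two edits:

```
deletion ACGGT>A at 153: lost 1 site(s) of TFA (SIM001)
insertion C>CG at 154: gained 1 site(s) of TFA (SIM001)
```

The deletion removes motif core bases, so the reference allele has a scan
hit overlapping the edited span that the alternate allele lacks — one lost
site. The insertion completes a partial instance — one gained site.

`examples/03_full_pipeline.py` runs the whole chain on the default
synthetic study (one 200 kb chromosome, 30 genes, 40 shared + 30 private
variants per line, 6 clustered pairs, 3 planted motif-site deletions, 1
insertion-created site, seed 7):

```
lineA: 11 exclusive variants, 6 candidate genes: ['gene0001', 'gene0002', 'gene0003', 'gene0004', 'gene0007', 'gene0016']
  gene0001 ('chr1', 152, 'ACGG', 'A'): lost TFA site
  gene0002 ('chr1', 6818, 'TTAG', 'T'): lost TFB site
  gene0003 ('chr1', 13484, 'GATC', 'G'): lost TFC site
  gene0004 ('chr1', 20151, 'C', 'CG'): gained TFA site
lineB: 7 exclusive variants, 3 candidate genes: ['gene0007', 'gene0011', 'gene0016']
  gene0016 ('chr1', 101836, 'T', 'TCAC'): splice no_predicted_effect
exact recovery of planted truth: True
```

Sensitivity and specificity are 1.0 at every stage: the pipeline kept
exactly the planted private well-supported variants, labeled each with its
true region class and gene, and called exactly the planted binding-site
gains and losses.

## Command line

```bash
substrain-delta simulate --outdir study/
substrain-delta filter --vcf-a A.vcf --vcf-b B.vcf --out-dir filtered/
substrain-delta assign --vcf filtered/exclusive_lineA.vcf --gff genes.gff3 \
    --bed regions.bed --out annotations_A.tsv
substrain-delta run-all --config pipeline.yaml
```

Exit codes: 0 ok, 2 usage/config, 3 format, 4 integrity/reference mismatch.

## Layout

- `src/substrain_delta/io_formats.py` — domain types; VCF/GFF3/BED/GMT/TSV/FASTA I/O
- `src/substrain_delta/exclusivity_filter.py` — quality/depth/spacing/exclusivity filters
- `src/substrain_delta/gene_assignment.py` — region classification, nearest-gene assignment
- `src/substrain_delta/candidate_triage.py` — gene-set + expression triage, candidate table
- `src/substrain_delta/effect_prediction.py` — PWM scanning, TFBS deltas, splice windows
- `src/substrain_delta/synthetic_data.py` — study simulator, ground truth, recovery metrics
- `src/substrain_delta/pipeline.py`, `cli.py` — orchestration and the thin CLI
- `docs/methods.md` — model, parameters, numerical choices, limitations
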