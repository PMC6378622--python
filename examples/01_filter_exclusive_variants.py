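"""Derive line-exclusive variant lists from a simulated pair of call sets.

Builds a small two-line study, then applies the filter chain — exclusivity
against the other line's raw calls, quality > 100, alt-allele depth > 10,
and > 10 nt spacing between same-line variants — and prints the per-stage
counts and the final SNP/indel summary per line.
"""

from substrain_delta import SimConfig, apply_filters, simulate

sim = simulate(SimConfig(seed=11, chrom_length=100_000, n_genes=15,
                         n_shared_variants=20, n_private_variants=15,
                         n_clustered_pairs=2))

final_a, final_b, report, _ = apply_filters(sim.vcf_a, sim.vcf_b)

print(f"input: {len(sim.vcf_a)} calls in {sim.vcf_a.line}, "
      f"{len(sim.vcf_b)} in {sim.vcf_b.line}")
for stage in report.stages:
    print(f"  {stage.line:6s} {stage.name:14s} {stage.n_in:3d} -> {stage.n_out:3d}"
          f"  (dropped {stage.n_in - stage.n_out})")
for line in (sim.vcf_a.line, sim.vcf_b.line):
    print(f"{line}: {report.snp_counts[line]} exclusive SNPs, "
          f"{report.indel_counts[line]} exclusive indels")

# Shared calls vanish at the exclusivity stage; weak calls (quality <= 100
# or depth <= 10) and clustered pairs (<= 10 nt apart) fall at the two
# numeric stages. What remains is each line's private, well-supported set.
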