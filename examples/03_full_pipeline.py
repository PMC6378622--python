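"""Run the whole pipeline on the default synthetic study and score it.

Simulates the reference toy study (200 kb chromosome, 30 genes, two lines
with shared and private variants, planted motif effects), runs
filter -> assign -> triage -> predict from the emitted files, and compares
the result against the planted ground truth stage by stage.
"""

import json
import tempfile
from pathlib import Path

from substrain_delta import PipelineConfig, SimConfig, run_all, simulate, truth_report

with tempfile.TemporaryDirectory() as tmp:
    sim = simulate(SimConfig(seed=7), Path(tmp) / "study")
    p = {k: str(v) for k, v in sim.paths.items()}
    run = run_all(PipelineConfig(
        vcf_a=p["vcf_a"], vcf_b=p["vcf_b"], fasta=p["fasta"], gff3=p["gff3"],
        bed=p["bed"], gmt=p["gmt"], expression=p["expression"], motifs=p["motifs"],
        outdir=str(Path(tmp) / "run"),
    ))

    for line in run.lines:
        cands = run.candidates[line]
        print(f"{line}: {len(run.final[line])} exclusive variants, "
              f"{len(cands)} candidate genes: {[c.gene_id for c in cands]}")
        for e in run.effects[line]:
            for d in e.tfbs:
                print(f"  {e.gene_id} {e.variant_key}: {d.status} {d.tf_name} site")
            if e.splice is not None:
                print(f"  {e.gene_id} {e.variant_key}: splice {e.splice.verdict}")

    report = truth_report(sim.truth, run)
    print("exact recovery of planted truth:", report["exact_recovery"])
    print(json.dumps({k: {"sensitivity": v["sensitivity"],
                          "specificity": v["specificity"]}
                      for k, v in report.items() if k != "exact_recovery"},
                     indent=2))

# Sensitivity/specificity of 1.0 at every stage means the pipeline kept
# exactly the planted private well-supported variants, labeled each with its
# true region class and gene, recovered exactly the planted candidate genes,
# and called exactly the planted TFBS gains/losses.
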