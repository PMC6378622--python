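"""Predict transcription-factor binding sites lost and gained by a variant.

Plants an exact motif instance in random background, then shows that a
3-nt deletion through the motif core is reported as a lost site, and an
insertion that completes a partial instance as a gained one — the
allele-aware scan behind the pipeline's regulatory effect calls.
"""

import numpy as np

from substrain_delta import PWM, Variant, tfbs_delta

rng = np.random.default_rng(5)
counts = np.ones((8, 4))
word = "AAACGGTC"  # consensus of the toy motif
for i, b in enumerate(word):
    counts[i, "ACGT".index(b)] = 97
pwm = PWM.from_counts("SIM001", "TFA", counts)

background = "".join(rng.choice(list("ACGT"), size=300))
genome = {"chr1": background[:150] + word + background[150:]}

# deletion of motif bases 4-6 (anchor base kept, VCF-style)
ref = genome["chr1"][152:157]
deletion = Variant(chrom="chr1", pos=153, ref=ref, alt=ref[0],
                   qual=300.0, alt_depth=40, line="lineA")
for d in tfbs_delta(genome, deletion, [pwm], threshold_rel=0.80):
    print(f"deletion {deletion.ref}>{deletion.alt} at {deletion.pos}: "
          f"{d.status} {d.count} site(s) of {d.tf_name} ({d.motif_id})")

# partial instance (one base missing) completed by an insertion
partial_genome = {"chr1": background[:150] + word[:4] + word[5:] + background[150:]}
insertion = Variant(chrom="chr1", pos=154, ref=word[3], alt=word[3] + word[4],
                    qual=300.0, alt_depth=40, line="lineA")
for d in tfbs_delta(partial_genome, insertion, [pwm], threshold_rel=0.80):
    print(f"insertion {insertion.ref}>{insertion.alt} at {insertion.pos}: "
          f"{d.status} {d.count} site(s) of {d.tf_name} ({d.motif_id})")

# A lost site means the reference allele carries a scan hit overlapping the
# edited bases that the alternate allele lacks; a gained site is the converse.
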