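import numpy as np
import pytest

from substrain_delta.io_formats import Variant, VariantSet
from substrain_delta.pipeline import PipelineConfig, run_all
from substrain_delta.synthetic_data import SimConfig, simulate


def make_variant(chrom="chr1", pos=100, ref="A", alt="G", qual=500.0, depth=50,
                 line="lineA") -> Variant:
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                   alt_depth=depth, line=line)


def random_variant_set(rng: np.random.Generator, line: str, n: int,
                       n_chroms: int = 2, pos_max: int = 5000) -> VariantSet:
    """A random SNP set with duplicate-free keys, any spacing."""
    seen = set()
    variants = []
    bases = "ACGT"
    while len(variants) < n:
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        pos = int(rng.integers(1, pos_max))
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        if ref == alt or (chrom, pos, ref, alt) in seen:
            continue
        seen.add((chrom, pos, ref, alt))
        variants.append(
            Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                    qual=float(rng.integers(0, 500)),
                    alt_depth=int(rng.integers(0, 60)), line=line)
        )
    return VariantSet.build(line, variants)


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """The default synthetic study, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("sim")
    return simulate(SimConfig(), outdir)


def pipeline_config_for(sim_result, outdir) -> PipelineConfig:
    p = {k: str(v) for k, v in sim_result.paths.items()}
    return PipelineConfig(
        vcf_a=p["vcf_a"], vcf_b=p["vcf_b"], fasta=p["fasta"], gff3=p["gff3"],
        bed=p["bed"], gmt=p["gmt"], expression=p["expression"], motifs=p["motifs"],
        line_a=sim_result.config.line_a, line_b=sim_result.config.line_b,
        expr_threshold=sim_result.config.expr_threshold,
        populations=tuple(sim_result.config.populations),
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def pipeline_run(sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    return run_all(pipeline_config_for(sim, outdir))
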