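"""Simulator contracts: determinism, planted-truth self-consistency, and
the recovery-metrics report."""

import dataclasses
from pathlib import Path

import pytest

from substrain_delta.errors import ConfigurationError, IntegrityError
from substrain_delta.io_formats import VariantSet, read_fasta, read_vcf
from substrain_delta.synthetic_data import (
    GroundTruth,
    SimConfig,
    TruthRecord,
    default_sim_motifs,
    oracle_delta_counts,
    simulate,
    truth_report,
)

SMALL = dict(chrom_length=80_000, n_genes=12, n_shared_variants=10,
             n_private_variants=10, n_clustered_pairs=2)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        simulate(SimConfig(**SMALL), tmp_path / "a")
        simulate(SimConfig(**SMALL), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seed_differs(self, tmp_path):
        simulate(SimConfig(seed=1, **SMALL), tmp_path / "a")
        simulate(SimConfig(seed=2, **SMALL), tmp_path / "b")
        assert (tmp_path / "a" / "genome.fa").read_bytes() != (
            tmp_path / "b" / "genome.fa"
        ).read_bytes()


class TestPlantedStructure:
    def test_asymmetric_private_counts(self, tmp_path):
        res = simulate(
            SimConfig(n_shared_variants=0, n_private_variants=(5, 0),
                      n_clustered_pairs=0, n_motif_disruptions=0,
                      n_motif_creations=0, **{k: v for k, v in SMALL.items()
                                              if "variant" not in k and "pair" not in k}),
            tmp_path,
        )
        assert len(res.vcf_b) == 0 and len(res.vcf_a) == 5
        assert all(r.exclusivity == "private" and r.line == res.config.line_a
                   for r in res.truth.records)

    def test_private_keys_never_in_other_line(self, sim):
        keys_a, keys_b = sim.vcf_a.keys(), sim.vcf_b.keys()
        for r in sim.truth.records:
            if r.exclusivity == "private":
                other = keys_b if r.line == sim.config.line_a else keys_a
                assert r.key not in other
            else:
                assert r.key in keys_a and r.key in keys_b

    def test_truth_counts_match_config(self, sim):
        cfg = sim.config
        privates = [r for r in sim.truth.records if r.exclusivity == "private"]
        shared = [r for r in sim.truth.records if r.exclusivity == "shared"]
        assert len(privates) == cfg.private_a + cfg.private_b
        assert len(shared) == 2 * cfg.n_shared_variants
        spaced = [r for r in privates if r.fate == "fail_spacing"]
        assert len(spaced) == 2 * cfg.n_clustered_pairs
        effects = [r for r in privates if r.motif_effect != "none"]
        assert len(effects) == cfg.n_motif_disruptions + cfg.n_motif_creations

    def test_clustered_pairs_within_gap(self, sim):
        by_line = {}
        for r in sim.truth.records:
            if r.fate == "fail_spacing":
                by_line.setdefault(r.line, []).append(r.pos)
        lo, hi = sim.config.cluster_gap_range
        for positions in by_line.values():
            positions.sort()
            for p in positions:
                gaps = [abs(p - q) for q in positions if q != p]
                assert lo <= min(gaps) <= hi

    def test_emitted_files_reload_to_memory_model(self, sim):
        assert read_fasta(sim.paths["fasta"]) == sim.genome
        assert read_vcf(sim.paths["vcf_a"], sim.config.line_a) == sim.vcf_a
        assert read_vcf(sim.paths["vcf_b"], sim.config.line_b) == sim.vcf_b
        back = GroundTruth.from_tsv(sim.paths["truth"])
        assert back == sim.truth


class TestMotifTruthSelfConsistency:
    def test_planted_effects_verified_by_bruteforce_rescan(self, sim):
        """Re-scanning the emitted genome reproduces every planted delta."""
        cfg = sim.config
        for r in sim.truth.records:
            if r.motif_effect == "none":
                continue
            status, motif_id = r.motif_effect.split(":")
            v = next(v for v in sim.vcf_a if v.key == r.key)
            got = oracle_delta_counts(sim.genome, v, sim.pwms, cfg.scan_threshold)
            assert got == {(motif_id, status): 1}

    def test_planted_words_are_nonpalindromic_and_distinct(self):
        from substrain_delta.effect_prediction import PWM, reverse_complement

        motifs = default_sim_motifs()
        words = {}
        for mid, (tf, counts) in motifs.items():
            pwm = PWM.from_counts(mid, tf, counts)
            words[mid] = pwm.consensus
        for mid, w in words.items():
            rc = reverse_complement(w)
            assert sum(a != b for a, b in zip(w, rc)) >= 2
            for other_id, other in words.items():
                if other_id != mid:
                    assert sum(a != b for a, b in zip(w, other)) >= 2


class TestConfigValidation:
    def test_infeasible_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(chrom_length=1000)  # no room for a gene block
        with pytest.raises(ConfigurationError):
            SimConfig(n_private_variants=2)  # cannot hold planted features
        with pytest.raises(ConfigurationError):
            SimConfig(line_a="x", line_b="x")

    def test_inconsistent_truth_record_rejected(self):
        rec = TruthRecord(
            line="lineA", chrom="chr1", pos=10, ref="A", alt="G",
            qual=500.0, alt_depth=50, exclusivity="private", fate="fail_qual",
            region_class="CDS", sub_context="exonic_CDS", gene_id="g1",
            distance=0, motif_effect="none",
        )
        with pytest.raises(IntegrityError):
            GroundTruth(records=(rec,), candidates={"lineA": frozenset(),
                                                    "lineB": frozenset()},
                        lines=("lineA", "lineB"), expr_threshold=120,
                        populations=("B.Fo",))


class _FakeRun:
    """Duck-typed pipeline result for degraded-pipeline scenarios."""

    def __init__(self, truth, stage_sets, annotations=None, candidates=None,
                 effects=None):
        self.stage_sets = stage_sets
        self.annotations = annotations or {}
        self.candidates = candidates or {}
        self.effects = effects or {}


class TestTruthReport:
    def test_perfect_pipeline_scores_ones(self, sim, pipeline_run):
        report = truth_report(sim.truth, pipeline_run)
        assert report["exact_recovery"] is True
        for stage, m in report.items():
            if stage == "exact_recovery":
                continue
            assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_disabled_quality_filter_costs_specificity(self, sim, tmp_path):
        from substrain_delta.exclusivity_filter import FilterThresholds, apply_filters

        t = FilterThresholds(min_qual_exclusive=0, min_alt_depth_exclusive=0)
        _, _, _, stage_sets = apply_filters(sim.vcf_a, sim.vcf_b, t)
        report = truth_report(sim.truth, _FakeRun(sim.truth, stage_sets))
        qd = report["quality_depth"]
        assert qd["sensitivity"] == 1.0
        assert qd["fp"] > 0 and qd["specificity"] < 1.0

    def test_empty_pipeline_output_scores_zero_sensitivity(self, sim):
        empty = {
            line: VariantSet.build(line, [])
            for line in (sim.config.line_a, sim.config.line_b)
        }
        stage_sets = {s: empty for s in ("exclusivity", "quality_depth", "spacing")}
        report = truth_report(sim.truth, _FakeRun(sim.truth, stage_sets))
        assert report["exclusivity"]["sensitivity"] == 0.0
        assert report["final"]["sensitivity"] == 0.0
        assert report["exact_recovery"] is False
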