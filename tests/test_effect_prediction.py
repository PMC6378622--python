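"""PWM ingestion, motif scanning vs brute-force and Biopython oracles,
TFBS gain/loss logic, and the splice-window surrogate."""

import numpy as np
import pytest

from substrain_delta.errors import FormatError, ReferenceMismatchError
from substrain_delta.effect_prediction import (
    PWM,
    SpliceWindows,
    default_acceptor_pwm,
    default_donor_pwm,
    read_motifs,
    reverse_complement,
    scan,
    splice_assess,
    tfbs_delta,
)
from substrain_delta.io_formats import GeneModel

from conftest import make_variant

BASES = "ACGT"
IDX = {b: i for i, b in enumerate(BASES)}


def random_pwm(rng, width=None, sharp=False) -> PWM:
    w = width or int(rng.integers(3, 9))
    if sharp:
        counts = np.ones((w, 4))
        for i in range(w):
            counts[i, rng.integers(4)] = 97
    else:
        counts = rng.integers(0, 50, size=(w, 4)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
    return PWM.from_counts("M1", "TF1", counts)


def brute_scan(seq, pwm, threshold):
    """Per-offset, per-strand rescoring in motif-position order."""
    lom = pwm.log_odds
    out = []
    for off in range(len(seq) - pwm.width + 1):
        window = seq[off : off + pwm.width]
        for strand, word in (("+", window), ("-", reverse_complement(window))):
            raw = 0.0
            for i, b in enumerate(word):
                raw += lom[i, IDX.get(b, 4)]
            rel = (raw - pwm.min_score) / (pwm.max_score - pwm.min_score)
            if rel >= threshold:
                out.append((off + 1, strand, raw))
    return sorted(out)


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestReadMotifs:
    JASPAR = """\
>MA0001.1 TFX
A [ 10  0  5 ]
C [  0 10  5 ]
G [  5  5  5 ]
T [  5  5  5 ]
"""
    TRANSFAC = """\
AC  MA0001.1
XX
ID  TFX
XX
P0      A      C      G      T
01     10      0      5      X
02      0     10      5      X
03      5      5      5      X
XX
//
"""

    def test_jaspar_counts_normalize(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(self.JASPAR)
        (pwm,) = read_motifs(p, "jaspar")
        assert pwm.width == 3
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        # zero count with eps=0.01: (0 + 0.01) / (20 + 0.04)
        assert pwm.probs[0, 1] == pytest.approx(0.01 / 20.04)

    def test_transfac_dialect_equivalence(self, tmp_path):
        p1 = tmp_path / "m.jaspar"
        p1.write_text(self.JASPAR)
        p2 = tmp_path / "m.transfac"
        # same counts, TRANSFAC column layout (positions as rows)
        p2.write_text(
            "AC  MA0001.1\nXX\nID  TFX\nXX\n"
            "P0      A      C      G      T\n"
            "01     10      0      5      5\n"
            "02      0     10      5      5\n"
            "03      5      5      5      5\n"
            "XX\n//\n"
        )
        (pj,) = read_motifs(p1, "jaspar")
        (pt,) = read_motifs(p2, "transfac")
        assert np.allclose(pj.probs, pt.probs)
        assert pj.motif_id == pt.motif_id == "MA0001.1"

    def test_unknown_dialect_and_empty_file(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("")
        from substrain_delta.errors import UsageError

        with pytest.raises(UsageError):
            read_motifs(p, "meme")
        with pytest.raises(FormatError):
            read_motifs(p, "jaspar")


class TestScan:
    def test_degenerate_width1_motif(self):
        counts = np.array([[97, 1, 1, 1]])
        pwm = PWM.from_counts("M", "M", counts)
        hits = scan("AAA", pwm, threshold_rel=0.99)
        fwd = [h for h in hits if h.strand == "+"]
        assert [h.start for h in fwd] == [1, 2, 3]

    def test_consensus_scores_max_anticonsensus_min(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            pwm = random_pwm(rng)
            lom = pwm.log_odds
            consensus = pwm.consensus
            anti = "".join(BASES[i] for i in lom[:, :4].argmin(axis=1))
            (hit,) = [h for h in scan(consensus, pwm, 0.999) if h.strand == "+"]
            assert hit.score == pytest.approx(pwm.max_score)
            raw_anti = sum(lom[i, IDX[b]] for i, b in enumerate(anti))
            assert raw_anti == pytest.approx(pwm.min_score)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            pwm = random_pwm(rng)
            seq = random_seq(rng, int(rng.integers(int(pwm.width), 60)))
            thr = float(rng.uniform(0.3, 0.95))
            got = sorted((h.start, h.strand, h.score) for h in scan(seq, pwm, thr))
            assert got == pytest.approx(brute_scan(seq, pwm, thr))

    def test_strand_symmetry_exact(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            pwm = random_pwm(rng)
            seq = random_seq(rng, 50)
            thr = float(rng.uniform(0.3, 0.9))
            fwd = {(h.start, h.strand, h.score) for h in scan(seq, pwm, thr)}
            n = len(seq) - pwm.width + 1
            mirrored = {
                (n + 1 - s, "-" if st == "+" else "+", sc) for s, st, sc in fwd
            }
            rc = {(h.start, h.strand, h.score) for h in scan(reverse_complement(seq), pwm, thr)}
            assert rc == mirrored  # exact, including float scores

    def test_relative_scores_bounded_and_threshold_monotone(self):
        rng = np.random.default_rng(23)
        pwm = random_pwm(rng, width=6)
        seq = random_seq(rng, 300)
        lo = scan(seq, pwm, 0.0)
        assert all(0.0 <= h.relative <= 1.0 for h in lo)
        prev = {(h.start, h.strand) for h in lo}
        for thr in (0.25, 0.5, 0.75, 1.0):
            cur = {(h.start, h.strand) for h in scan(seq, pwm, thr)}
            assert cur <= prev
            prev = cur

    def test_short_sequence_empty(self):
        rng = np.random.default_rng(24)
        assert scan("AC", random_pwm(rng, width=5), 0.5) == []

    def test_n_bases_score_expected_logodds(self):
        counts = np.array([[97, 1, 1, 1], [1, 97, 1, 1]])
        pwm = PWM.from_counts("M", "M", counts)
        # with a uniform background the expected log-odds of a column is
        # sum_b 0.25*log2(4 p_b); must lie within [col_min, col_max]
        lom = pwm.log_odds
        assert np.all(lom[:, 4] >= lom[:, :4].min(axis=1))
        assert np.all(lom[:, 4] <= lom[:, :4].max(axis=1))
        hits = scan("NN", pwm, 0.0)
        assert all(0.0 <= h.relative <= 1.0 for h in hits)


class TestAgainstBiopython:
    def test_pssm_scores_agree(self):
        """Independent cross-check of the scoring core against Bio.motifs."""
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        rng = np.random.default_rng(25)
        for _ in range(5):
            w = int(rng.integers(4, 8))
            counts_int = rng.integers(1, 50, size=(w, 4))
            m = bio_motifs.Motif(
                counts={b: [int(counts_int[i, j]) for i in range(w)]
                        for j, b in enumerate(BASES)}
            )
            pwm_bio = m.counts.normalize(pseudocounts=0.01)
            pssm = pwm_bio.log_odds()
            ours = PWM.from_counts("M", "M", counts_int.astype(float))
            seq = random_seq(rng, 40)
            bio_scores = pssm.calculate(Seq(seq))
            hits = {h.start: h.score for h in scan(seq, ours, -np.inf) if h.strand == "+"}
            for off, expected in enumerate(np.atleast_1d(bio_scores)):
                assert hits[off + 1] == pytest.approx(float(expected), abs=1e-4)


class TestTfbsDelta:
    def setup_method(self):
        counts = np.ones((8, 4))
        word = "AAACGGTC"
        for i, b in enumerate(word):
            counts[i, IDX[b]] = 97
        self.pwm = PWM.from_counts("M1", "TF1", counts)
        self.word = word

    def _genome_with(self, core: str, seed=30, n=400, at=200):
        rng = np.random.default_rng(seed)
        seq = list(random_seq(rng, n))
        seq[at - 1 : at - 1 + len(core)] = list(core)
        return {"chr1": "".join(seq)}

    def test_deletion_destroys_planted_site(self):
        genome = self._genome_with(self.word)
        ref = genome["chr1"][201:206]  # anchor + 4 deleted bases
        v = make_variant(pos=202, ref=ref, alt=ref[0])
        deltas = tfbs_delta(genome, v, [self.pwm], 0.80)
        lost = [d for d in deltas if d.status == "lost" and d.motif_id == "M1"]
        assert len(lost) == 1 and lost[0].count == 1
        assert not [d for d in deltas if d.status == "gained"]

    def test_insertion_creates_site(self):
        partial = self.word[:4] + self.word[5:]
        genome = self._genome_with(partial)
        v = make_variant(pos=203, ref=self.word[3], alt=self.word[3] + self.word[4])
        deltas = tfbs_delta(genome, v, [self.pwm], 0.80)
        gained = [d for d in deltas if d.status == "gained"]
        assert len(gained) == 1 and gained[0].count == 1

    def test_identity_substitution_is_empty(self):
        genome = self._genome_with(self.word)

        # a Variant can never hold ref == alt, so hand tfbs_delta a bare
        # stand-in carrying an unnormalized identity substitution
        class FakeVariant:
            chrom, pos = "chr1", 100
            ref = alt = genome["chr1"][99]
            line = "lineA"
            key = ("chr1", 100, ref, alt)

        assert tfbs_delta(genome, FakeVariant(), [self.pwm], 0.8) == []

    def test_reference_mismatch_hard_fails(self):
        genome = {"chr1": "ACGT" * 100}
        base = genome["chr1"][49]
        wrong = "A" if base != "A" else "C"
        v = make_variant(pos=50, ref=wrong, alt="G" if wrong != "G" else "T")
        with pytest.raises(ReferenceMismatchError):
            tfbs_delta(genome, v, [self.pwm], 0.8)

    def test_allele_swap_symmetry_randomized(self):
        rng = np.random.default_rng(31)
        pwms = [random_pwm(rng, sharp=True) for _ in range(3)]
        for i, p in enumerate(pwms):
            object.__setattr__(p, "motif_id", f"M{i}")
        genome_seq = random_seq(rng, 3000)
        checked = 0
        while checked < 50:
            pos = int(rng.integers(20, 2900))
            kind = rng.integers(3)
            base = genome_seq[pos - 1]
            if kind == 0:
                ref, alt = base, str(rng.choice([b for b in BASES if b != base]))
            elif kind == 1:
                ref = base
                alt = base + random_seq(rng, int(rng.integers(1, 5)))
            else:
                n = int(rng.integers(1, 5))
                ref, alt = genome_seq[pos - 1 : pos + n], base
            if ref == alt:
                continue
            genome = {"chr1": genome_seq}
            v = make_variant(pos=pos, ref=ref, alt=alt)
            fwd = {(d.motif_id, d.status): d.count
                   for d in tfbs_delta(genome, v, pwms, 0.75)}
            # swap: apply alt to the genome, then assess the reverse edit
            swapped_seq = genome_seq[: pos - 1] + alt + genome_seq[pos - 1 + len(ref):]
            v_swap = make_variant(pos=pos, ref=alt, alt=ref)
            rev = {(d.motif_id, d.status): d.count
                   for d in tfbs_delta({"chr1": swapped_seq}, v_swap, pwms, 0.75)}
            assert fwd == {(m, {"lost": "gained", "gained": "lost"}[s]): c
                           for (m, s), c in rev.items()}
            checked += 1


class TestSplice:
    def _gene(self, strand="+"):
        # exons 101-200 and 301-400, intron 201-300
        return GeneModel("g1", "g1", "chr1", strand, 101, 400,
                         ((101, 200), (301, 400)), ((120, 200), (301, 380)))

    def _genome(self, seed=40):
        rng = np.random.default_rng(seed)
        return {"chr1": random_seq(rng, 600)}

    def test_deep_intronic_is_no_effect(self):
        genome = self._genome()
        v = make_variant(pos=250, ref=genome["chr1"][249],
                         alt="A" if genome["chr1"][249] != "A" else "C")
        res = splice_assess(genome, v, self._gene())
        assert res.verdict == "no_predicted_effect"
        assert not res.in_donor_window and not res.in_acceptor_window

    def test_donor_gt_disruption_is_possible_effect(self):
        genome = self._genome()
        seq = list(genome["chr1"])
        seq[200] = "G"  # intron +1
        seq[201] = "T"  # intron +2
        genome = {"chr1": "".join(seq)}
        v = make_variant(pos=201, ref="G", alt="A")
        res = splice_assess(genome, v, self._gene())
        assert res.in_donor_window
        assert res.donor_delta is not None and res.donor_delta < 0
        assert res.verdict == "possible_effect"

    def test_minus_strand_windows_match_bruteforce_extraction(self):
        genome = self._genome()
        gene = self._gene(strand="-")
        # minus-strand donor sits at the intron's genomic end (301 boundary)
        donor = default_donor_pwm()
        v_pos = 300  # intron end = genomic donor +1 for the minus strand
        v = make_variant(pos=v_pos, ref=genome["chr1"][v_pos - 1],
                         alt="A" if genome["chr1"][v_pos - 1] != "A" else "C")
        res = splice_assess(genome, v, gene)
        assert res.in_donor_window
        # brute force: window covers genomic [295, 303]; score rc(window)
        from substrain_delta.effect_prediction import _window_raw_score

        ref_win = reverse_complement(genome["chr1"][294:303])
        alt_chrom = genome["chr1"][: v_pos - 1] + v.alt + genome["chr1"][v_pos:]
        alt_win = reverse_complement(alt_chrom[294:303])
        expected = _window_raw_score(alt_win, donor) - _window_raw_score(ref_win, donor)
        assert res.donor_delta == pytest.approx(expected)

    def test_intronless_gene_is_no_effect(self):
        gene = GeneModel("g1", "g1", "chr1", "+", 101, 400, ((101, 400),), ())
        genome = self._genome()
        v = make_variant(pos=250, ref=genome["chr1"][249],
                         alt="A" if genome["chr1"][249] != "A" else "C")
        res = splice_assess(genome, v, gene)
        assert res.verdict == "no_predicted_effect"

    def test_default_pwms_well_formed(self):
        for pwm in (default_donor_pwm(), default_acceptor_pwm()):
            assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert default_donor_pwm().width == 3 + 6
        assert default_acceptor_pwm().width == 14 + 1
        assert default_donor_pwm().consensus[3:5] == "GT"
        assert default_acceptor_pwm().consensus[12:14] == "AG"
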