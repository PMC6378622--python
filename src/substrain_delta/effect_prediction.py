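"""Regulatory effect prediction for candidate variants.

Two predictions are made per variant, depending on where it falls:

* **TFBS gain/loss** — the local reference window around the variant and
  the same window with the alternate allele substituted are both scanned
  with a set of position-weight matrices (PWMs) on both strands; binding
  sites present on one side but not the other, at the edited span, are
  reported as lost or gained. This is how a deletion can remove binding
  sites in a regulatory region or an insertion create one.
* **Splice-window assessment** — intronic variants are checked against
  donor (-3..+6) and acceptor (-14..+1) windows at every intron boundary
  of their host gene, strand-aware; a variant inside a window is scored
  as the alt-minus-ref change of a consensus splice-site PWM. This is a
  deliberately simple consensus surrogate, not a reimplementation of
  dedicated splice predictors; deep intronic variants always come back
  ``no_predicted_effect``.

Scores are summed log2 odds against a background distribution
(uniform by default), normalized to a relative score in [0, 1] by the
per-matrix attainable extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, ReferenceMismatchError, UsageError
from .io_formats import GeneModel, Variant

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"
DEFAULT_SCAN_THRESHOLD = 0.80
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_SPLICE_DELTA_THRESHOLD = 2.0


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp.get(b, "N") for b in reversed(seq))


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Positional base-probability matrix with background and pseudocount.

    ``probs`` has shape (W, 4) in A, C, G, T order; every row sums to 1.
    Log-odds are taken base 2 against ``background``.
    """

    motif_id: str
    tf_name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise FormatError(f"PWM {self.motif_id}: matrix must be (W, 4) with W >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise FormatError(f"PWM {self.motif_id}: rows must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        tf_name: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "PWM":
        """Counts -> probabilities: (c + eps) / (column_total + 4 eps)."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise FormatError(f"PWM {motif_id}: counts must be (W, 4)")
        totals = counts.sum(axis=1)
        if np.any(totals + 4 * pseudocount <= 0):
            raise FormatError(f"PWM {motif_id}: zero-sum column with zero pseudocount")
        probs = (counts + pseudocount) / (totals + 4 * pseudocount)[:, None]
        bg = background if background is not None else np.full(4, 0.25)
        return cls(motif_id=motif_id, tf_name=tf_name, probs=probs,
                   background=bg, pseudocount=pseudocount)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(W, 5) matrix: columns A,C,G,T plus the N/ambiguous column.

        An N base contributes its expected log-odds under the background,
        sum_b q(b) log2(p(b,i)/q(b)), which lies between the per-position
        min and max so relative scores stay within [0, 1].
        """
        lo = np.log2(self.probs / self.background[None, :])
        n_col = (self.background[None, :] * lo).sum(axis=1, keepdims=True)
        return np.concatenate([lo, n_col], axis=1)

    @property
    def min_score(self) -> float:
        return float(self.log_odds[:, :4].min(axis=1).sum())

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def relative(self, raw: float) -> float:
        return (raw - self.min_score) / (self.max_score - self.min_score)


def read_motifs(path: str | Path, dialect: str = "jaspar") -> list[PWM]:
    """Load JASPAR or TRANSFAC count matrices as PWMs.

    Counts are converted to probabilities with the default pseudocount;
    matrices are returned in file order.
    """
    from Bio import motifs as bio_motifs

    if dialect not in {"jaspar", "transfac"}:
        raise UsageError(f"unknown motif dialect {dialect!r} (use 'jaspar' or 'transfac')")
    try:
        with open(path) as fh:
            records = bio_motifs.parse(fh, dialect)
            parsed = list(records)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"{path}: cannot parse {dialect} motifs: {exc}") from exc
    pwms: list[PWM] = []
    for i, m in enumerate(parsed):
        counts = np.array([[m.counts[b][j] for b in BASES] for j in range(m.length)])
        if dialect == "jaspar":
            motif_id = getattr(m, "matrix_id", None) or m.name or f"motif_{i + 1}"
            tf_name = m.name or motif_id
        else:
            motif_id = m.get("AC") or m.get("ID") or m.name or f"motif_{i + 1}"
            tf_name = m.get("ID") or m.name or motif_id
        pwms.append(PWM.from_counts(motif_id, tf_name, counts))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_motifs_jaspar(pwm_counts: Mapping[str, tuple[str, np.ndarray]], path: str | Path) -> None:
    """Write integer count matrices in JASPAR format: {id: (tf_name, counts)}."""
    with open(path, "w") as fh:
        for motif_id, (tf_name, counts) in pwm_counts.items():
            counts = np.asarray(counts)
            fh.write(f">{motif_id} {tf_name}\n")
            for bi, b in enumerate(BASES):
                row = " ".join(str(int(c)) for c in counts[:, bi])
                fh.write(f"{b} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class MotifHit:
    motif_id: str
    chrom: str
    start: int  # 1-based leftmost base of the site on the forward strand
    strand: str
    score: float
    relative: float


def encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> 4."""
    table = np.full(256, 4, dtype=np.int64)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _forward_scores(enc: np.ndarray, lom: np.ndarray) -> np.ndarray:
    # accumulate position by position so each window's score is summed in
    # motif order, bit-identical to a per-offset loop
    w = lom.shape[0]
    if enc.size < w:
        return np.zeros(0)
    n = enc.size - w + 1
    scores = np.zeros(n)
    for i in range(w):
        scores += lom[i, enc[i : i + n]]
    return scores


def scan(
    seq: str,
    pwm: PWM,
    threshold_rel: float = DEFAULT_SCAN_THRESHOLD,
    chrom: str = ".",
    offset: int = 1,
) -> list[MotifHit]:
    """All motif hits on both strands with relative score >= threshold.

    ``offset`` is the 1-based coordinate of ``seq[0]``; hit starts are the
    leftmost base of the site in those coordinates regardless of strand.
    A minus-strand site is scored on the reverse complement of its window,
    position by position in motif order, so strand symmetry is exact.
    """
    w = pwm.width
    if len(seq) < w:
        return []
    lom = pwm.log_odds  # (W, 5)
    enc = encode(seq)
    span = pwm.max_score - pwm.min_score
    hits: list[MotifHit] = []
    fwd = _forward_scores(enc, lom)
    # minus strand: forward-scan the reverse complement, then mirror starts
    enc_rc = np.where(enc == 4, 4, 3 - enc)[::-1]
    rev = _forward_scores(enc_rc, lom)
    n = len(seq) - w + 1
    for i in range(n):
        rel = (fwd[i] - pwm.min_score) / span
        if rel >= threshold_rel:
            hits.append(MotifHit(pwm.motif_id, chrom, offset + i, "+", float(fwd[i]), float(rel)))
    for j in range(n):
        rel = (rev[j] - pwm.min_score) / span
        if rel >= threshold_rel:
            i = n - 1 - j  # leftmost base of the site on the forward strand
            hits.append(MotifHit(pwm.motif_id, chrom, offset + i, "-", float(rev[j]), float(rel)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# TFBS delta
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class TFBSDelta:
    variant_key: tuple[str, int, str, str]
    motif_id: str
    tf_name: str
    status: str  # "gained" | "lost"
    count: int
    ref_hits: tuple[MotifHit, ...]
    alt_hits: tuple[MotifHit, ...]


def _hits_overlapping(
    hits: Sequence[MotifHit], widths: Mapping[str, int], span: tuple[int, int]
) -> list[MotifHit]:
    out = []
    for h in hits:
        w = widths[h.motif_id]
        if h.start <= span[1] and span[0] <= h.start + w - 1:
            out.append(h)
    return out


def tfbs_delta(
    genome: Mapping[str, str],
    v: Variant,
    pwms: Sequence[PWM],
    threshold_rel: float = DEFAULT_SCAN_THRESHOLD,
) -> list[TFBSDelta]:
    """Binding sites gained or lost by substituting the alt allele.

    The scan window is the reference interval
    ``[pos - (Wmax-1), pos + len(ref) - 1 + (Wmax-1)]`` clipped to the
    chromosome, with Wmax the widest motif. A site "belongs" to the edit
    when its interval overlaps the edited span; for each (motif, strand)
    the lost count is max(ref_n - alt_n, 0) over such sites and the
    gained count the converse, so positional shifts introduced by indels
    do not spuriously pair or unpair sites.
    """
    if v.chrom not in genome:
        raise ReferenceMismatchError(f"chromosome {v.chrom!r} not in genome")
    chrom_seq = genome[v.chrom]
    ref_at = chrom_seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
    if ref_at != v.ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: genome has {ref_at!r}, variant ref is {v.ref!r}"
        )
    if v.ref == v.alt:
        return []
    w_max = max(p.width for p in pwms)
    win_start = max(1, v.pos - (w_max - 1))
    win_end = min(len(chrom_seq), v.pos + len(v.ref) - 1 + (w_max - 1))
    ref_window = chrom_seq[win_start - 1 : win_end]
    edit_lo = v.pos - win_start  # 0-based offset of the edit inside the window
    alt_window = (
        ref_window[:edit_lo] + v.alt + ref_window[edit_lo + len(v.ref):]
    )
    ref_span = (v.pos, v.pos + len(v.ref) - 1)
    alt_span = (win_start + edit_lo, win_start + edit_lo + len(v.alt) - 1)
    widths = {p.motif_id: p.width for p in pwms}
    names = {p.motif_id: p.tf_name for p in pwms}

    deltas: list[TFBSDelta] = []
    for pwm in pwms:
        ref_hits = _hits_overlapping(
            scan(ref_window, pwm, threshold_rel, chrom=v.chrom, offset=win_start),
            widths, ref_span,
        )
        alt_hits = _hits_overlapping(
            scan(alt_window, pwm, threshold_rel, chrom=v.chrom, offset=win_start),
            widths, alt_span,
        )
        lost = gained = 0
        for strand in "+-":
            n_ref = sum(1 for h in ref_hits if h.strand == strand)
            n_alt = sum(1 for h in alt_hits if h.strand == strand)
            lost += max(n_ref - n_alt, 0)
            gained += max(n_alt - n_ref, 0)
        for status, count in (("lost", lost), ("gained", gained)):
            if count:
                deltas.append(
                    TFBSDelta(
                        variant_key=v.key,
                        motif_id=pwm.motif_id,
                        tf_name=names[pwm.motif_id],
                        status=status,
                        count=count,
                        ref_hits=tuple(ref_hits),
                        alt_hits=tuple(alt_hits),
                    )
                )
    deltas.sort(key=lambda d: (d.motif_id, d.status))
    return deltas


# ---------------------------------------------------------------------------
# Splice-window assessment
# ---------------------------------------------------------------------------

# Approximate mammalian splice-site base frequencies; the donor covers the
# last 3 exonic and first 6 intronic bases (GT at +1/+2), the acceptor the
# last 14 intronic and first exonic base (AG at -2/-1, upstream pyrimidine
# tract). Values are a consensus surrogate, not fitted to any dataset.
_DONOR_FREQS = [
    # A     C     G     T        position (exon -3 .. intron +6)
    (0.33, 0.37, 0.18, 0.12),  # -3
    (0.60, 0.13, 0.14, 0.13),  # -2
    (0.08, 0.04, 0.81, 0.07),  # -1
    (0.001, 0.001, 0.997, 0.001),  # +1 G
    (0.001, 0.001, 0.001, 0.997),  # +2 T
    (0.58, 0.03, 0.36, 0.03),  # +3
    (0.70, 0.08, 0.12, 0.10),  # +4
    (0.06, 0.04, 0.84, 0.06),  # +5
    (0.16, 0.17, 0.15, 0.52),  # +6
]
_ACCEPTOR_FREQS = (
    [(0.09, 0.31, 0.12, 0.48)] * 10  # -14..-5 polypyrimidine tract
    + [
        (0.24, 0.30, 0.21, 0.25),  # -4
        (0.04, 0.74, 0.01, 0.21),  # -3
        (0.997, 0.001, 0.001, 0.001),  # -2 A
        (0.001, 0.001, 0.997, 0.001),  # -1 G
        (0.27, 0.14, 0.47, 0.12),  # +1 (first exonic base)
    ]
)


def _freqs_to_pwm(motif_id: str, freqs) -> PWM:
    probs = np.asarray(freqs, dtype=float)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWM(motif_id=motif_id, tf_name=motif_id, probs=probs)


def default_donor_pwm() -> PWM:
    return _freqs_to_pwm("splice_donor", _DONOR_FREQS)


def default_acceptor_pwm() -> PWM:
    return _freqs_to_pwm("splice_acceptor", _ACCEPTOR_FREQS)


@dataclass(frozen=True, slots=True)
class SpliceWindows:
    """Window extents in nt around each splice site, exon side / intron side."""

    donor_exonic: int = 3
    donor_intronic: int = 6
    acceptor_intronic: int = 14
    acceptor_exonic: int = 1


@dataclass(frozen=True, slots=True)
class SpliceAssessment:
    variant_key: tuple[str, int, str, str]
    in_donor_window: bool
    in_acceptor_window: bool
    donor_delta: float | None
    acceptor_delta: float | None
    verdict: str  # "no_predicted_effect" | "possible_effect"


def _splice_site_windows(gene: GeneModel, windows: SpliceWindows):
    """Yield (kind, genomic_start, genomic_end, anchor, anchor_side).

    ``anchor`` is the exon-boundary coordinate the window is pinned to;
    ``anchor_side`` is "left" when the window's left edge is fixed in
    genomic coordinates and "right" when the right edge is.
    """
    for intron_start, intron_end in gene.introns:
        if gene.strand == "+":
            d_s = intron_start - windows.donor_exonic
            d_e = intron_start + windows.donor_intronic - 1
            yield ("donor", d_s, d_e, d_s, "left")
            a_s = intron_end - windows.acceptor_intronic + 1
            a_e = intron_end + windows.acceptor_exonic
            yield ("acceptor", a_s, a_e, a_e, "right")
        else:
            d_s = intron_end - windows.donor_intronic + 1
            d_e = intron_end + windows.donor_exonic
            yield ("donor", d_s, d_e, d_e, "right")
            a_s = intron_start - windows.acceptor_exonic
            a_e = intron_start + windows.acceptor_intronic - 1
            yield ("acceptor", a_s, a_e, a_s, "left")


def _window_raw_score(seq: str, pwm: PWM) -> float:
    lom = pwm.log_odds
    enc = encode(seq)
    return float(lom[np.arange(len(enc)), enc].sum())


def _extract_window(
    chrom_seq: str, start: int, end: int, strand: str
) -> str:
    s = chrom_seq[max(0, start - 1) : end]
    return reverse_complement(s) if strand == "-" else s


def splice_assess(
    genome: Mapping[str, str],
    v: Variant,
    gene: GeneModel,
    donor_pwm: PWM | None = None,
    acceptor_pwm: PWM | None = None,
    windows: SpliceWindows = SpliceWindows(),
    delta_threshold: float = DEFAULT_SPLICE_DELTA_THRESHOLD,
) -> SpliceAssessment:
    """Score an intronic variant against its gene's splice-site windows.

    The window sequence is re-extracted from the edited chromosome,
    anchored at the exon-boundary side so that indels shift the intron
    side rather than the conserved boundary. The verdict is
    ``possible_effect`` iff the variant lies inside a window and the
    absolute PWM score change exceeds ``delta_threshold`` (bits).
    """
    donor_pwm = donor_pwm or default_donor_pwm()
    acceptor_pwm = acceptor_pwm or default_acceptor_pwm()
    chrom_seq = genome[v.chrom]
    ref_at = chrom_seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
    if ref_at != v.ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: genome has {ref_at!r}, variant ref is {v.ref!r}"
        )
    if not gene.introns:
        return SpliceAssessment(v.key, False, False, None, None, "no_predicted_effect")

    shift = len(v.alt) - len(v.ref)
    edited = chrom_seq[: v.pos - 1] + v.alt + chrom_seq[v.pos - 1 + len(v.ref):]

    def map_coord(x: int) -> int:
        if x <= v.pos:
            return x
        if x > v.pos + len(v.ref) - 1:
            return x + shift
        return v.pos  # inside the edited span: clamp to the anchor

    span = v.span
    in_donor = in_acceptor = False
    donor_delta: float | None = None
    acceptor_delta: float | None = None
    for kind, w_s, w_e, anchor, side in _splice_site_windows(gene, windows):
        if not (span[0] <= w_e and w_s <= span[1]):
            continue
        pwm = donor_pwm if kind == "donor" else acceptor_pwm
        length = w_e - w_s + 1
        ref_seq = _extract_window(chrom_seq, w_s, w_e, gene.strand)
        if side == "left":
            a = map_coord(w_s)
            alt_seq = edited[a - 1 : a - 1 + length]
        else:
            a = map_coord(w_e)
            alt_seq = edited[max(0, a - length) : a]
        if gene.strand == "-":
            alt_seq = reverse_complement(alt_seq)
        if len(ref_seq) != pwm.width or len(alt_seq) != pwm.width:
            continue  # window clipped at a chromosome edge
        delta = _window_raw_score(alt_seq, pwm) - _window_raw_score(ref_seq, pwm)
        if kind == "donor":
            in_donor = True
            donor_delta = delta if donor_delta is None else max(donor_delta, delta, key=abs)
        else:
            in_acceptor = True
            acceptor_delta = delta if acceptor_delta is None else max(acceptor_delta, delta, key=abs)
    candidates = [d for d in (donor_delta, acceptor_delta) if d is not None]
    effect = any(abs(d) > delta_threshold for d in candidates)
    verdict = "possible_effect" if ((in_donor or in_acceptor) and effect) else "no_predicted_effect"
    return SpliceAssessment(v.key, in_donor, in_acceptor, donor_delta, acceptor_delta, verdict)


# ---------------------------------------------------------------------------
# Per-candidate routing
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class VariantEffect:
    variant_key: tuple[str, int, str, str]
    line: str
    gene_id: str | None
    region_class: str
    sub_context: str
    tfbs: tuple[TFBSDelta, ...] = ()
    splice: SpliceAssessment | None = None
    flag: str = ""


def predict_all(
    candidates,
    genome: Mapping[str, str],
    genes: Mapping[str, GeneModel],
    pwms: Sequence[PWM],
    threshold_rel: float = DEFAULT_SCAN_THRESHOLD,
    donor_pwm: PWM | None = None,
    acceptor_pwm: PWM | None = None,
    splice_windows: SpliceWindows = SpliceWindows(),
    splice_delta_threshold: float = DEFAULT_SPLICE_DELTA_THRESHOLD,
) -> list[VariantEffect]:
    """Route each candidate variant to the appropriate predictor.

    RR and intergenic variants get a TFBS gain/loss scan; intronic
    variants a splice-window assessment; UTR variants a location flag
    (a 5' UTR variant can alter transcript regulation without touching a
    TFBS); coding variants are flagged out of scope for regulatory
    prediction.
    """
    effects: list[VariantEffect] = []
    for cand in candidates:
        for ann in cand.annotations:
            v = ann.variant
            rc = ann.region_class.value
            tfbs: tuple[TFBSDelta, ...] = ()
            splice: SpliceAssessment | None = None
            flag = ""
            if rc in ("RR", "intergenic"):
                tfbs = tuple(tfbs_delta(genome, v, pwms, threshold_rel))
            elif ann.sub_context == "intronic" and ann.gene_id in genes:
                splice = splice_assess(
                    genome, v, genes[ann.gene_id], donor_pwm, acceptor_pwm,
                    splice_windows, splice_delta_threshold,
                )
            elif ann.sub_context == "UTR5":
                flag = "located in 5' UTR - possible regulatory effect"
            elif ann.sub_context == "UTR3":
                flag = "located in 3' UTR - possible regulatory effect"
            elif rc == "CDS":
                flag = "coding - out of scope for regulatory prediction"
            effects.append(
                VariantEffect(
                    variant_key=v.key,
                    line=v.line,
                    gene_id=ann.gene_id,
                    region_class=rc,
                    sub_context=ann.sub_context,
                    tfbs=tfbs,
                    splice=splice,
                    flag=flag,
                )
            )
    effects.sort(key=lambda e: (e.variant_key, e.line))
    return effects


def effects_to_records(effects: Sequence[VariantEffect]) -> list[dict]:
    """JSON-ready rendering of an effect report."""
    out = []
    for e in effects:
        rec: dict = {
            "chrom": e.variant_key[0],
            "pos": e.variant_key[1],
            "ref": e.variant_key[2],
            "alt": e.variant_key[3],
            "line": e.line,
            "gene_id": e.gene_id,
            "region_class": e.region_class,
            "sub_context": e.sub_context,
            "flag": e.flag,
            "tfbs": [
                {
                    "motif_id": d.motif_id,
                    "tf_name": d.tf_name,
                    "status": d.status,
                    "count": d.count,
                }
                for d in e.tfbs
            ],
        }
        if e.splice is not None:
            rec["splice"] = {
                "in_donor_window": e.splice.in_donor_window,
                "in_acceptor_window": e.splice.in_acceptor_window,
                "donor_delta": None if e.splice.donor_delta is None
                else float(f"{e.splice.donor_delta:.6g}"),
                "acceptor_delta": None if e.splice.acceptor_delta is None
                else float(f"{e.splice.acceptor_delta:.6g}"),
                "verdict": e.splice.verdict,
            }
        out.append(rec)
    return out
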