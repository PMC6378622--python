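"""Line-exclusive variant filtering.

Implements the four-part filter used to derive substrain-specific variant
lists from a pair of per-line call sets: keep variants with quality
strictly above 100, alternate-allele depth strictly above 10, more than
10 nt away from any same-line neighbor, and absent (by full allele key)
from the other line's call set. The thresholds are strict inequalities
throughout.

Default stage order: exclusivity is keyed against the other line's
*unfiltered* normalized set — "not present in the other line" is read
conservatively as "not called there at all, even weakly" — followed by the
quality/depth filter, then spacing. Both order (``exclusivity_against``)
and the close-pair convention (``spacing_mode``) are switchable, because
neither is pinned down by the published description.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .errors import IntegrityError, UsageError
from .io_formats import Variant, VariantSet, check_line_labels

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True, slots=True)
class FilterThresholds:
    """Strict (exclusive) cutoffs: keep qual > 100, depth > 10, gap > 10 nt."""

    min_qual_exclusive: float = 100.0
    min_alt_depth_exclusive: int = 10
    min_gap_nt: int = 10

    def __post_init__(self) -> None:
        if min(self.min_qual_exclusive, self.min_alt_depth_exclusive, self.min_gap_nt) < 0:
            raise UsageError("filter thresholds must be non-negative")


@dataclass(slots=True)
class StageCount:
    name: str
    line: str
    n_in: int
    n_out: int
    dropped_keys: tuple[VariantKey, ...]


@dataclass(slots=True)
class FilterReport:
    """Telescoped per-stage counts plus final per-line SNP/INDEL summaries."""

    stages: list[StageCount] = field(default_factory=list)
    snp_counts: dict[str, int] = field(default_factory=dict)
    indel_counts: dict[str, int] = field(default_factory=dict)

    def add_stage(self, name: str, line: str, before: VariantSet, after: VariantSet) -> None:
        dropped = tuple(sorted(before.keys() - after.keys()))
        if len(after) + len(dropped) != len(before):
            raise IntegrityError(f"stage {name}/{line}: dropped + kept != input")
        self.stages.append(StageCount(name, line, len(before), len(after), dropped))

    def validate_telescope(self) -> None:
        """Output of stage k must equal input of stage k+1, per line."""
        by_line: dict[str, list[StageCount]] = {}
        for s in self.stages:
            by_line.setdefault(s.line, []).append(s)
        for line, stages in by_line.items():
            for a, b in zip(stages, stages[1:]):
                if a.n_out != b.n_in:
                    raise IntegrityError(
                        f"line {line}: stage {a.name} out={a.n_out} != {b.name} in={b.n_in}"
                    )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "line": s.line,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_dropped": len(s.dropped_keys),
                    "dropped_keys": [list(k) for k in s.dropped_keys],
                }
                for s in self.stages
            ],
            "snp_counts": dict(sorted(self.snp_counts.items())),
            "indel_counts": dict(sorted(self.indel_counts.items())),
        }


def filter_quality_depth(vs: VariantSet, t: FilterThresholds) -> VariantSet:
    """Keep variants with qual > min_qual AND alt_depth > min_depth (strict)."""
    kept = [
        v
        for v in vs
        if v.qual > t.min_qual_exclusive and v.alt_depth > t.min_alt_depth_exclusive
    ]
    return VariantSet(line=vs.line, variants=tuple(kept))


def filter_spacing(
    vs: VariantSet,
    t: FilterThresholds,
    mode: Literal["drop-all", "keep-first"] = "drop-all",
) -> VariantSet:
    """Remove variants closer than the spacing cutoff to a same-line neighbor.

    Distance is |pos_i - pos_j| between anchor positions on the same
    chromosome. In ``drop-all`` mode (default) *both* members of any pair
    at distance <= min_gap_nt are removed — equivalently, any variant with
    some neighbor at <= min_gap_nt; because the input is position-sorted
    this adjacent-pair sweep equals the all-pairs definition. In
    ``keep-first`` mode a left-to-right greedy sweep keeps a variant only
    when it is > min_gap_nt from the last kept one.
    """
    keys = [v.key for v in vs.variants]
    if keys != sorted(keys):
        raise IntegrityError("filter_spacing requires a sorted VariantSet")
    gap = t.min_gap_nt
    vars_ = vs.variants
    if mode == "drop-all":
        drop = [False] * len(vars_)
        for i in range(len(vars_) - 1):
            a, b = vars_[i], vars_[i + 1]
            if a.chrom == b.chrom and abs(b.pos - a.pos) <= gap:
                drop[i] = drop[i + 1] = True
        kept = [v for v, d in zip(vars_, drop) if not d]
    elif mode == "keep-first":
        kept = []
        last: Variant | None = None
        for v in vars_:
            if last is None or v.chrom != last.chrom or v.pos - last.pos > gap:
                kept.append(v)
                last = v
    else:
        raise UsageError(f"unknown spacing mode {mode!r}")
    return VariantSet(line=vs.line, variants=tuple(kept))


def call_exclusive(vs_a: VariantSet, vs_b: VariantSet) -> tuple[VariantSet, VariantSet]:
    """Per-line variants absent by (chrom, pos, ref, alt) key from the other line."""
    check_line_labels(vs_a, vs_b)
    keys_a, keys_b = vs_a.keys(), vs_b.keys()
    excl_a = VariantSet(vs_a.line, tuple(v for v in vs_a if v.key not in keys_b))
    excl_b = VariantSet(vs_b.line, tuple(v for v in vs_b if v.key not in keys_a))
    return excl_a, excl_b


def summarize(excl_a: VariantSet, excl_b: VariantSet, report: FilterReport | None = None) -> FilterReport:
    """Per-line SNP and INDEL counts of the final exclusive sets.

    SNPs are 1:1 single-base substitutions; everything else (insertions,
    deletions, multi-nucleotide substitutions) is counted as INDEL,
    matching a two-class SNP/INDEL summary.
    """
    if report is None:
        report = FilterReport()
    for vs in (excl_a, excl_b):
        report.snp_counts[vs.line] = sum(1 for v in vs if v.is_snp)
        report.indel_counts[vs.line] = sum(1 for v in vs if not v.is_snp)
    return report


def apply_filters(
    vs_a: VariantSet,
    vs_b: VariantSet,
    thresholds: FilterThresholds | None = None,
    exclusivity_against: Literal["raw", "filtered"] = "raw",
    spacing_mode: Literal["drop-all", "keep-first"] = "drop-all",
) -> tuple[VariantSet, VariantSet, FilterReport, dict[str, dict[str, VariantSet]]]:
    """Run the full filter chain and return final sets, report, and stage sets.

    The fourth return value maps stage name -> line label -> VariantSet
    after that stage, for downstream accounting.
    """
    t = thresholds or FilterThresholds()
    check_line_labels(vs_a, vs_b)
    report = FilterReport()
    stage_sets: dict[str, dict[str, VariantSet]] = {}

    if exclusivity_against == "raw":
        ex_a, ex_b = call_exclusive(vs_a, vs_b)
        report.add_stage("exclusivity", vs_a.line, vs_a, ex_a)
        report.add_stage("exclusivity", vs_b.line, vs_b, ex_b)
        stage_sets["exclusivity"] = {vs_a.line: ex_a, vs_b.line: ex_b}
        qd_a, qd_b = filter_quality_depth(ex_a, t), filter_quality_depth(ex_b, t)
        report.add_stage("quality_depth", vs_a.line, ex_a, qd_a)
        report.add_stage("quality_depth", vs_b.line, ex_b, qd_b)
        stage_sets["quality_depth"] = {vs_a.line: qd_a, vs_b.line: qd_b}
        sp_a = filter_spacing(qd_a, t, mode=spacing_mode)
        sp_b = filter_spacing(qd_b, t, mode=spacing_mode)
        report.add_stage("spacing", vs_a.line, qd_a, sp_a)
        report.add_stage("spacing", vs_b.line, qd_b, sp_b)
        stage_sets["spacing"] = {vs_a.line: sp_a, vs_b.line: sp_b}
        final_a, final_b = sp_a, sp_b
    elif exclusivity_against == "filtered":
        qd_a, qd_b = filter_quality_depth(vs_a, t), filter_quality_depth(vs_b, t)
        report.add_stage("quality_depth", vs_a.line, vs_a, qd_a)
        report.add_stage("quality_depth", vs_b.line, vs_b, qd_b)
        stage_sets["quality_depth"] = {vs_a.line: qd_a, vs_b.line: qd_b}
        sp_a = filter_spacing(qd_a, t, mode=spacing_mode)
        sp_b = filter_spacing(qd_b, t, mode=spacing_mode)
        report.add_stage("spacing", vs_a.line, qd_a, sp_a)
        report.add_stage("spacing", vs_b.line, qd_b, sp_b)
        stage_sets["spacing"] = {vs_a.line: sp_a, vs_b.line: sp_b}
        final_a, final_b = call_exclusive(sp_a, sp_b)
        report.add_stage("exclusivity", vs_a.line, sp_a, final_a)
        report.add_stage("exclusivity", vs_b.line, sp_b, final_b)
        stage_sets["exclusivity"] = {vs_a.line: final_a, vs_b.line: final_b}
    else:
        raise UsageError(f"unknown exclusivity_against mode {exclusivity_against!r}")

    summarize(final_a, final_b, report)
    report.validate_telescope()
    return final_a, final_b, report, stage_sets
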