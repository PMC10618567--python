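"""Scar-event scoring from allele-specific copy-number segments.

A tumor genome is represented as per-chromosome runs of segments carrying
integer total and minor-allele copy numbers.  Three event classes are
counted:

* **LOH** — maximal regions with zero minor-allele copies (and at least one
  retained copy), longer than 15 Mb, shorter than the whole chromosome.
* **TAI** — maximal allelically imbalanced regions (total != 2 * minor)
  that reach a telomere, do not cross the centromere, are longer than
  11 Mb and are sub-chromosomal.
* **LST** — breakpoints between adjacent allele-specific copy-number
  regions both longer than 10 Mb, counted per arm after smoothing away
  regions shorter than 3 Mb, with the inter-region gap at most 3 Mb.

The GI/HRD score is the plain sum LOH + TAI + LST.  All length thresholds
are strict, and "whole chromosome" means covering at least a configurable
fraction (default 99%) of the modeled chromosome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome import GenomeBuild, arm_of, crosses_centromere, normalize_chrom, reaches_telomere

__all__ = [
    "Segment",
    "SegmentProfile",
    "ScoreParams",
    "ScarEvent",
    "HRDResult",
    "normalize_profile",
    "score_loh",
    "score_tai",
    "score_lst",
    "score_gi",
    "arm_event_density",
]

MB = 1_000_000


@dataclass(frozen=True)
class Segment:
    """One segment: 0-based half-open interval with (total, minor) copy numbers."""

    start: int
    end: int
    cn_total: int
    cn_minor: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment [{self.start}, {self.end}): start must be < end")
        if self.cn_total < 0 or self.cn_minor < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.cn_minor > self.cn_total - self.cn_minor:
            raise ValueError(
                f"cn_minor={self.cn_minor} exceeds the major allele count for cn_total={self.cn_total}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.cn_total, self.cn_minor)

    @property
    def is_loh(self) -> bool:
        """Zero minor-allele copies with at least one retained copy."""
        return self.cn_minor == 0 and self.cn_total >= 1

    @property
    def is_imbalanced(self) -> bool:
        """The two alleles have unequal copy numbers."""
        return self.cn_total != 2 * self.cn_minor


@dataclass
class SegmentProfile:
    """Per-sample segments grouped by chromosome, sorted and non-overlapping."""

    sample: str
    segments: dict[str, list[Segment]] = field(default_factory=dict)

    def chromosomes(self) -> list[str]:
        return list(self.segments)

    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())

    def state_at(self, chrom: str, pos: int) -> tuple[int, int] | None:
        """Allele-specific state covering a position, or None if uncovered."""
        for seg in self.segments.get(normalize_chrom(chrom), ()):
            if seg.start <= pos < seg.end:
                return seg.state
        return None


@dataclass(frozen=True)
class ScoreParams:
    """Scoring thresholds.  Lengths are megabases; tolerances base pairs."""

    loh_min_mb: float = 15.0
    tai_min_mb: float = 11.0
    lst_min_region_mb: float = 10.0
    lst_smooth_mb: float = 3.0
    lst_max_gap_mb: float = 3.0
    telomere_tol_bp: int = 1_000
    whole_chrom_fraction: float = 0.99
    bridge_gap_bp: int = 0
    include_sex_chromosomes: bool = False


@dataclass(frozen=True)
class ScarEvent:
    kind: str  # "LOH" | "TAI" | "LST"
    chrom: str
    arm: str
    start: int
    end: int


@dataclass(frozen=True)
class HRDResult:
    sample: str
    loh: int
    tai: int
    lst: int
    events: tuple[ScarEvent, ...] = ()

    @property
    def gi_score(self) -> int:
        return self.loh + self.tai + self.lst


def normalize_profile(profile: SegmentProfile, bridge_gap_bp: int = 0) -> SegmentProfile:
    """Sort segments, reject overlaps, and merge same-state neighbours.

    Adjacent segments with identical (total, minor) state whose gap is at
    most ``bridge_gap_bp`` are merged into one segment spanning the gap.
    """
    out: dict[str, list[Segment]] = {}
    for chrom, segs in profile.segments.items():
        ordered = sorted(segs, key=lambda s: s.start)
        merged: list[Segment] = []
        for seg in ordered:
            if not merged:
                merged.append(seg)
                continue
            prev = merged[-1]
            if seg.start < prev.end:
                raise ValueError(
                    f"sample {profile.sample}: overlapping segments on chromosome {chrom} "
                    f"at [{prev.start}, {prev.end}) and [{seg.start}, {seg.end})"
                )
            if seg.state == prev.state and seg.start - prev.end <= bridge_gap_bp:
                merged[-1] = replace(prev, end=seg.end)
            else:
                merged.append(seg)
        out[chrom] = merged
    return SegmentProfile(sample=profile.sample, segments=out)


def _maximal_runs(segs: list[Segment], predicate) -> list[tuple[int, int]]:
    """Maximal (start, end) extents of strictly adjacent segments satisfying a predicate."""
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    prev_end: int | None = None
    for seg in segs:
        if predicate(seg):
            if cur is not None and seg.start == prev_end:
                cur = (cur[0], seg.end)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (seg.start, seg.end)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
        prev_end = seg.end
    if cur is not None:
        runs.append(cur)
    return runs


def _is_whole_chromosome(length: int, chrom_length: int, fraction: float) -> bool:
    return length >= fraction * chrom_length


def score_loh(
    profile: SegmentProfile, genome: GenomeBuild, params: ScoreParams = ScoreParams()
) -> tuple[int, list[ScarEvent]]:
    """Count LOH scar events: minor-copy-zero regions > ``loh_min_mb``,
    sub-chromosomal, with at least one retained copy."""
    events: list[ScarEvent] = []
    for chrom in genome.scoring_chromosomes(params.include_sex_chromosomes):
        segs = profile.segments.get(chrom)
        if not segs:
            continue
        cm = genome.chromosome(chrom)
        for start, end in _maximal_runs(segs, lambda s: s.is_loh):
            length = end - start
            if length <= params.loh_min_mb * MB:
                continue
            if _is_whole_chromosome(length, cm.length, params.whole_chrom_fraction):
                continue
            events.append(ScarEvent("LOH", chrom, _midpoint_arm(genome, chrom, start, end), start, end))
    return len(events), events


def score_tai(
    profile: SegmentProfile, genome: GenomeBuild, params: ScoreParams = ScoreParams()
) -> tuple[int, list[ScarEvent]]:
    """Count TAI scar events: telomere-anchored allelic-imbalance regions
    > ``tai_min_mb`` that do not cross the centromere and are sub-chromosomal."""
    events: list[ScarEvent] = []
    for chrom in genome.scoring_chromosomes(params.include_sex_chromosomes):
        segs = profile.segments.get(chrom)
        if not segs:
            continue
        cm = genome.chromosome(chrom)
        for start, end in _maximal_runs(segs, lambda s: s.is_imbalanced):
            length = end - start
            if length <= params.tai_min_mb * MB:
                continue
            if not reaches_telomere(genome, chrom, start, end, params.telomere_tol_bp):
                continue
            if crosses_centromere(genome, chrom, start, end):
                continue
            if _is_whole_chromosome(length, cm.length, params.whole_chrom_fraction):
                continue
            events.append(ScarEvent("TAI", chrom, _midpoint_arm(genome, chrom, start, end), start, end))
    return len(events), events


def _clip_to_arm(segs: list[Segment], lo: int, hi: int) -> list[tuple[int, int, tuple[int, int]]]:
    out = []
    for seg in segs:
        s, e = max(seg.start, lo), min(seg.end, hi)
        if s < e:
            out.append((s, e, seg.state))
    return out


def _smooth_regions(
    regions: list[tuple[int, int, tuple[int, int]]], min_keep_bp: float
) -> list[tuple[int, int, tuple[int, int]]]:
    """Drop regions shorter than ``min_keep_bp``, then re-merge consecutive
    regions with identical state (the merged extent spans the removed gap)."""
    kept = [r for r in regions if r[1] - r[0] >= min_keep_bp]
    merged: list[tuple[int, int, tuple[int, int]]] = []
    for r in kept:
        if merged and merged[-1][2] == r[2]:
            merged[-1] = (merged[-1][0], r[1], r[2])
        else:
            merged.append(r)
    return merged


def score_lst(
    profile: SegmentProfile, genome: GenomeBuild, params: ScoreParams = ScoreParams()
) -> tuple[int, list[ScarEvent]]:
    """Count large-scale state transitions per chromosome arm.

    The centromere is a hard boundary and never contributes a breakpoint.
    Regions shorter than ``lst_smooth_mb`` are smoothed away before
    counting; a transition qualifies when both flanking regions exceed
    ``lst_min_region_mb`` and their genomic gap is at most ``lst_max_gap_mb``.
    """
    events: list[ScarEvent] = []
    for chrom in genome.scoring_chromosomes(params.include_sex_chromosomes):
        segs = profile.segments.get(chrom)
        if not segs:
            continue
        cm = genome.chromosome(chrom)
        for arm_label, (lo, hi) in (("p", cm.p_arm), ("q", cm.q_arm)):
            regions = _smooth_regions(_clip_to_arm(segs, lo, hi), params.lst_smooth_mb * MB)
            for left, right in zip(regions, regions[1:]):
                if left[2] == right[2]:
                    continue
                if (left[1] - left[0]) <= params.lst_min_region_mb * MB:
                    continue
                if (right[1] - right[0]) <= params.lst_min_region_mb * MB:
                    continue
                if right[0] - left[1] > params.lst_max_gap_mb * MB:
                    continue
                events.append(ScarEvent("LST", chrom, arm_label, left[1], right[0]))
    return len(events), events


def score_gi(
    profile: SegmentProfile, genome: GenomeBuild, params: ScoreParams = ScoreParams()
) -> HRDResult:
    """Normalize a profile and compute the GI/HRD score = LOH + TAI + LST."""
    norm = normalize_profile(profile, params.bridge_gap_bp)
    n_loh, ev_loh = score_loh(norm, genome, params)
    n_tai, ev_tai = score_tai(norm, genome, params)
    n_lst, ev_lst = score_lst(norm, genome, params)
    return HRDResult(
        sample=profile.sample,
        loh=n_loh,
        tai=n_tai,
        lst=n_lst,
        events=tuple(ev_loh + ev_tai + ev_lst),
    )


def _midpoint_arm(genome: GenomeBuild, chrom: str, start: int, end: int) -> str:
    """Arm holding the event midpoint; centromeric midpoints fall to the nearer arm."""
    cm = genome.chromosome(chrom)
    mid = (start + end) // 2
    label = arm_of(genome, chrom, min(mid, cm.length - 1))
    if label != "cen":
        return label
    cen_mid = (cm.cen_start + cm.cen_end) / 2
    return "p" if mid < cen_mid else "q"


def arm_event_density(results: list[HRDResult], genome: GenomeBuild):
    """Cohort-wide per-arm event counts, as a DataFrame indexed by arm
    (``1p``, ``1q``, ...) with columns loh/tai/lst/total."""
    import pandas as pd

    arms = []
    for chrom in genome.autosome_names() + tuple(c for c in ("X", "Y") if c in genome.chromosomes):
        arms += [f"{chrom}p", f"{chrom}q"]
    table = pd.DataFrame(0, index=arms, columns=["loh", "tai", "lst", "total"])
    for res in results:
        for ev in res.events:
            key = f"{ev.chrom}{ev.arm}"
            if key in table.index:
                table.loc[key, ev.kind.lower()] += 1
    table["total"] = table[["loh", "tai", "lst"]].sum(axis=1)
    return table
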