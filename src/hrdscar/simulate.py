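"""Synthetic cohort generator with ground truth, plus the independent
bin-rasterizing scoring oracle.

The generator emulates what the analysis consumes: per-sample integer
allele-specific segment profiles over the packaged hg19 autosomes with
planted scar lesions, variant tables carrying TP53 configurations and a
TMB-calibrated somatic background, and clinical tables whose survival
times follow an exponential proportional-hazards model with hazard ratios
taken from the risk-model defaults (OS high-vs-low 8.56, PFS high 4.76,
medium 2.29).

Ground-truth scores always come from :func:`oracle_score`, never from the
planted lesion counts: lesion classes interact (an interstitial LOH region
also creates two large-scale transitions), and the oracle resolves that
cross-talk the same way the definitions do.

All generated breakpoints sit on a 100-kb grid, matching the resolution of
the packaged coordinate model and of the oracle's rasterization, so engine
and oracle length arithmetic agree exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBuild
from .risk import assign_gi_prs, compute_cutoff
from .scoring import MB, ScoreParams, Segment, SegmentProfile, normalize_profile

__all__ = [
    "LesionPlan",
    "SimConfig",
    "SyntheticCohort",
    "oracle_score",
    "simulate_profile",
    "simulate_variants",
    "simulate_clinical_survival",
    "simulate_cohort",
    "write_cohort",
]

GRID = 100_000  # bp; generator breakpoint resolution == oracle bin size

# Somatic background drawn over panel-style genes; TP53 is handled separately.
BACKGROUND_GENES = (
    "LRP1B", "SPTA1", "CDKN2A", "RB1", "KEAP1", "STK11", "NF1", "EGFR", "KRAS",
    "BRAF", "PIK3CA", "PTEN", "BRCA1", "BRCA2", "ATM", "ATR", "FANCA", "MET",
    "ERBB2", "SMARCA4", "ARID1A", "NOTCH1", "FAT1", "KMT2D", "ZFHX3", "CREBBP",
)


# ---------------------------------------------------------------------------
# Independent scoring oracle
# ---------------------------------------------------------------------------

def _bin_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i0, i1) runs of True bins."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _state_regions(total: np.ndarray, minor: np.ndarray, lo: int, hi: int) -> list[tuple[int, int, tuple[int, int]]]:
    """Runs of identical covered (total, minor) state over bins [lo, hi)."""
    regions: list[tuple[int, int, tuple[int, int]]] = []
    i = lo
    while i < hi:
        if total[i] < 0:
            i += 1
            continue
        j = i + 1
        while j < hi and total[j] == total[i] and minor[j] == minor[i]:
            j += 1
        regions.append((i, j, (int(total[i]), int(minor[i]))))
        i = j
    return regions


def oracle_score(
    profile: SegmentProfile,
    genome: GenomeBuild,
    params: ScoreParams = ScoreParams(),
    bin_bp: int = GRID,
) -> tuple[int, int, int]:
    """Brute-force (LOH, TAI, LST) by rasterizing each chromosome into
    fixed-size bins of allele-specific state and applying the printed
    definitions literally to maximal runs.  Intended for testing only.
    """
    n_loh = n_tai = n_lst = 0
    for chrom in genome.scoring_chromosomes(params.include_sex_chromosomes):
        cm = genome.chromosome(chrom)
        n_bins = math.ceil(cm.length / bin_bp)
        total = np.full(n_bins, -1, dtype=int)
        minor = np.full(n_bins, -1, dtype=int)
        for seg in profile.segments.get(chrom, ()):  # left-edge sampling
            i0 = math.ceil(seg.start / bin_bp)
            i1 = math.ceil(seg.end / bin_bp)
            total[i0:i1] = seg.cn_total
            minor[i0:i1] = seg.cn_minor
        covered = total >= 0

        # LOH: minor-copy zero with a retained copy, >15 Mb, sub-chromosomal
        for i0, i1 in _bin_runs(covered & (minor == 0) & (total >= 1)):
            length = (i1 - i0) * bin_bp
            if length > params.loh_min_mb * MB and length < params.whole_chrom_fraction * cm.length:
                n_loh += 1

        # TAI: imbalance reaching a telomere, not crossing the centromere, >11 Mb
        for i0, i1 in _bin_runs(covered & (total != 2 * minor)):
            length = (i1 - i0) * bin_bp
            reaches = i0 == 0 or i1 == n_bins
            crosses = i0 * bin_bp < cm.cen_start and (i1 - 1) * bin_bp >= cm.cen_end
            if (
                length > params.tai_min_mb * MB
                and reaches
                and not crosses
                and length < params.whole_chrom_fraction * cm.length
            ):
                n_tai += 1

        # LST: per arm, smooth out <3 Mb regions, count >10 Mb state transitions
        for lo_bp, hi_bp in (cm.p_arm, cm.q_arm):
            lo, hi = math.ceil(lo_bp / bin_bp), math.ceil(hi_bp / bin_bp)
            regions = [
                r for r in _state_regions(total, minor, lo, hi)
                if (r[1] - r[0]) * bin_bp >= params.lst_smooth_mb * MB
            ]
            merged: list[tuple[int, int, tuple[int, int]]] = []
            for r in regions:
                if merged and merged[-1][2] == r[2]:
                    merged[-1] = (merged[-1][0], r[1], r[2])
                else:
                    merged.append(r)
            for a, b in zip(merged, merged[1:]):
                if a[2] == b[2]:
                    continue
                if (a[1] - a[0]) * bin_bp <= params.lst_min_region_mb * MB:
                    continue
                if (b[1] - b[0]) * bin_bp <= params.lst_min_region_mb * MB:
                    continue
                if (b[0] - a[1]) * bin_bp > params.lst_max_gap_mb * MB:
                    continue
                n_lst += 1
    return n_loh, n_tai, n_lst


# ---------------------------------------------------------------------------
# Profile generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionPlan:
    """Planted lesion counts for one synthetic profile.

    ``tp53_loh`` forces a minor-copy-zero lesion over the TP53 locus;
    otherwise the locus is kept heterozygous so that the TP53 status the
    variant generator requests is the status the caller gets back.
    """

    n_interstitial_loh: int = 0
    n_telomeric_ai: int = 0
    n_staircase: int = 0
    whole_chrom_loh: bool = False
    tp53_loh: bool = False


_INTERSTITIAL_STATES = ((2, 0), (1, 0))
_TELOMERIC_STATES = ((3, 1), (1, 0), (2, 0))
_STAIRCASE_STATES = ((2, 1), (3, 1), (4, 1), (4, 2))


class PlacementError(RuntimeError):
    """No non-overlapping placement found for a planned lesion."""


def _grid_uniform(rng: np.random.Generator, lo_bp: float, hi_bp: float) -> int:
    """A random multiple of the generator grid in [lo_bp, hi_bp]."""
    lo, hi = math.ceil(lo_bp / GRID), math.floor(hi_bp / GRID)
    return int(rng.integers(lo, hi + 1)) * GRID


def simulate_profile(
    genome: GenomeBuild,
    plan: LesionPlan,
    rng: np.random.Generator,
    sample: str = "S",
    max_tries: int = 200,
) -> SegmentProfile:
    """A diploid (2,1) autosomal genome with the planned lesions planted at
    non-overlapping, grid-aligned positions.

    Lesion classes: interstitial copy-neutral or deletion LOH (5-40 Mb),
    telomere-anchored gains/losses (5-30 Mb), staircase runs of 2-4 short
    state changes (2-15 Mb each), and optional whole-chromosome LOH.
    """
    tp53 = genome.genes["TP53"]
    lesions: dict[str, list[tuple[int, int, tuple[int, int]]]] = {
        c: [] for c in genome.autosome_names()
    }
    whole_chrom: str | None = None

    def overlaps_existing(chrom: str, start: int, end: int) -> bool:
        if chrom == whole_chrom:
            return True
        return any(start < e and end > s for s, e, _ in lesions[chrom])

    def violates_tp53(chrom: str, start: int, end: int, state: tuple[int, int]) -> bool:
        # keep the locus heterozygous unless the plan asked for TP53 LOH
        if chrom != tp53.chrom or state[1] != 0:
            return False
        return start < tp53.end and end > tp53.start

    def place(chrom: str, start: int, end: int, state: tuple[int, int]) -> None:
        lesions[chrom].append((start, end, state))

    if plan.tp53_loh:
        cm = genome.chromosome(tp53.chrom)
        length = _grid_uniform(rng, 10 * MB, 20 * MB)
        state = _INTERSTITIAL_STATES[int(rng.integers(len(_INTERSTITIAL_STATES)))]
        assert length <= cm.cen_start and length > tp53.end
        place(tp53.chrom, 0, length, state)

    arms = [
        (chrom, lo, hi)
        for chrom in genome.autosome_names()
        for lo, hi in (genome.chromosome(chrom).p_arm, genome.chromosome(chrom).q_arm)
    ]

    def try_place(kind: str) -> None:
        for _ in range(max_tries):
            chrom, lo, hi = arms[int(rng.integers(len(arms)))]
            arm_len = hi - lo
            if kind == "interstitial":
                length = _grid_uniform(rng, 5 * MB, min(40 * MB, arm_len))
                start = lo + _grid_uniform(rng, 0, arm_len - length)
                pieces = [(start, start + length, _INTERSTITIAL_STATES[int(rng.integers(2))])]
            elif kind == "telomeric":
                length = _grid_uniform(rng, 5 * MB, min(30 * MB, arm_len))
                state = _TELOMERIC_STATES[int(rng.integers(len(_TELOMERIC_STATES)))]
                start = lo if lo == 0 else hi - length
                pieces = [(start, start + length, state)]
            else:  # staircase
                k = int(rng.integers(2, 5))
                block_lens = [_grid_uniform(rng, 2 * MB, 15 * MB) for _ in range(k)]
                span = sum(block_lens)
                if span > arm_len:
                    continue
                start = lo + _grid_uniform(rng, 0, arm_len - span)
                states: list[tuple[int, int]] = []
                while len(states) < k:
                    s = _STAIRCASE_STATES[int(rng.integers(len(_STAIRCASE_STATES)))]
                    if states and s == states[-1]:
                        continue
                    states.append(s)
                pieces = []
                pos = start
                for blen, s in zip(block_lens, states):
                    pieces.append((pos, pos + blen, s))
                    pos += blen
            span_start, span_end = pieces[0][0], pieces[-1][1]
            if overlaps_existing(chrom, span_start, span_end):
                continue
            if any(violates_tp53(chrom, s, e, st) for s, e, st in pieces):
                continue
            for s, e, st in pieces:
                place(chrom, s, e, st)
            return
        raise PlacementError(f"could not place a {kind} lesion after {max_tries} tries")

    for _ in range(plan.n_interstitial_loh):
        try_place("interstitial")
    for _ in range(plan.n_telomeric_ai):
        try_place("telomeric")
    for _ in range(plan.n_staircase):
        try_place("staircase")

    if plan.whole_chrom_loh:
        candidates = [
            c for c in genome.autosome_names() if not lesions[c] and c != tp53.chrom
        ]
        if not candidates:
            raise PlacementError("no lesion-free chromosome left for whole-chromosome LOH")
        whole_chrom = candidates[int(rng.integers(len(candidates)))]
        lesions[whole_chrom] = [(0, genome.chromosome(whole_chrom).length, (2, 0))]

    segments: dict[str, list[Segment]] = {}
    for chrom in genome.autosome_names():
        cm = genome.chromosome(chrom)
        segs: list[Segment] = []
        pos = 0
        for s, e, st in sorted(lesions[chrom]):
            if pos < s:
                segs.append(Segment(pos, s, 2, 1))
            segs.append(Segment(s, e, st[0], st[1]))
            pos = e
        if pos < cm.length:
            segs.append(Segment(pos, cm.length, 2, 1))
        segments[chrom] = segs
    return normalize_profile(SegmentProfile(sample=sample, segments=segments))


# ---------------------------------------------------------------------------
# Variant generator
# ---------------------------------------------------------------------------

def simulate_variants(
    sample: str,
    tp53_state: str,
    mechanism: str,
    tmb_count: int,
    minor_cn_at_tp53: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """A MAF-lite variant table for one sample.

    Emits TP53 mutations realizing the requested status (``wild_type``,
    ``monoallelic``, or ``biallelic`` via ``mutation_plus_loh`` /
    ``germline_plus_somatic`` / ``two_somatic``) and enough background
    nonsynonymous somatic SNVs that the total qualifying TMB count equals
    ``tmb_count``.  Every emitted variant passes the default filters.
    Returns the table and the realized qualifying count.
    """
    if tp53_state == "biallelic" and mechanism == "mutation_plus_loh" and minor_cn_at_tp53 != 0:
        raise ValueError(
            f"sample {sample}: biallelic-via-LOH requested but the profile has "
            f"minor copy number {minor_cn_at_tp53} at TP53; the generator must "
            "coordinate profile and variants"
        )
    if tp53_state != "biallelic" and minor_cn_at_tp53 == 0:
        raise ValueError(
            f"sample {sample}: TP53 locus has LOH in the profile but state "
            f"{tp53_state!r} was requested"
        )

    rows: list[dict] = []

    def tp53_mutation(origin: str) -> None:
        af = 0.5 if origin == "germline" else float(np.round(rng.uniform(0.10, 0.60), 3))
        depth = int(rng.integers(300, 1200))
        rows.append(
            {
                "sample": sample,
                "gene": "TP53",
                "chrom": "17",
                "pos": int(rng.integers(7_571_720, 7_590_869)),
                "variant_class": "SNV",
                "nonsynonymous": True,
                "coding": True,
                "origin": origin,
                "af": af,
                "depth": depth,
                "supporting_reads": max(8, int(round(af * depth))),
                "pop_freq": 0.0,
                "hotspot": False,
                "copy_ratio": np.nan,
            }
        )

    n_tp53_somatic = 0
    if tp53_state == "monoallelic":
        tp53_mutation("somatic")
        n_tp53_somatic = 1
    elif tp53_state == "biallelic":
        if mechanism == "mutation_plus_loh":
            origin = "germline" if rng.random() < 0.2 else "somatic"
            tp53_mutation(origin)
            n_tp53_somatic = int(origin == "somatic")
        elif mechanism == "germline_plus_somatic":
            tp53_mutation("germline")
            tp53_mutation("somatic")
            n_tp53_somatic = 1
        elif mechanism == "two_somatic":
            tp53_mutation("somatic")
            tp53_mutation("somatic")
            n_tp53_somatic = 2
        else:
            raise ValueError(f"unknown biallelic mechanism {mechanism!r}")
    elif tp53_state != "wild_type":
        raise ValueError(f"unknown TP53 state {tp53_state!r}")

    n_background = max(0, int(tmb_count) - n_tp53_somatic)
    for _ in range(n_background):
        gene = BACKGROUND_GENES[int(rng.integers(len(BACKGROUND_GENES)))]
        af = float(np.round(rng.uniform(0.05, 0.45), 3))
        depth = int(rng.integers(300, 1200))
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "chrom": "1",
                "pos": int(rng.integers(1_000_000, 100_000_000)),
                "variant_class": "SNV",
                "nonsynonymous": True,
                "coding": True,
                "origin": "somatic",
                "af": af,
                "depth": depth,
                "supporting_reads": max(8, int(round(af * depth))),
                "pop_freq": 0.0,
                "hotspot": False,
                "copy_ratio": np.nan,
            }
        )
    realized = n_background + n_tp53_somatic
    return pd.DataFrame(rows), realized


# ---------------------------------------------------------------------------
# Clinical / survival generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    Per-sample lesion counts are Poisson with the stated means scaled by an
    exponential instability multiplier (long-tailed cohorts are what makes
    a top-20% cutoff meaningful).  Survival uses an exponential
    proportional-hazards model; the default log-hazard coefficients encode
    the risk-model hazard ratios (OS: medium 2.29, high 8.56; PFS: medium
    2.29, high 4.76) with administrative censoring at the follow-up horizon.
    """

    seed: int = 0
    n_samples: int = 200
    mean_interstitial_loh: float = 1.5
    mean_telomeric_ai: float = 1.2
    mean_staircase: float = 1.0
    p_whole_chrom_loh: float = 0.05
    tp53_probs: tuple[float, float, float] = (0.45, 0.25, 0.30)  # wild, mono, biallelic
    biallelic_mechanism_probs: tuple[float, float, float] = (0.6, 0.1, 0.3)  # loh, g+s, s+s
    tmb_mean: float = 8.0
    top_fraction: float = 0.20
    os_beta_medium: float = math.log(2.29)
    os_beta_high: float = math.log(8.56)
    pfs_beta_medium: float = math.log(2.29)
    pfs_beta_high: float = math.log(4.76)
    os_baseline_hazard: float = 0.010  # events per month in the low-risk group
    pfs_baseline_hazard: float = 0.020
    censor_horizon_months: float = 60.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.tp53_probs) - 1.0) > 1e-9:
            raise ValueError("tp53_probs must sum to 1")
        if abs(sum(self.biallelic_mechanism_probs) - 1.0) > 1e-9:
            raise ValueError("biallelic_mechanism_probs must sum to 1")
        if self.os_baseline_hazard <= 0 or self.pfs_baseline_hazard <= 0:
            raise ValueError("baseline hazards must be positive")


@dataclass
class SyntheticCohort:
    config: SimConfig
    profiles: list[SegmentProfile]
    variants: pd.DataFrame
    clinical: pd.DataFrame
    ground_truth: pd.DataFrame
    cutoff: float


def simulate_clinical_survival(
    assignments: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical table with covariates and exponential PH survival times.

    ``assignments`` needs columns ``sample`` and ``gi_prs``.  Stage and TNM
    marginals shift with the risk category so that characteristic-table
    gradients are qualitatively reproducible.
    """
    rows = []
    for _, a in assignments.iterrows():
        prs = int(a["gi_prs"])
        lp_os = {0: 0.0, 1: config.os_beta_medium, 2: config.os_beta_high}[prs]
        lp_pfs = {0: 0.0, 1: config.pfs_beta_medium, 2: config.pfs_beta_high}[prs]
        t_os = rng.exponential(1.0 / (config.os_baseline_hazard * math.exp(lp_os)))
        t_pfs = rng.exponential(1.0 / (config.pfs_baseline_hazard * math.exp(lp_pfs)))
        horizon = config.censor_horizon_months
        t34 = rng.random() < 0.18 + 0.17 * prs
        n_pos = rng.random() < 0.20 + 0.23 * prs
        m1 = rng.random() < 0.19 + 0.21 * prs
        late = rng.random() < 0.26 + 0.27 * prs
        rows.append(
            {
                "sample": a["sample"],
                "age": float(np.round(np.clip(rng.normal(56.0 + 3.4 * prs, 8.0), 25, 92), 1)),
                "sex": "male" if rng.random() < 0.40 + 0.08 * prs else "female",
                "t_stage": int(rng.integers(3, 5)) if t34 else int(rng.integers(1, 3)),
                "n_stage": int(rng.integers(1, 4)) if n_pos else 0,
                "m_stage": int(m1),
                "stage": ("III" if rng.random() < 0.6 else "IV") if late
                else ("I" if rng.random() < 0.6 else "II"),
                "histology": "LUAD",
                "os_months": float(np.round(min(t_os, horizon), 2)),
                "os_event": int(t_os <= horizon),
                "pfs_months": float(np.round(min(t_pfs, horizon), 2)),
                "pfs_event": int(t_pfs <= horizon),
                "lp_os": lp_os,
                "lp_pfs": lp_pfs,
            }
        )
    df = pd.DataFrame(rows)
    if config.censor_horizon_months <= 0:
        df["os_event"] = 0
        df["pfs_event"] = 0
    return df


# ---------------------------------------------------------------------------
# Whole-cohort assembly
# ---------------------------------------------------------------------------

_TP53_STATES = ("wild_type", "monoallelic", "biallelic")
_MECHANISMS = ("mutation_plus_loh", "germline_plus_somatic", "two_somatic")


def simulate_cohort(
    config: SimConfig,
    genome: GenomeBuild,
    params: ScoreParams = ScoreParams(),
) -> SyntheticCohort:
    """Generate a full synthetic cohort: profiles, variants, clinical table
    and a ground-truth table (oracle scores, TP53 status, risk labels).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[SegmentProfile] = []
    variant_frames: list[pd.DataFrame] = []
    gt_rows: list[dict] = []

    for i in range(config.n_samples):
        sample = f"S{i:04d}"
        state = _TP53_STATES[int(rng.choice(3, p=np.asarray(config.tp53_probs)))]
        mechanism = "none"
        if state == "biallelic":
            mechanism = _MECHANISMS[
                int(rng.choice(3, p=np.asarray(config.biallelic_mechanism_probs)))
            ]
        intensity = rng.exponential(1.0)
        plan = LesionPlan(
            n_interstitial_loh=int(rng.poisson(config.mean_interstitial_loh * intensity)),
            n_telomeric_ai=int(rng.poisson(config.mean_telomeric_ai * intensity)),
            n_staircase=int(rng.poisson(config.mean_staircase * intensity)),
            whole_chrom_loh=bool(rng.random() < config.p_whole_chrom_loh),
            tp53_loh=(mechanism == "mutation_plus_loh"),
        )
        profile = simulate_profile(genome, plan, rng, sample=sample)
        loh, tai, lst = oracle_score(profile, genome, params)
        tp53_locus = genome.genes["TP53"]
        minor_cn = profile.state_at(tp53_locus.chrom, (tp53_locus.start + tp53_locus.end) // 2)[1]
        tmb_target = int(rng.poisson(config.tmb_mean))
        vdf, tmb_realized = simulate_variants(
            sample, state, mechanism, tmb_target, minor_cn, rng
        )
        profiles.append(profile)
        if len(vdf):
            variant_frames.append(vdf)
        gt_rows.append(
            {
                "sample": sample,
                "true_loh": loh,
                "true_tai": tai,
                "true_lst": lst,
                "true_gi": loh + tai + lst,
                "tp53_state": state,
                "tp53_mechanism": mechanism,
                "tp53_altered": state != "wild_type",
                "tmb_count": tmb_realized,
            }
        )

    ground_truth = pd.DataFrame(gt_rows)
    rule = compute_cutoff(ground_truth["true_gi"].to_numpy(), config.top_fraction)
    ground_truth["hrd_high"] = ground_truth["true_gi"] >= rule.cutoff
    assignments = [
        assign_gi_prs(r["sample"], r["hrd_high"], r["tp53_altered"])
        for _, r in ground_truth.iterrows()
    ]
    ground_truth["gi_prs"] = [a.gi_prs for a in assignments]
    ground_truth["category"] = [a.category for a in assignments]

    clinical = simulate_clinical_survival(ground_truth[["sample", "gi_prs"]], config, rng)
    ground_truth["lp_os"] = clinical["lp_os"].to_numpy()
    ground_truth["lp_pfs"] = clinical["lp_pfs"].to_numpy()
    clinical = clinical.drop(columns=["lp_os", "lp_pfs"])

    variants = (
        pd.concat(variant_frames, ignore_index=True)
        if variant_frames
        else pd.DataFrame(columns=["sample", "gene", "variant_class", "origin"])
    )
    return SyntheticCohort(
        config=config,
        profiles=profiles,
        variants=variants,
        clinical=clinical,
        ground_truth=ground_truth,
        cutoff=rule.cutoff,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write segments/variants/clinical/ground-truth TSVs plus a manifest
    recording the config and the ground-truth cutoff."""
    from .tables import write_clinical, write_segments, write_variants

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "segments": str(outdir / "segments.tsv"),
        "variants": str(outdir / "variants.tsv"),
        "clinical": str(outdir / "clinical.tsv"),
        "ground_truth": str(outdir / "ground_truth.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_segments(paths["segments"], cohort.profiles)
    write_variants(paths["variants"], cohort.variants)
    write_clinical(paths["clinical"], cohort.clinical)
    cohort.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    manifest = {"config": asdict(cohort.config), "cutoff": cohort.cutoff}
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
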