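"""Variant filtering, panel TMB, gene-level CNV state and TP53 biallelic calling.

Filtering mirrors a targeted-panel pipeline: minimum depth 100, class-specific
supporting-read minima (SNV 8, insertion 2, deletion 5), population-frequency
cutoff 0.1%, and material-specific allele-fraction floors.  TMB divides the
qualifying nonsynonymous somatic mutation count by the panel's 1.003 Mb coding
footprint, excluding hotspot mutations, CNVs, SVs and germline variants.
TP53 is called biallelic when a passing mutation co-occurs with loss of the
wild-type allele (minor copy number 0 at the locus), or when two passing
mutations hit both alleles (germline + somatic, or two somatic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild
from .scoring import SegmentProfile

__all__ = [
    "FilterConfig",
    "TP53Status",
    "TMBValue",
    "filter_variants",
    "compute_tmb",
    "call_cnv_state",
    "gene_alteration_matrix",
    "classify_tp53",
    "minor_cn_at_gene",
]

PANEL_SIZE_MB = 1.003


@dataclass(frozen=True)
class FilterConfig:
    """Threshold filters applied to raw variant calls.

    ``material`` switches the AF floors between tissue and plasma assays.
    """

    min_depth: int = 100
    min_supporting_reads: dict = field(
        default_factory=lambda: {"SNV": 8, "INS": 2, "DEL": 5}
    )
    max_pop_freq: float = 0.001
    min_af: dict = field(default_factory=lambda: {"tissue": 0.02, "plasma": 0.002})
    min_max_af: dict = field(default_factory=lambda: {"tissue": 0.05, "plasma": 0.01})
    material: str = "tissue"
    cnv_deletion_max_ratio: float = 1.5
    cnv_amplification_min_ratio: float = 2.64
    panel_size_mb: float = PANEL_SIZE_MB

    @property
    def af_floor(self) -> float:
        return self.min_af[self.material]

    @property
    def max_af_floor(self) -> float:
        return self.min_max_af[self.material]


@dataclass(frozen=True)
class TP53Status:
    status: str  # wild_type | monoallelic | biallelic
    mechanism: str  # none | mutation_plus_loh | germline_plus_somatic | two_somatic | multi
    evidence: tuple[str, ...] = ()
    warning: str | None = None


@dataclass(frozen=True)
class TMBValue:
    mutation_count: int
    panel_size_mb: float
    tmb: float
    valid: bool

    def __post_init__(self) -> None:
        assert abs(self.tmb - self.mutation_count / self.panel_size_mb) < 1e-12


def filter_variants(
    variants: pd.DataFrame, config: FilterConfig = FilterConfig(), with_reasons: bool = False
):
    """Apply threshold filters; returns passing rows (and, optionally, a
    reason per dropped row).  Idempotent: filtering a filtered table is a
    no-op.  Small-variant thresholds do not apply to CNV/SV rows.
    """
    unknown = set(variants["variant_class"]) - {"SNV", "INS", "DEL", "CNV", "SV"}
    if unknown:
        raise ValueError(f"unknown variant class(es): {sorted(unknown)}")
    reasons: dict = {}
    keep = pd.Series(True, index=variants.index)
    small = variants["variant_class"].isin(("SNV", "INS", "DEL"))
    for idx in variants.index[small]:
        row = variants.loc[idx]
        reason = _small_variant_fail_reason(row, config)
        if reason is not None:
            keep[idx] = False
            reasons[idx] = reason
    passing = variants[keep]
    if with_reasons:
        return passing, reasons
    return passing


def _small_variant_fail_reason(row: pd.Series, config: FilterConfig) -> str | None:
    if pd.notna(row["depth"]) and row["depth"] < config.min_depth:
        return f"depth<{config.min_depth}"
    min_reads = config.min_supporting_reads[row["variant_class"]]
    if pd.notna(row["supporting_reads"]) and row["supporting_reads"] < min_reads:
        return f"supporting_reads<{min_reads}"
    if pd.notna(row["pop_freq"]) and row["pop_freq"] > config.max_pop_freq:
        return f"pop_freq>{config.max_pop_freq}"
    if pd.notna(row["af"]) and row["af"] < config.af_floor:
        return f"af<{config.af_floor}"
    return None


def compute_tmb(variants: pd.DataFrame, config: FilterConfig = FilterConfig()) -> TMBValue:
    """Panel TMB for one sample's (filtered) variants.

    Qualifying mutations are nonsynonymous coding SNVs/indels of somatic
    origin with AF at or above the material floor, excluding hotspot-flagged
    rows.  CNVs, SVs and germline rows never count.  The value is flagged
    invalid when the maximum AF over small variants falls below the material
    threshold (5% tissue / 1% plasma).
    """
    small = variants[variants["variant_class"].isin(("SNV", "INS", "DEL"))]
    qualifying = small[
        (small["origin"] == "somatic")
        & (small["nonsynonymous"] == True)  # noqa: E712 — NaN-aware comparison
        & (small["coding"] == True)  # noqa: E712
        & (small["hotspot"] != True)  # noqa: E712
        & (small["af"] >= config.af_floor)
    ]
    count = int(len(qualifying))
    # maxAF below the floor suggests tumor content too low for a trustworthy TMB
    max_af = small["af"].max()
    valid = bool(pd.notna(max_af) and max_af >= config.max_af_floor)
    return TMBValue(
        mutation_count=count,
        panel_size_mb=config.panel_size_mb,
        tmb=count / config.panel_size_mb,
        valid=valid,
    )


def call_cnv_state(copy_ratio: float, config: FilterConfig = FilterConfig()) -> str:
    """Gene-level CNV state from a coverage copy ratio.

    The detection limits are attainable values: ratio <= 1.5 is a deletion,
    ratio >= 2.64 an amplification, anything between is neutral.
    """
    if copy_ratio < 0:
        raise ValueError(f"copy ratio must be >= 0, got {copy_ratio}")
    if copy_ratio <= config.cnv_deletion_max_ratio:
        return "deletion"
    if copy_ratio >= config.cnv_amplification_min_ratio:
        return "amplification"
    return "neutral"


def gene_alteration_matrix(
    variants: pd.DataFrame,
    samples: list[str] | None = None,
    genes: list[str] | None = None,
    min_rate: float = 0.0,
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Binary sample x gene alteration matrix from passing somatic calls.

    A cell is 1 when the sample carries at least one somatic small variant
    or a non-neutral CNV in the gene.  ``min_rate`` (e.g. 0.05) restricts
    columns to genes altered in at least that fraction of samples.
    """
    som = variants[variants["origin"] == "somatic"]
    is_cnv = som["variant_class"] == "CNV"
    cnv_altered = is_cnv & som["copy_ratio"].map(
        lambda r: pd.notna(r) and call_cnv_state(r, config) != "neutral"
    )
    sv_or_small = som["variant_class"].isin(("SNV", "INS", "DEL", "SV"))
    altered = som[cnv_altered | sv_or_small]
    if samples is None:
        samples = sorted(variants["sample"].unique())
    if genes is None:
        genes = sorted(altered["gene"].unique())
    matrix = pd.DataFrame(0, index=list(samples), columns=list(genes), dtype=int)
    for _, row in altered.iterrows():
        if row["sample"] in matrix.index and row["gene"] in matrix.columns:
            matrix.loc[row["sample"], row["gene"]] = 1
    if min_rate > 0 and len(matrix):
        rates = matrix.mean(axis=0)
        matrix = matrix.loc[:, rates >= min_rate]
    return matrix


def minor_cn_at_gene(
    profile: SegmentProfile, genome: GenomeBuild, gene: str = "TP53"
) -> int | None:
    """Minor copy number of the segment containing the gene midpoint, or
    None when the locus is uncovered."""
    locus = genome.genes[gene]
    mid = (locus.start + locus.end) // 2
    state = profile.state_at(locus.chrom, mid)
    return None if state is None else state[1]


def classify_tp53(
    tp53_variants: pd.DataFrame, minor_cn_at_tp53: int | None
) -> TP53Status:
    """Mono/biallelic TP53 status from passing TP53 mutations plus the
    minor copy number of the segment covering the locus.

    Biallelic combinations: a (germline or somatic) mutation with LOH of the
    remaining allele; a germline plus a somatic mutation; two somatic
    mutations (assumed in trans; no phasing).  Mechanism precedence:
    mutation_plus_loh > germline_plus_somatic > two_somatic.
    """
    small = tp53_variants[tp53_variants["variant_class"].isin(("SNV", "INS", "DEL"))]
    origins = sorted(small["origin"].tolist())
    n_mut = len(origins)
    n_somatic = origins.count("somatic")
    n_germline = origins.count("germline")
    loh = minor_cn_at_tp53 == 0
    warning = None
    if minor_cn_at_tp53 is None and n_mut > 0:
        warning = "TP53 locus not covered by any segment; status from mutations alone"
        loh = False

    evidence = tuple(f"{o} mutation" for o in origins) + ((f"minor_cn=0 at TP53",) if loh else ())

    if n_mut == 0:
        # LOH alone leaves one functional allele
        return TP53Status("wild_type", "none", evidence, warning)
    if n_mut >= 1 and loh:
        return TP53Status("biallelic", "mutation_plus_loh", evidence, warning)
    if n_germline >= 1 and n_somatic >= 1:
        return TP53Status("biallelic", "germline_plus_somatic", evidence, warning)
    if n_somatic >= 2:
        return TP53Status("biallelic", "two_somatic", evidence, warning)
    if n_mut == 1:
        return TP53Status("monoallelic", "none", evidence, warning)
    # >=2 germline-only mutations: not in the recognized biallelic combinations
    return TP53Status(
        "monoallelic",
        "multi",
        evidence,
        warning or "multiple germline mutations; treated as monoallelic-equivalent",
    )
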