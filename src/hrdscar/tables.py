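"""Readers and writers for segment, variant, clinical and result tables.

All on-disk tables are TSV with fixed header names; column order is free
and extra columns are preserved on read but ignored by the pipeline.
Segment coordinates are 1-based inclusive on disk (SEG convention) and
0-based half-open in memory.  Every validation error names the offending
file and line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBuild, normalize_chrom
from .scoring import Segment, SegmentProfile

__all__ = [
    "read_segments",
    "write_segments",
    "read_variants",
    "write_variants",
    "read_clinical",
    "write_clinical",
    "write_results_json",
    "stage_to_numeric",
    "numeric_to_stage",
    "SEGMENT_COLUMNS",
    "VARIANT_COLUMNS",
    "CLINICAL_COLUMNS",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "cn_total", "cn_minor"]

VARIANT_COLUMNS = [
    "sample", "gene", "chrom", "pos", "variant_class", "nonsynonymous", "coding",
    "origin", "af", "depth", "supporting_reads", "pop_freq", "hotspot", "copy_ratio",
]

CLINICAL_COLUMNS = [
    "sample", "age", "sex", "t_stage", "n_stage", "m_stage", "stage", "histology",
    "os_months", "os_event", "pfs_months", "pfs_event",
]

VARIANT_CLASSES = {"SNV", "INS", "DEL", "CNV", "SV"}

_STAGES = ["I", "II", "III", "IV"]


def stage_to_numeric(stage: str) -> int:
    """Clinical stage roman numeral -> 1..4."""
    try:
        return _STAGES.index(str(stage).strip().upper()) + 1
    except ValueError:
        raise ValueError(f"unknown clinical stage {stage!r}; expected I-IV") from None


def numeric_to_stage(code: int) -> str:
    if not 1 <= int(code) <= 4:
        raise ValueError(f"clinical stage code {code} out of range 1-4")
    return _STAGES[int(code) - 1]


class TableFormatError(ValueError):
    """A table failed validation; the message carries file and line context."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")


def _err(path, idx: int, message: str) -> TableFormatError:
    # +2: one for the header line, one for 1-based numbering
    return TableFormatError(f"{path}, line {idx + 2}: {message}")


def read_segments(path, genome: GenomeBuild) -> list[SegmentProfile]:
    """Read a SEG-like TSV into per-sample profiles.

    Expected columns: sample, chrom, start, end, cn_total, cn_minor with
    1-based inclusive coordinates.  Rows are grouped by sample in order of
    first appearance; invariants (start < end, minor is the smaller allele,
    known chromosome) are enforced per row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, SEGMENT_COLUMNS, path)
    profiles: dict[str, dict[str, list[Segment]]] = {}
    for idx, row in df.iterrows():
        try:
            chrom = normalize_chrom(row["chrom"])
            start1, end1 = int(row["start"]), int(row["end"])
            cn_total, cn_minor = int(row["cn_total"]), int(row["cn_minor"])
        except (TypeError, ValueError) as e:
            raise _err(path, idx, f"malformed row: {e}") from None
        if chrom not in genome.chromosomes:
            raise _err(path, idx, f"unknown chromosome {row['chrom']!r}")
        if start1 >= end1:
            raise _err(path, idx, f"start ({start1}) must be < end ({end1})")
        cm = genome.chromosome(chrom)
        if start1 < 1 or end1 > cm.length:
            raise _err(path, idx, f"segment [{start1}, {end1}] outside chromosome {chrom} (length {cm.length})")
        try:
            seg = Segment(start=start1 - 1, end=end1, cn_total=cn_total, cn_minor=cn_minor)
        except ValueError as e:
            raise _err(path, idx, str(e)) from None
        profiles.setdefault(str(row["sample"]), {}).setdefault(chrom, []).append(seg)
    return [SegmentProfile(sample=s, segments=by_chrom) for s, by_chrom in profiles.items()]


def write_segments(path, profiles: list[SegmentProfile]) -> None:
    """Write profiles back to the 1-based inclusive SEG-like TSV dialect."""
    rows = []
    for prof in profiles:
        for chrom in sorted(prof.segments, key=_chrom_sort_key):
            for seg in prof.segments[chrom]:
                rows.append(
                    {
                        "sample": prof.sample,
                        "chrom": chrom,
                        "start": seg.start + 1,
                        "end": seg.end,
                        "cn_total": seg.cn_total,
                        "cn_minor": seg.cn_minor,
                    }
                )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def _chrom_sort_key(name: str):
    return (0, int(name)) if name.isdigit() else (1, name)


def read_variants(path) -> pd.DataFrame:
    """Read a MAF-lite variant TSV.

    Missing optional numeric fields stay NaN (never silently 0); origin and
    variant class are case-normalized; AF and population frequency must lie
    in [0, 1] and supporting reads cannot exceed depth.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample", "gene", "variant_class", "origin"], path)
    out = pd.DataFrame(index=df.index)
    for col in VARIANT_COLUMNS:
        out[col] = df[col] if col in df.columns else np.nan
    out["sample"] = out["sample"].astype(str)
    out["gene"] = out["gene"].astype(str)
    out["variant_class"] = out["variant_class"].str.upper().str.strip()
    out["origin"] = out["origin"].str.lower().str.strip()
    for col in ("nonsynonymous", "coding", "hotspot"):
        out[col] = _parse_bool(out[col])
    for col in ("pos", "depth", "supporting_reads"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for col in ("af", "pop_freq", "copy_ratio"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    for idx in out.index:
        row = out.loc[idx]
        if row["variant_class"] not in VARIANT_CLASSES:
            raise _err(path, idx, f"unknown variant class {row['variant_class']!r}")
        if row["origin"] not in ("somatic", "germline"):
            raise _err(path, idx, f"unknown origin {row['origin']!r}")
        for col in ("af", "pop_freq"):
            v = row[col]
            if pd.notna(v) and not 0.0 <= v <= 1.0:
                raise _err(path, idx, f"{col}={v} outside [0, 1]")
        if pd.notna(row["copy_ratio"]) and row["copy_ratio"] < 0:
            raise _err(path, idx, f"copy_ratio={row['copy_ratio']} is negative")
        if (
            pd.notna(row["depth"])
            and pd.notna(row["supporting_reads"])
            and row["supporting_reads"] > row["depth"]
        ):
            raise _err(path, idx, "supporting_reads exceeds depth")
    return out


def write_variants(path, variants: pd.DataFrame) -> None:
    df = variants.copy()
    for col in ("nonsynonymous", "coding", "hotspot"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(bool(v)))
    df.to_csv(path, sep="\t", index=False)


def _parse_bool(series: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v) or str(v).strip() == "":
            return np.nan
        s = str(v).strip().lower()
        if s in ("1", "true", "yes", "y"):
            return True
        if s in ("0", "false", "no", "n"):
            return False
        raise TableFormatError(f"cannot parse boolean value {v!r}")

    return series.map(one)


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical/survival TSV: demographics, TNM, stage, OS/PFS."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CLINICAL_COLUMNS, path)
    out = df[CLINICAL_COLUMNS].copy()
    out["sample"] = out["sample"].astype(str)
    if out["sample"].duplicated().any():
        dupes = sorted(out.loc[out["sample"].duplicated(), "sample"].unique())
        raise TableFormatError(f"{path}: duplicate sample ids {dupes}")
    out["age"] = pd.to_numeric(out["age"])
    out["sex"] = out["sex"].str.lower().str.strip()
    for col, lo, hi in (("t_stage", 1, 4), ("n_stage", 0, 3), ("m_stage", 0, 1)):
        out[col] = pd.to_numeric(out[col]).astype(int)
        bad = ~out[col].between(lo, hi)
        if bad.any():
            raise _err(path, int(np.flatnonzero(bad)[0]), f"{col} outside [{lo}, {hi}]")
    out["stage"] = out["stage"].map(lambda s: numeric_to_stage(stage_to_numeric(s)))
    out["histology"] = out["histology"].str.upper().str.strip()
    for col in ("os_months", "pfs_months"):
        out[col] = pd.to_numeric(out[col])
        bad = out[col] < 0
        if bad.any():
            raise _err(path, int(np.flatnonzero(bad)[0]), f"negative {col}")
    for col in ("os_event", "pfs_event"):
        out[col] = pd.to_numeric(out[col]).astype(int)
        bad = ~out[col].isin((0, 1))
        if bad.any():
            raise _err(path, int(np.flatnonzero(bad)[0]), f"{col} must be 0/1")
    return out


def write_clinical(path, clinical: pd.DataFrame) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def write_results_json(path, per_sample: dict, meta: dict | None = None) -> None:
    """One machine-readable summary per run: sample -> scores/statuses/risk."""
    payload = {"meta": meta or {}, "samples": per_sample}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
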