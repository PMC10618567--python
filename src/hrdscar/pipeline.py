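"""End-to-end orchestration: score -> annotate -> stratify -> statistics.

`run_pipeline` sequences the library stages over the three input tables and
writes plain TSV outputs plus one JSON summary and a manifest; the
characteristics table mirrors the familiar clinical Table layout (per risk
category: n, mean age with 95% CI, and dichotomized sex/T/N/M/stage counts
with percentages, BH-adjusted tests across characteristics).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .genome import load_reference
from .risk import assign_gi_prs, assign_hrd_class, compute_cutoff, CutoffRule
from .scoring import HRDResult, ScoreParams, arm_event_density, score_gi
from .stats import bh_adjust, cox_univariate_then_multivariable, km_estimate, logrank_test
from .tables import read_clinical, read_segments, read_variants, write_results_json
from .variants import FilterConfig, compute_tmb, classify_tp53, filter_variants, minor_cn_at_gene

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_characteristics_table", "score_cohort", "annotate_cohort", "stratify_cohort"]


@dataclass
class RunConfig:
    segments: str
    variants: str | None = None
    clinical: str | None = None
    build: str = "hg19"
    params: ScoreParams = field(default_factory=ScoreParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    top_fraction: float = 0.20
    fixed_cutoff: float | None = None
    histology: str | None = None  # restrict the cutoff cohort, e.g. "LUAD"
    outdir: str = "hrdscar_out"
    seed: int = 0


def _round1(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def score_cohort(profiles, genome, params: ScoreParams) -> tuple[pd.DataFrame, list[HRDResult]]:
    """Score every profile; returns the per-sample score table and results."""
    results = [score_gi(p, genome, params) for p in profiles]
    scores = pd.DataFrame(
        {
            "sample": [r.sample for r in results],
            "loh": [r.loh for r in results],
            "tai": [r.tai for r in results],
            "lst": [r.lst for r in results],
            "gi_score": [r.gi_score for r in results],
        }
    )
    return scores, results


def annotate_cohort(variants: pd.DataFrame, profiles, genome, filters: FilterConfig) -> pd.DataFrame:
    """Filter variants, then per-sample TMB and TP53 status."""
    passing = filter_variants(variants, filters)
    by_sample = {p.sample: p for p in profiles}
    rows = []
    for sample, prof in by_sample.items():
        sv = passing[passing["sample"] == sample]
        tmb = compute_tmb(sv, filters)
        minor = minor_cn_at_gene(prof, genome, "TP53")
        status = classify_tp53(sv[sv["gene"] == "TP53"], minor)
        rows.append(
            {
                "sample": sample,
                "tmb_count": tmb.mutation_count,
                "tmb": tmb.tmb,
                "tmb_valid": tmb.valid,
                "tp53_status": status.status,
                "tp53_mechanism": status.mechanism,
                "tp53_altered": status.status in ("monoallelic", "biallelic"),
                "tp53_minor_cn": minor,
            }
        )
    return pd.DataFrame(rows)


def stratify_cohort(
    scores: pd.DataFrame,
    annotation: pd.DataFrame,
    top_fraction: float = 0.20,
    fixed_cutoff: float | None = None,
    cutoff_samples: list[str] | None = None,
) -> tuple[pd.DataFrame, CutoffRule]:
    """Join scores with TP53 status and assign GI-pRS categories.

    The cutoff is either supplied (the fixed clinical '>= 24' rule) or
    computed from the scores of ``cutoff_samples`` (default: all samples).
    """
    merged = scores.merge(annotation[["sample", "tp53_altered"]], on="sample", how="left")
    merged["tp53_altered"] = merged["tp53_altered"].fillna(False).astype(bool)
    if fixed_cutoff is not None:
        rule = CutoffRule(top_fraction=top_fraction, cutoff=float(fixed_cutoff))
    else:
        pool = merged if cutoff_samples is None else merged[merged["sample"].isin(cutoff_samples)]
        rule = compute_cutoff(pool["gi_score"].to_numpy(), top_fraction)
    assignments = [
        assign_gi_prs(r["sample"], assign_hrd_class(r["gi_score"], rule), r["tp53_altered"])
        for _, r in merged.iterrows()
    ]
    risk = merged.copy()
    risk["hrd_high"] = [a.hrd_high for a in assignments]
    risk["gi_prs"] = [a.gi_prs for a in assignments]
    risk["category"] = [a.category for a in assignments]
    return risk, rule


def make_characteristics_table(
    risk: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical characteristics by GI-pRS category.

    Returns ``(summary, tests)``: the summary holds one row per
    characteristic level and category with count and half-up one-decimal
    percentage (mean and 95% CI for age); the tests table holds one
    chi-square (categorical) or one-way ANOVA (age) p per characteristic,
    BH-adjusted across characteristics.  Empty categories are emitted with
    n = 0 and excluded from testing.
    """
    df = risk[["sample", "gi_prs"]].merge(clinical, on="sample")
    cats = [0, 1, 2]
    groups = {c: df[df["gi_prs"] == c] for c in cats}
    dichotomies = {
        "sex_male": lambda g: g["sex"] == "male",
        "t_stage_3_4": lambda g: g["t_stage"] >= 3,
        "n_stage_1_3": lambda g: g["n_stage"] >= 1,
        "m_stage_1": lambda g: g["m_stage"] == 1,
        "stage_III_IV": lambda g: g["stage"].isin(("III", "IV")),
    }
    rows = []
    for c in cats:
        g = groups[c]
        n = len(g)
        if n:
            mean = float(g["age"].mean())
            sd = float(g["age"].std(ddof=1)) if n > 1 else 0.0
            half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n) if n > 1 else 0.0
            rows.append(
                {"characteristic": "age", "level": "mean", "category": c, "n": n,
                 "value": mean, "ci_low": mean - half, "ci_high": mean + half, "pct": np.nan}
            )
        else:
            rows.append({"characteristic": "age", "level": "mean", "category": c, "n": 0,
                         "value": np.nan, "ci_low": np.nan, "ci_high": np.nan, "pct": np.nan})
        for name, fn in dichotomies.items():
            k = int(fn(g).sum()) if n else 0
            pct = _round1(100.0 * k / n) if n else np.nan
            rows.append({"characteristic": name, "level": "yes", "category": c, "n": k,
                         "value": np.nan, "ci_low": np.nan, "ci_high": np.nan, "pct": pct})
            rows.append({"characteristic": name, "level": "no", "category": c, "n": (n - k) if n else 0,
                         "value": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "pct": _round1(100.0 * (n - k) / n) if n else np.nan})
    summary = pd.DataFrame(rows)

    nonempty = [c for c in cats if len(groups[c]) > 0]
    tests = []
    if len(nonempty) >= 2:
        age_groups = [groups[c]["age"].to_numpy() for c in nonempty]
        if all(len(a) >= 2 for a in age_groups):
            p_age = float(sps.f_oneway(*age_groups).pvalue)
            if np.isfinite(p_age):  # zero-variance ages make the test degenerate
                tests.append({"characteristic": "age", "p_value": p_age})
        for name, fn in dichotomies.items():
            table = np.array(
                [[int(fn(groups[c]).sum()), int((~fn(groups[c])).sum())] for c in nonempty]
            )
            if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
                p_cat = float(sps.chi2_contingency(table).pvalue)
                if np.isfinite(p_cat):
                    tests.append({"characteristic": name, "p_value": p_cat})
    tests_df = pd.DataFrame(tests)
    if len(tests_df):
        tests_df["p_adjusted"] = bh_adjust(tests_df["p_value"])
    return summary, tests_df


def _survival_outputs(risk: pd.DataFrame, clinical: pd.DataFrame, outdir: Path) -> dict:
    df = risk.merge(clinical, on="sample")
    df["sex_male"] = (df["sex"] == "male").astype(int)
    df["t_3_4"] = (df["t_stage"] >= 3).astype(int)
    df["n_pos"] = (df["n_stage"] >= 1).astype(int)
    df["m_1"] = (df["m_stage"] == 1).astype(int)
    df["hrd_high"] = df["hrd_high"].astype(int)
    df["tp53_altered"] = df["tp53_altered"].astype(int)
    out = {}
    for endpoint, time_col, event_col in (("os", "os_months", "os_event"), ("pfs", "pfs_months", "pfs_event")):
        km_frames = []
        for cat, sub in df.groupby("category"):
            km = km_estimate(sub[time_col], sub[event_col], label=str(cat))
            km.insert(0, "category", cat)
            km_frames.append(km)
        km_all = pd.concat(km_frames, ignore_index=True)
        km_all.to_csv(outdir / f"km_{endpoint}.tsv", sep="\t", index=False)
        stat, p = logrank_test(df[time_col], df[event_col], df["gi_prs"])
        out[f"logrank_{endpoint}"] = {"statistic": stat, "p_value": p}
        variables = ["hrd_high", "tp53_altered", "age", "sex_male", "t_3_4", "n_pos", "m_1"]
        uni, multi = cox_univariate_then_multivariable(df, time_col, event_col, variables)
        uni.to_csv(outdir / f"cox_{endpoint}_univariate.tsv", sep="\t", index=False)
        multi.to_csv(outdir / f"cox_{endpoint}_multivariable.tsv", sep="\t", index=False)
        out[f"cox_{endpoint}"] = {"univariate": uni.to_dict("records"), "multivariable": multi.to_dict("records")}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run score -> annotate -> stratify -> statistics and write the bundle.

    Survival statistics and the characteristics table require the clinical
    table; requesting them without one is a stage error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_reference(config.build)

    logger.info("stage score: reading %s", config.segments)
    profiles = read_segments(config.segments, genome)
    scores, results = score_cohort(profiles, genome, config.params)
    scores.to_csv(outdir / "scores.tsv", sep="\t", index=False)
    events = pd.DataFrame(
        [
            {"sample": r.sample, "kind": e.kind, "chrom": e.chrom, "arm": e.arm,
             "start": e.start, "end": e.end}
            for r in results
            for e in r.events
        ]
    )
    events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    arm_event_density(results, genome).to_csv(outdir / "arm_density.tsv", sep="\t")

    annotation = pd.DataFrame({"sample": scores["sample"], "tp53_altered": False})
    if config.variants is not None:
        logger.info("stage annotate: reading %s", config.variants)
        variants = read_variants(config.variants)
        annotation = annotate_cohort(variants, profiles, genome, config.filters)
        annotation.to_csv(outdir / "tp53_tmb.tsv", sep="\t", index=False)

    clinical = None
    cutoff_samples = None
    if config.clinical is not None:
        clinical = read_clinical(config.clinical)
        if config.histology is not None:
            cutoff_samples = clinical.loc[
                clinical["histology"] == config.histology, "sample"
            ].tolist()

    logger.info("stage stratify")
    risk, rule = stratify_cohort(
        scores, annotation, config.top_fraction, config.fixed_cutoff, cutoff_samples
    )
    risk.to_csv(outdir / "risk.tsv", sep="\t", index=False)

    bundle: dict = {
        "cutoff": rule.cutoff,
        "cutoff_mode": "fixed" if config.fixed_cutoff is not None else f"top_{config.top_fraction:g}",
        "n_samples": int(len(scores)),
    }
    if clinical is not None:
        logger.info("stage statistics")
        summary, tests = make_characteristics_table(risk, clinical)
        summary.to_csv(outdir / "characteristics.tsv", sep="\t", index=False)
        tests.to_csv(outdir / "characteristics_tests.tsv", sep="\t", index=False)
        bundle.update(_survival_outputs(risk, clinical, outdir))

    per_sample = {
        r["sample"]: {
            "loh": int(r["loh"]), "tai": int(r["tai"]), "lst": int(r["lst"]),
            "gi_score": int(r["gi_score"]), "hrd_high": bool(r["hrd_high"]),
            "tp53_altered": bool(r["tp53_altered"]), "gi_prs": int(r["gi_prs"]),
            "category": r["category"],
        }
        for _, r in risk.iterrows()
    }
    write_results_json(
        outdir / "summary.json",
        per_sample,
        meta={"cutoff": rule.cutoff, "cutoff_mode": bundle["cutoff_mode"]},
    )
    manifest = {
        "version": __version__,
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("params", "filters")},
            "params": asdict(config.params),
            "filters": {k: v for k, v in asdict(config.filters).items()},
        },
        "cutoff": {"value": rule.cutoff, "mode": bundle["cutoff_mode"], "degenerate": rule.degenerate},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["risk"] = risk
    bundle["scores"] = scores
    return bundle
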