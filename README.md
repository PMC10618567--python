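# hrdscar

Genomic-instability scar scoring and survival risk stratification for
tumor panel sequencing, built around allele-specific copy-number segment
profiles.

Homologous recombination deficiency (HRD) leaves characteristic "scars" in
a tumor genome. Given per-sample segments carrying integer total and
minor-allele copy numbers, `hrdscar` counts the three canonical scar event
classes and sums them into the genomic-instability score used clinically:

- **LOH** — maximal regions with zero minor-allele copies (and ≥1 retained
  copy), longer than 15 Mb and shorter than the whole chromosome;
- **TAI** — maximal allelically imbalanced regions (total ≠ 2·minor) that
  reach a telomere, do not cross the centromere, and are longer than 11 Mb;
- **LST** — per-arm breakpoints between allele-specific copy-number regions
  both longer than 10 Mb, after smoothing away regions shorter than 3 Mb;
- **GI/HRD score** = LOH + TAI + LST.

On top of the score it implements the downstream clinical analysis for
lung-adenocarcinoma cohorts: panel TMB (qualifying nonsynonymous somatic
mutations / 1.003 Mb), TP53 mono/biallelic status (mutation + LOH,
germline + somatic, or two somatic mutations), the top-20% GI/HRD-high
cutoff applied as `score ≥ cutoff`, and the three-level genomic-instability
prognostic risk score

```
GI-pRS = 1[GI/HRD high] + 1[TP53 altered]   (0 = low, 1 = medium, 2 = high)
```

with the cohort statistics used around it: pooled-t group comparisons and
Fisher co-occurrence with Benjamini–Hochberg correction, ROC/AUC,
Kaplan–Meier, log-rank, and univariate → multivariable Cox regression.
A synthetic-cohort generator plants scar lesions, TP53 configurations, a
TMB-calibrated mutation background, and proportional-hazards survival with
known hazard ratios, and ships with an independent bin-rasterizing scoring
oracle for validation.

## Input tables

All inputs are TSV with fixed header names (column order free, extra
columns ignored); coordinates are 1-based inclusive (SEG convention).

| file | required columns |
|---|---|
| segments | `sample chrom start end cn_total cn_minor` |
| variants | `sample gene variant_class origin` plus `chrom pos nonsynonymous coding af depth supporting_reads pop_freq hotspot copy_ratio` |
| clinical | `sample age sex t_stage n_stage m_stage stage histology os_months os_event pfs_months pfs_event` |

## Worked example

`examples/01_score_profile.py` builds a profile with a 20 Mb interstitial
deletion LOH on 1p and a 12 Mb telomeric gain on 2p and prints:

```
sample TUMOR-1: LOH=1 TAI=1 LST=3 GI/HRD score=5
  LOH on 1p [30.0, 50.0] Mb
  TAI on 2p [0.0, 12.0] Mb
  LST on 1p [30.0, 30.0] Mb
  LST on 1p [50.0, 50.0] Mb
  LST on 2p [12.0, 12.0] Mb
```

The LOH region contributes one LOH event *and* two large-scale transitions
(its breakpoints); the telomeric gain one TAI and one further transition —
scar classes overlap by construction, and the score is their plain sum.
`examples/04_survival_analysis.py` simulates 1200 patients with the
risk-model hazard ratios planted and recovers them by Cox regression:

```
Cox is_medium: HR = 2.02 (95% CI 1.68-2.42)
Cox is_high: HR = 8.25 (95% CI 6.84-9.95)
```

i.e. estimates near the planted medium-vs-low 2.29 and high-vs-low 8.56.

## Command line

A thin CLI wraps the library:

```bash
hrdscar simulate --seed 1 --n-samples 200 --outdir cohort/
hrdscar run --segments cohort/segments.tsv --variants cohort/variants.tsv \
            --clinical cohort/clinical.tsv --outdir out/
hrdscar stratify --scores out/scores.tsv --tp53-status out/tp53_tmb.tsv --fixed-cutoff 24
```

Subcommands: `score`, `tp53`, `tmb`, `stratify`, `survival`, `simulate`,
`report`, `run`. Outputs are plain TSV plus one `summary.json` per run and
a `manifest.json` recording the configuration.

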