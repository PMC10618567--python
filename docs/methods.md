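# Methods

## Segment model and coordinates

A tumor genome is a per-chromosome list of sorted, non-overlapping segments
carrying integer allele-specific copy numbers `(cn_total, cn_minor)`, with
`cn_minor` the smaller parental allele count (`cn_minor ≤ cn_total −
cn_minor` is enforced). Internally all coordinates are 0-based half-open;
on disk the SEG dialect is 1-based inclusive. Profiles are normalized
before scoring: segments sorted, overlaps rejected, and adjacent segments
with identical state merged, optionally bridging inter-segment gaps up to
`bridge_gap_bp` (default 0; sparse panel segmentations may need Mb-scale
values).

The packaged hg19 model provides the 22 autosomes plus X/Y with arm
intervals and the TP53 locus (chr17:7,571,720–7,590,868, overridable).
Chromosome lengths and centromere bounds are stored at 100-kb resolution
(UCSC hg19 values truncated to the grid). Scar scoring operates at
megabase scale, so sub-100-kb boundary precision is immaterial; the uniform
grid also keeps the scoring engine's exact interval arithmetic and the
validation oracle's fixed-bin rasterization in exact agreement. Sex
chromosomes are excluded from scoring by default (`include_sex_chromosomes`
flips this): scar scores are conventionally autosomal.

## Scar event definitions

All length thresholds are strict in the direction their wording implies.

- **LOH**: maximal runs of strictly adjacent segments with `cn_minor = 0`
  and `cn_total ≥ 1`, length > 15 Mb, not spanning the whole chromosome.
  Homozygous deletions `(0,0)` do not qualify — there is no retained
  allele — and they break an LOH run. Runs may mix states (e.g. `(1,0)`
  followed by `(2,0)` is one region).
- **TAI**: maximal runs of allelic imbalance (`cn_total ≠ 2·cn_minor`,
  any mix of imbalanced states) that come within `telomere_tol_bp`
  (default 1 kb) of a chromosome end, do not overlap both arms, and have
  length > 11 Mb. Note `(0,0)` is arithmetically balanced.
- **LST**: computed per arm with the centromere as a hard boundary that
  never contributes a breakpoint. Segments are clipped to the arm, regions
  shorter than 3 Mb are dropped, surviving same-state neighbours re-merge
  across the removed gaps, and a transition counts when both flanking
  regions exceed 10 Mb and the gap between them is at most 3 Mb
  (`lst_max_gap_mb`, exposed because segmentation pipelines differ on it).

"Whole chromosome" (the LOH/TAI sub-chromosomal requirement) means
covering ≥ 99% of the modeled chromosome length (`whole_chrom_fraction`):
real panel segments rarely touch the exact ends. One shared fraction
serves both event classes.

The GI/HRD score is the unweighted sum LOH + TAI + LST; no ploidy
correction is applied anywhere. For arm-density tables an event is
assigned to the arm holding its midpoint (a midpoint inside the centromere
falls to the nearer arm); LST breakpoints are intrinsically arm-local.

## Validation oracle

`hrdscar.simulate.oracle_score` is an independent implementation used only
for testing: it rasterizes each chromosome into 0.1-Mb bins sampled at bin
left edges, finds maximal qualifying runs, and applies the three
definitions literally. The acceptance suite requires exact count equality
with the segment-walking engine on 500 random synthetic profiles, plus
split- and order-invariance of the engine under re-segmentation. Because
generated breakpoints and the packaged coordinate model sit on the same
100-kb grid, engine and oracle length comparisons are exact, not
approximate; on off-grid real data only the engine's exact arithmetic is
used.

## Variant filtering, TMB, TP53

Threshold filters mirror a targeted-panel pipeline: depth ≥ 100;
supporting reads ≥ 8 (SNV), ≥ 2 (insertion), ≥ 5 (deletion); population
frequency ≤ 0.1%; allele fraction ≥ 2% for tissue (0.2% plasma). Read-level
false-positive filtering is upstream and out of scope. Gene-level CNV
calls use the detection limits as attainable thresholds: copy ratio ≤ 1.5
deletion, ≥ 2.64 amplification.

TMB divides the qualifying count — nonsynonymous, coding, somatic SNVs and
indels at or above the AF floor, excluding hotspot-flagged rows — by the
panel's 1.003 Mb coding footprint. CNVs, SVs and germline variants never
count. When the maximum AF across a sample's small variants is below 5%
(tissue; 1% plasma) the value is flagged invalid rather than erroring:
low maximum AF suggests tumor content too low to trust a low TMB. The
hotspot flag is an input annotation, not computed.

TP53 status: **biallelic** when a passing mutation co-occurs with minor
copy number 0 at the locus, or when two passing mutations form germline +
somatic or somatic + somatic (assumed in trans; no phasing attempted);
**monoallelic** for a single mutation with the wild-type allele retained;
**wild-type** otherwise — LOH alone leaves one functional allele. Mechanism
precedence when several apply: mutation + LOH > germline + somatic > two
somatic. Germline-only double mutations fall outside the recognized
biallelic combinations and are reported as monoallelic-equivalent `multi`
with a warning. An uncovered locus yields a mutation-only call with a
warning flag. Downstream, "TP53 altered" means any passing TP53 mutation
(mono- or biallelic), never LOH alone.

## Cutoff and GI-pRS

The GI/HRD-high cutoff follows the panel-TMB convention: the smallest
observed score `t` with `|{s ≥ t}|/n ≤ 0.20`, applied as `score ≥ t`.
Ties are therefore handled conservatively (the high class never exceeds
the target fraction); if all scores are equal no threshold works and the
rule degenerates to max + 1 with an empty high class and a logged warning
(`W_CUTOFF_DEGENERATE`). A fixed clinical cutoff (e.g. 24) can be supplied
instead, and the cutoff cohort can be restricted to one histology (LUAD)
since score distributions differ between adenocarcinoma and squamous
histology. GI-pRS is the indicator sum of GI/HRD-high and TP53-altered,
mapped 0 → low, 1 → medium, 2 → high.

## Statistics

Group score comparisons use the pooled-variance two-sided t test (Welch
behind a flag — the choice matters only under strong variance
heterogeneity); co-occurrence uses the two-sided Fisher exact test
(point-probability method) with direction from the odds ratio;
multiplicity is controlled by Benjamini–Hochberg within each screen.
AUC is the Mann–Whitney statistic with ties counted one half. Survival
uses the product-limit estimator, the standard observed-minus-expected
log-rank chi-square, and Cox partial likelihood with Efron tie handling
(delegated to lifelines; the contracts, not the optimizer, are normative
and are pinned by hand-computed oracles in the tests). Model building
follows a univariate screen: covariates with univariate p < 0.05 enter the
multivariable model. The characteristics table reports per-category n,
mean age with a t-based 95% CI, and dichotomized sex/T/N/M/stage counts
with half-up one-decimal percentages; age is tested by one-way ANOVA,
categories by chi-square, BH-adjusted across characteristics; degenerate
tests (empty categories, zero variance) are skipped, not forced.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the assay: integer allele-specific segments over the packaged autosomes,
starting diploid `(2,1)`. Lesion classes per sample: interstitial
copy-neutral or deletion LOH (5–40 Mb), telomere-anchored gains/losses
(5–30 Mb), staircase runs of 2–4 short state changes (2–15 Mb each), and
occasional whole-chromosome LOH (probability 0.05) — lengths chosen to
straddle every scoring threshold. Counts are Poisson with means 1.5 / 1.2
/ 1.0 scaled by a per-sample exponential instability multiplier: the long
tail is what makes a top-20% cutoff meaningful. Ground-truth scores come
from the oracle, never from planted lesion counts, because lesion classes
interact (an interstitial LOH is also two LSTs).

TP53 states are drawn wild/mono/biallelic with probabilities 0.45 / 0.25 /
0.30 (biallelic mechanisms 0.6 LOH, 0.1 germline + somatic, 0.3 two
somatic), with the profile and variant generators coordinated: the LOH
mechanism forces a minor-copy-zero lesion over the locus, all other states
keep it heterozygous, and an inconsistent request is an error rather than
a silent fix. Background somatic mutations bring each sample's qualifying
TMB count to a Poisson(8) target exactly, all emitted variants passing the
default filters.

Survival is exponential proportional hazards on the GI-pRS linear
predictor with planted log-hazard coefficients ln 2.29 (medium) and
ln 8.56 (high) for OS, ln 2.29 and ln 4.76 for PFS — the high-vs-low and
medium-vs-low hazard ratios of the risk model; the OS medium coefficient
is a modeling default chosen equal to the PFS value, as no separate OS
medium ratio is defined. Baseline hazards (0.010 and 0.020 events/month)
give the low-risk group roughly 45% OS event probability before
administrative censoring at 60 months. Age, sex and TNM marginals shift
with the risk category so characteristic-table gradients appear
qualitatively. The generator is deterministic given its seed, to the byte
on disk.

What the synthetic cohorts do **not** emulate: SNP-level BAF/logR noise
and segmentation error (profiles are exact), purity/ploidy estimation,
subclonality, off-grid breakpoints, covariate-dependent censoring, and
histology mixtures (all samples are LUAD by default). Passing tests
therefore demonstrate correctness of the counting rules, the calling
logic, the cutoff/risk algebra and the statistical machinery on clean
segment input — not robustness to segmentation noise, which is upstream of
this package's contract.

## Problem sizes and numerics

The test suite scores 500 random profiles against the oracle and verifies
invariance under 200 random re-segmentations; hazard-ratio recovery uses
n = 2000 with 100 replicates (the planted HR 8.56 estimate falls in
[6.5, 11.5] in ≥ 90 of 100 seeds). The acceptance script uses a
400-sample pipeline cohort and a 4000-sample survival cohort, at which the
Cox standard error on the log hazard ratio is ≈ 0.05–0.07. Cutoff and
score arithmetic is exact integer work; the only floating-point
comparisons are the Mb thresholds, applied to integer base-pair lengths
well away from representability issues.

## Known limitations

- LOH/TAI run-building requires strict segment adjacency; uncovered gaps
  split regions unless bridged explicitly via `bridge_gap_bp`.
- The LST inter-region gap rule and the 99% whole-chromosome fraction are
  conventions exposed as parameters; other pipelines may differ.
- No ploidy-adjusted score variants, no mutational-signature inference,
  no SNP-level segmentation; the pipeline starts from called segments.
- The Fisher p uses the point-probability two-sided convention; other
  two-sided definitions can differ for small tables.
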