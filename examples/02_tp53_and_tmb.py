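"""Variant filtering, panel TMB and TP53 biallelic status for one sample.

Builds a small MAF-lite variant table: a somatic TP53 mutation, a germline
TP53 mutation, a hotspot mutation, a low-depth call, and a handful of
qualifying somatic background mutations.
"""

import numpy as np
import pandas as pd

from hrdscar import FilterConfig, classify_tp53, compute_tmb, filter_variants

def row(**kw):
    base = dict(sample="TUMOR-1", gene="KRAS", chrom="12", pos=25_000_000,
                variant_class="SNV", nonsynonymous=True, coding=True,
                origin="somatic", af=0.25, depth=600, supporting_reads=150,
                pop_freq=0.0, hotspot=False, copy_ratio=np.nan)
    base.update(kw)
    return base

variants = pd.DataFrame([
    row(gene="TP53", chrom="17", pos=7_578_406, af=0.42),
    row(gene="TP53", chrom="17", pos=7_577_121, origin="germline", af=0.51),
    row(gene="BRAF", hotspot=True),               # hotspot: filtered in, excluded from TMB
    row(gene="STK11", depth=80),                  # fails the depth >= 100 filter
    *[row(gene=g, pos=i) for i, g in enumerate(["LRP1B", "SPTA1", "CDKN2A", "RB1", "KEAP1"])],
])

config = FilterConfig(material="tissue")
passing, reasons = filter_variants(variants, config, with_reasons=True)
print(f"{len(variants)} calls, {len(passing)} pass filters; dropped: {list(reasons.values())}")

tmb = compute_tmb(passing, config)
print(f"TMB = {tmb.mutation_count}/{tmb.panel_size_mb} = {tmb.tmb:.3f} mut/Mb "
      f"(valid={tmb.valid})")

# minor copy number 1 at the TP53 locus: no LOH of the wild-type allele
status = classify_tp53(passing[passing["gene"] == "TP53"], minor_cn_at_tp53=1)
print(f"TP53: {status.status} via {status.mechanism}; evidence: {list(status.evidence)}")

# The germline + somatic pair disables both TP53 alleles, so the call is
# biallelic even though the locus keeps both copies.  The TMB count holds
# the 6 qualifying somatic nonsynonymous mutations (5 background + somatic
# TP53): germline and hotspot calls are excluded by the printed rules.
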