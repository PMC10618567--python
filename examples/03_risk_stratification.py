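"""GI/HRD-high cutoff and GI-pRS risk categories for a toy cohort.

The high/low cutoff follows the panel-TMB convention: the smallest observed
score that keeps at most 20% of the cohort at or above it.  GI-pRS adds the
TP53-alteration flag: 0 = low, 1 = medium, 2 = high risk.
"""

import numpy as np

from hrdscar import assign_gi_prs, assign_hrd_class, compute_cutoff

rng = np.random.default_rng(7)
scores = rng.poisson(9, size=100)          # integer GI/HRD scores
tp53 = rng.random(100) < 0.45              # 45% of samples TP53-altered

rule = compute_cutoff(scores, top_fraction=0.20)
print(f"top-20% cutoff: score >= {rule.cutoff:g} is GI/HRD-high "
      f"({np.mean(scores >= rule.cutoff):.0%} of the cohort)")

categories = {}
for i, (s, t) in enumerate(zip(scores, tp53)):
    a = assign_gi_prs(f"S{i}", assign_hrd_class(s, rule), bool(t))
    categories[a.category] = categories.get(a.category, 0) + 1
print("GI-pRS categories:", dict(sorted(categories.items())))

# Low-risk patients have neither risk factor, medium exactly one, high both.
# The cutoff is conservative at ties: the high class never exceeds 20%.
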