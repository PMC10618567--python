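"""Kaplan-Meier, log-rank and Cox analysis of a simulated risk cohort.

Survival times follow an exponential proportional-hazards model with the
risk-model hazard ratios planted (OS: medium 2.29, high 8.56 vs low); Cox
regression should recover them.
"""

import numpy as np
import pandas as pd

from hrdscar.simulate import SimConfig, simulate_clinical_survival
from hrdscar.stats import cox_fit, km_estimate, logrank_test

n = 1200
rng = np.random.default_rng(42)
assignments = pd.DataFrame({"sample": [f"S{i}" for i in range(n)],
                            "gi_prs": np.tile([0, 1, 2], n // 3)})
clinical = simulate_clinical_survival(assignments, SimConfig(seed=0), rng)

for cat in (0, 1, 2):
    sub = clinical[assignments["gi_prs"] == cat]
    km = km_estimate(sub["os_months"], sub["os_event"])
    below = km[km["survival"] <= 0.5]
    median = below["time"].iloc[0] if len(below) else float("inf")
    print(f"GI-pRS {cat}: n={len(sub)}, median OS = {median:.1f} months")

stat, p = logrank_test(clinical["os_months"], clinical["os_event"], assignments["gi_prs"])
print(f"log-rank across categories: chi2 = {stat:.1f}, p = {p:.3g}")

df = clinical.assign(is_medium=(assignments["gi_prs"] == 1).astype(int),
                     is_high=(assignments["gi_prs"] == 2).astype(int))
fit = cox_fit(df, "os_months", "os_event", ["is_medium", "is_high"])
for _, r in fit.iterrows():
    print(f"Cox {r['variable']}: HR = {r['hr']:.2f} "
          f"(95% CI {r['hr_lower95']:.2f}-{r['hr_upper95']:.2f})")

# The estimated hazard ratios should sit near the planted 2.29 (medium) and
# 8.56 (high); the spread of the confidence intervals shows the precision a
# cohort of this size affords.
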