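"""Rank-based longitudinal tests on a small two-group dataset.

Builds an F1-LD-F1 layout (two genotypes x three time points), prints the
relative treatment effects (probability-scale effect sizes), the Wald-type
and ANOVA-type statistics for each effect, and Bonferroni-corrected
p-values.
"""

import numpy as np
import pandas as pd

from pharmaeeg.longstats import (LongitudinalDataset, bonferroni, fit_design,
                                 relative_effects)

rng = np.random.default_rng(0)
rows = []
for genotype, n, trend in (("WT", 9, 0.0), ("KO", 8, 0.4)):
    for i in range(n):
        subject_offset = rng.normal(0, 0.2)
        for t in range(3):
            rows.append({"unit": f"{genotype}{i}", "genotype": genotype,
                         "time": t,
                         "value": np.exp(subject_offset + trend * t
                                         + rng.normal(0, 0.2))})
data = pd.DataFrame(rows)
ld = LongitudinalDataset(data, unit="unit", factors=("genotype",),
                         time="time", value="value")

print("relative treatment effects (p_hat in (0,1), weighted mean = 0.5):")
print(relative_effects(ld).round(3).to_string(index=False))

fits = fit_design(ld)
print("\neffect tests (WTS: chi-square, df = contrast rank; "
      "ATS: Box-approximated df):")
raw = {}
for effect, res in fits.items():
    w, a = res["wts"], res["ats"]
    raw[effect] = a.p_raw
    print(f"  {effect:12s} WTS={w.statistic:7.3f} (df={w.df}, p={w.p_raw:.2e})  "
          f"ATS={a.statistic:7.3f} (df={a.df:.2f}, p={a.p_raw:.2e})")

m = len(raw)
print(f"\nBonferroni over the {m} effects:")
for effect, p in raw.items():
    print(f"  {effect:12s} p_corrected = {bonferroni(p, m):.3g}")
print("\nThe KO group's injected upward time trend shows up as significant")
print("genotype x time interaction; the rank tests see only order information.")
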