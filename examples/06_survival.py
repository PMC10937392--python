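"""Kaplan-Meier and log-rank comparison of the immune subtypes.

Simulates a 240-sample cohort whose survival hazards depend on subtype
(IM4 has a hazard ratio of 3 versus IM2), fits KM curves, and runs the
global log-rank test with BH-adjusted pairwise comparisons gated on the
global p < 0.05.
"""

import numpy as np
import pandas as pd

from dccd import km_fit, logrank, simulate_bulk_cohort

_, meta, truth = simulate_bulk_cohort(n_samples=240, seed=0)
records = pd.DataFrame({
    "sample_id": meta.index,
    "time": meta["os_time"],
    "event": meta["os_event"],
    "group": truth.bulk_subtype_labels.loc[meta.index],
})
records = records[records["time"] > 0]

curves = km_fit(records)
for name, curve in sorted(curves.items()):
    idx = np.searchsorted(-curve.survival, -0.5)
    med = curve.times[idx] if idx < len(curve.times) else float("inf")
    print(f"{name}: KM median survival ~ {med:.0f} days")

chi2, p, pairs = logrank(records)
print(f"\nglobal log-rank: chi2 = {chi2:.2f}, p = {p:.2e}")
if pairs is not None:
    print(pairs.to_string(index=False))
# IM4 (the DCCD subtype) shows the shortest median survival; the
# pairwise table isolates which subtype contrasts drive the global
# difference, with BH-adjusted p-values.
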