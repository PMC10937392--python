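"""Score de-clear-cell differentiation (DCCD) on a gradient cohort.

Simulates 150 bulk samples blending the IM2 and IM4 signatures by a
planted mixing fraction, computes DCCD = z(IM4 score) - z(IM2 score) per
sample, and checks that the score recovers each sample's position on the
IM2->IM4 continuum.
"""

from dccd import (dccd_score, dccd_trajectory, default_bulk_signatures,
                  pearson, simulate_bulk_cohort)

sigs = default_bulk_signatures()
expr, meta, truth = simulate_bulk_cohort(
    n_samples=150, signatures=sigs, dccd_gradient=True, seed=2)
res = dccd_score(expr, sigs["IM2"], sigs["IM4"])
print(res.head(3)[["entity_id", "dccd_score", "label", "rank"]])

r, _ = pearson(res.set_index("entity_id")
               .loc[truth.dccd_mixing_fraction.index, "dccd_score"],
               truth.dccd_mixing_fraction)
print(f"correlation with planted mixing fraction: r = {r:.3f}")

traj = dccd_trajectory(res, expr.to_log2(), sigs["IM4"][:5], window=11)
first = traj.iloc[0]
print(f"smoothed IM4 gene {traj.index[0]}: "
      f"{first.iloc[0]:.2f} (IM2 end) -> {first.iloc[-1]:.2f} (IM4 end)")
# DCCD > 0 marks IM4-like (de-clear-cell) samples; ranking by the score
# is the bulk pseudotrajectory, along which IM4 signature genes rise
# monotonically after moving-average smoothing.
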