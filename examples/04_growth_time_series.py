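"""Follow a growing gallery system image by image.

The synthetic generator grows a branching system from an entrance and
emits the project a user would have traced; compute_series turns it into
one summary row per image with per-rank lengths and growth increments.
"""

from gallerytrack import GrowthParams, compute_series, generate

params = GrowthParams(seed=7, n_steps=12, branch_prob_per_step=0.2)
state, truth = generate(params)

print("serial  total_mm  primary  secondary  tertiary  growth_mm  galleries")
for r in compute_series(state, "synth"):
    print(f"{r.serial:6d}  {r.total_mm:8.2f}  {r.len1_mm:7.2f}  "
          f"{r.len2_mm:9.2f}  {r.len3_mm:8.2f}  {r.growth_mm:9.2f}  "
          f"{r.n_galleries:9d}")
print(f"\nground-truth final total: {truth.steps[-1].total_mm:.2f} mm")
# The totals are cumulative and non-decreasing (galleries only grow);
# the last line shows the pipeline agrees with the generator's bookkeeping.
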