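"""Color-patch and true/false ROI definition on synthetic maps.

Shows the two ROI procedures: (1) bilateral color patches from a
chromatic-vs-achromatic contrast t map (3.5 mm spheres at cluster
centers, top 50 voxels per hemisphere, collapsed to 100), and (2) the
anti-double-dipping true/false ROI built from four define/measure
combinations (top 10 voxels each, combined top 50).
"""

import numpy as np

import memcolor as mc

# -- color patches ---------------------------------------------------------
shape = (22, 14, 14)
rng = np.random.default_rng(0)
tmap = np.zeros(shape)
tmap[3:8, 4:9, 4:9] = 5 + rng.random((5, 5, 5))     # left-hemisphere cluster
tmap[14:19, 4:9, 4:9] = 5 + rng.random((5, 5, 5))   # right-hemisphere cluster
vt = mc.default_voxel_table(shape)
patches = mc.define_color_patches(tmap, vt, threshold_t=2.0)
for roi in patches:
    print(f"color patch {roi.name}: {roi.hemisphere}, {roi.n_voxels} voxels, "
          f"center {roi.center}")

# -- true/false ROI with the 4 combinations --------------------------------
conds = [f"{o}_{tf}" for o in mc.EXP3_OBJECTS for tf in ("true", "false")]
n_runs, n_vox = 8, 120
values = rng.normal(0, 0.2, size=(n_runs * len(conds), n_vox))
is_true = np.array([c.endswith("_true") for c in conds * n_runs])
# 70 modulated voxels with graded effect sizes, so the 4 sub-ROIs overlap
# only partially and the combined top-50 selection has something to do
values[np.ix_(is_true, np.arange(70))] += rng.uniform(0.1, 1.0, 70)
import pandas as pd
pattern = mc.PatternMatrix(values, pd.DataFrame({
    "experiment": "EXP3", "condition": conds * n_runs,
    "run": np.repeat(np.arange(1, n_runs + 1), len(conds)),
    "session": 1, "period": "first",
}))

schemes = mc.enumerate_combinations(mc.RED_GREEN_CATEGORIES)
subrois = [
    mc.define_truefalse_roi(pattern, np.ones(n_vox, bool), s, top_n=10)
    for s in schemes
]
combined = mc.combine_subrois(subrois, top_n_combined=50)
print(f"\n{len(schemes)} define/measure combinations; "
      f"combined ROI has {combined.n_voxels} voxels")
n_hit = len(set(combined.voxels) & set(range(70)))
print(f"{n_hit}/{combined.n_voxels} combined-ROI voxels are truly modulated")

# Each combination defines its sub-ROI from half the objects and measures
# on the other half, so no measurement reuses its defining samples.
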