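"""Simulate a grating run as raw MION time series and re-estimate the betas.

Builds one block-design run of the grating experiment, renders it as a
raw-polarity MION time series for a small voxel grid, fits the GLM and
compares the recovered condition responses with the planted patterns.
"""

import numpy as np

import memcolor as mc

truth = mc.plant_codes(27, "V4like", mc.GeneratorParams(noise_sd=0.0), seed=42)
design = mc.make_design("EXP1", run_index=1, seed=42)
print(f"run: {len(design.stimulus_blocks())} stimulus blocks, "
      f"{design.n_volumes} volumes at TR {design.tr} s")

ts, events = mc.simulate_timeseries(design, truth, grid_shape=(3, 3, 3), noise_sd=0.2)
X = mc.build_design_matrix(design)
fit = mc.fit_glm(ts, X, normalize=False)

for cond in mc.CHROMATIC:
    planted = mc.condition_signal(truth, "EXP1", cond)
    r = np.corrcoef(fit.beta(cond), planted)[0, 1]
    print(f"{cond:>7}: correlation(recovered beta, planted pattern) = {r:.3f}")

# The correlations are near 1: the sign-inverted GLM betas recover the
# planted voxel patterns from the raw (activation-decreasing) signal.
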