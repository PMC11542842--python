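# Methods

This note documents the models, parameters and numerical choices behind
`memcolor`.  Nothing here reports an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Experimental designs

All three simulated experiments use the same block grammar: 15 s
stimulus blocks alternating with 10 s neutral baseline blocks, runs
beginning and ending with a baseline, TR = 2.5 s, and every condition
appearing exactly three times per run in a pseudorandom order seeded by
`(seed, experiment, run)`.  Exp 1 has six grating conditions (red,
green, yellow; 25/50/75 % contrast achromatic), Exp 2 six grayscale
objects (strawberry, watermelon, cabbage, kiwi, banana, corn), Exp 3
eight true/false-colored object conditions (red and green categories
only).  The per-run repetition count for Exp 1 mirrors Exp 2's three
repeats; the default study size is 20 runs per experiment, split into 4
sessions whose first/second halves define the "period" factor used by
the familiarization analyses.

## The generator

`plant_codes` draws independent Gaussian-random unit axes per hue,
object identity and the true/false pattern.  Axes are deliberately *not*
orthogonalized: distinct codes in cortex are distinct, not orthogonal,
and nothing downstream requires orthogonality.

**Shape axes are correlated, not clustered.**  Each object gets its own
shape axis, and the six axes are drawn (via a Cholesky factor) with
pairwise correlations equal to the package's default shape-similarity
matrix.  Hard shape clusters would make the confound-excluded fold
logic degenerate — every comparison either tied or perfectly
anti-symmetric, so the shape confound would cancel instead of biasing
the unrestricted decoder.  The default similarity values encode the
qualitative structure of the stimulus set: high within-color similarity
(strawberry–watermelon 0.70, cabbage–kiwi 0.80), strawberry slightly
*more* similar in shape to cabbage (0.72) than to watermelon — the
counter-diagnostic case the fold logic exploits — kiwi closer to cabbage
(0.80) than to watermelon (0.45) in both color and shape, and the
elongated yellow objects (banana, corn: 0.80 together) distant (0.30)
from everything else.  These values were fixed once from a
normal-approximation analysis of the LDA score: the single
counter-diagnostic margin is small (0.02) so confound-excluded accuracy
sits near chance, while the aligned margins are large (0.15–0.35) so
the unrestricted decoder is reliably fooled by shape alone.

**Default effect sizes** (in units of the per-sample voxel noise
σ = 1): grating loading 1.0; memory-color transfer γ = 1.0 (transfer
decoding then lands around 0.43 vs. chance 1/3 at study scale,
comparable to in-vivo effect sizes); shape strength 2.0 (shape drives
ventral-stream patterns more strongly than memory color); identity and
true/false pattern strengths 1.0; true/false amplitude (0.3, 0.0) —
present in the first half of sessions, gone in the second, the
short-term familiarization signature.  No quantitative effect sizes
exist for these latent codes in vivo; the defaults are free parameters
of the artifact, chosen once and documented here.

Noise is i.i.d. Gaussian across voxels and samples.  Beta-level
simulation is the default path (decoding operates on GLM response
estimates); `simulate_timeseries` exists to exercise the GLM stage and
emits the *raw* MION polarity (signal decreases with activation).

## Response model

The MION impulse response is a unit-area gamma variate with shape 3 and
scale 3 s (mode 6 s, long tail) — the functional form is a package
constant because no analytic form is standard; all round trips use the
same kernel for simulation and fitting, so conclusions do not depend on
its exact shape.  Condition regressors are block boxcars convolved with
the kernel on a TR/10 grid; nuisance regressors are Legendre
polynomials of order 2 per run, with optional extra (motion) columns.
Estimation is per-voxel OLS per run — one sample per (condition, run),
the granularity leave-one-run-out schemes need — with betas sign-
inverted so positive means activation.  Percent-of-run-mean
normalization is available (and makes betas invariant to rescaling a
run); the exact round-trip checks run unnormalized so recovered betas
are in planted units.

## ROI procedures

Color patches: one-tailed suprathreshold clusters of the
chromatic-vs-achromatic t map (6-connectivity, t-weighted centers of
mass), a 3.5 mm sphere per cluster, top 50 voxels by t within sphere ∩
brain mask per hemisphere, left/right patches paired by nearest
mirrored centers and collapsed to 100 bilateral voxels.  The ranking
statistic is the contrast t; spheres smaller than 50 voxels keep
everything with a warning.  Hemisphere is the sign of world x.

True/false ROIs: four define/measure combinations (one exemplar per
color defines, the other is measured — never the same conditions), top
10 true-minus-false voxels per combination within the anatomical mask,
combined by taking the top 50 within a continuous mask formed from the
sub-ROI union plus every voxel 6-adjacent to two or more distinct
sub-ROIs (four top-10 sub-ROIs alone cannot supply 50 voxels; simple
morphological closing erodes thin ROIs away, so adjacency bridging is
used instead).  If fewer than 50 voxels survive, all survivors are used.

## Decoding

LDA with equal priors; pooled within-class covariance shrunk toward
`(tr(S)/p) I` with Ledoit–Wolf λ by default (ROIs have 100 voxels but
folds may train on fewer samples).  λ = 1 reduces exactly to nearest
class mean — the closed-form oracle the tests compare against.
Z-scoring is per voxel with statistics from the training samples only;
zero-variance voxels map to 0 and are flagged.  Transfer decoding
z-scores the grating and object experiments separately (their baselines
differ) and fits once on all grating runs, testing per object run.
Fold aggregation is the arithmetic mean of fold accuracies, which
equals pooled correct/total whenever fold sizes are equal.  Searchlight
neighborhoods are the 50 nearest in-mask voxels by world distance, ties
broken by grid order so results are storage-order invariant.

## Inference

Exact binomial tests (one-tailed for above-chance claims) serve the
searchlight, where per-sphere counts are compared against chance
descriptively and FDR-corrected.  For ROI-level decoding the package
uses run-level label-permutation tests instead: fold schemes that reuse
test samples across folds (exemplar splits) make pooled counts
overdispersed, and simulation during development showed the pooled
binomial to be badly anti-conservative there (null exemplar-split
accuracy has spread ≈0.11 where a binomial assumes ≈0.07).  Permuting
condition labels within runs — the run is the exchangeability unit —
yields calibrated p-values for every scheme (verified at type-I error
0.05 ± 0.02 in the suite).  The period × true/false interaction is the
difference of true-minus-false differences between session halves,
tested by permuting the period assignment of runs, two-tailed.  This
resampling machinery replaces a mixed-model formulation with
monkey/session/run random factors: it respects the same exchangeability
structure while being exactly calibrated and dependency-free.  FDR is
Benjamini–Hochberg per analysis across regions; `bh_fdr` accepts a
fixed family size larger than the supplied p-values for reproducing
fixed-layout ROI tables.  Cohen's d uses the pooled standard deviation.

## What the generator does and does not emulate

It reproduces the latent-code logic of the study — shared color axes
between gratings and object memory colors, a graded shape confound, an
identity code, and a period-dependent familiarity amplitude — with
run/session/period bookkeeping, so every fold scheme, ROI rule and test
can be exercised against ground truth.  It does **not** emulate spatial
autocorrelation (noise is white by default), physiological or motion
artifacts, inter-animal variability, session-level drifts in SNR, or
any retinotopic/eccentricity structure.  Passing tests therefore
demonstrate the *procedures* are correct and calibrated, not that the
in-vivo effect sizes would be recovered from real data.

## Problem sizes

The suite and the acceptance script run the chance-calibration study at
200 replicates × 20 runs × 100 voxels (the study's run count and ROI
size), planted-recovery checks at 10–40 replicates, and the GLM
round-trip at 200 noise replicates on a small grid — sizes chosen to
give stable Monte-Carlo bands while keeping a full run in the
single-digit minutes on one CPU.

## Known limitations

Confound-excluded accuracy is computed over few kept cases (the default
similarity matrix keeps one exemplar in one fold), so its per-dataset
value is coarse; analyses aggregate over replicate datasets.  With 100
voxels the realized correlations of planted axes fluctuate (sd ≈ 0.1)
around their targets, which overdisperses per-dataset accuracies —
Monte-Carlo bands over replicates, not binomial bands, are the correct
reference for generator-level checks.  The equiluminant-grayscale step
re-centers L* by a shift (preserving the original SD); out-of-gamut
colors clip on back-conversion, so hue-swap round trips are exact only
up to clipping.  Procrustes alignment includes uniform scaling by
default (boundary extraction scale is arbitrary); pass `scaling=False`
to keep size differences.
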