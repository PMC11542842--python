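"""Region-of-interest definition: color patches and true/false ROIs.

Color patches are suprathreshold clusters of the chromatic-vs-achromatic
contrast: a 3.5-mm sphere is placed at each cluster's t-weighted center
of mass, the 50 most color-biased voxels inside the sphere are kept per
hemisphere, and matching left/right patches are collapsed into one
bilateral 100-voxel region.  True/false ROIs avoid double dipping by
splitting the stimulus set into four define/measure combinations (top 10
voxels each within an anatomical mask) that are then combined into a top
50-voxel region.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats as sps

from .glm import contrast_map
from .patterns import PatternMatrix

log = logging.getLogger("memcolor")


@dataclass
class ROI:
    """A named voxel set (linear indices into the grid)."""

    name: str
    hemisphere: str  # left / right / bilateral
    voxels: np.ndarray
    center: tuple[float, float, float]
    ranking_stat: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.unique(np.asarray(self.voxels, dtype=int))
        if self.voxels.size == 0:
            raise ValueError("ROI voxel set is empty")
        if self.hemisphere not in ("left", "right", "bilateral"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.size)


def select_equiluminant_pair(
    mt_responses: dict[str, float],
    v1_chromatic: dict[str, float],
    v1_achromatic: dict[str, float],
) -> tuple[str, str]:
    """Pick the most equiluminant chromatic grating and its achromatic match.

    The chromatic condition evoking the weakest motion-area (MT) response
    is the most subjectively equiluminant one; the achromatic condition
    whose V1 response is closest to that grating's V1 response matches it
    in effective contrast.  Ties resolve in fixed label order
    (red < green < yellow; 25 < 50 < 75 % contrast) with a logged warning.
    """
    chrom_order = ("red", "green", "yellow")
    ach_order = ("ach25", "ach50", "ach75")
    for cond in chrom_order:
        if cond not in mt_responses or cond not in v1_chromatic:
            raise ValueError(f"missing chromatic condition {cond!r}")
    for cond in ach_order:
        if cond not in v1_achromatic:
            raise ValueError(f"missing achromatic condition {cond!r}")

    mt = [mt_responses[c] for c in chrom_order]
    best = int(np.argmin(mt))
    if mt.count(min(mt)) > 1:
        log.warning("MT response tie; choosing %r by label order", chrom_order[best])
    chromatic = chrom_order[best]

    target = v1_chromatic[chromatic]
    gaps = [abs(v1_achromatic[c] - target) for c in ach_order]
    besta = int(np.argmin(gaps))
    if gaps.count(min(gaps)) > 1:
        log.warning("V1 match tie; choosing %r by label order", ach_order[besta])
    return chromatic, ach_order[besta]


def top_n_voxels(
    stat_map: np.ndarray, mask: np.ndarray, n: int, name: str = "top_n"
) -> np.ndarray:
    """Deterministic top-``n`` in-mask voxels by statistic.

    Ties break by linear grid index, so the result does not depend on
    voxel storage order.  A mask smaller than ``n`` returns the whole
    mask with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    stat = np.asarray(stat_map, dtype=float).ravel()
    idx = np.flatnonzero(np.asarray(mask).ravel())
    if idx.size <= n:
        if idx.size < n:
            log.warning("%s: mask has only %d voxels (< %d); keeping all", name, idx.size, n)
        return np.sort(idx)
    order = np.lexsort((idx, -stat[idx]))
    return np.sort(idx[order[:n]])


def _cluster_centers(tmap: np.ndarray, supra: np.ndarray) -> list[np.ndarray]:
    """t-weighted center of mass of each 6-connected suprathreshold cluster."""
    structure = ndi.generate_binary_structure(3, 1)
    labels, n = ndi.label(supra, structure=structure)
    centers = []
    for lab in range(1, n + 1):
        ijk = np.argwhere(labels == lab)
        w = tmap[tuple(ijk.T)]
        w = np.clip(w, 0, None)
        if w.sum() <= 0:
            w = np.ones(len(ijk))
        centers.append((ijk * w[:, None]).sum(axis=0) / w.sum())
    return centers


def define_color_patches(
    tmap: np.ndarray,
    voxel_table: pd.DataFrame,
    threshold_p: float = 0.05,
    dof: int | None = None,
    threshold_t: float | None = None,
    brain_mask: np.ndarray | None = None,
    radius_mm: float = 3.5,
    top_n_per_hemi: int = 50,
) -> list[ROI]:
    """Color-bias patches from a 3-D chromatic-vs-achromatic t map.

    Suprathreshold voxels (one-tailed p < ``threshold_p`` at ``dof``
    degrees of freedom, or an explicit ``threshold_t``) are clustered
    with 6-connectivity; a ``radius_mm`` sphere around each cluster's
    center of mass is intersected with the brain mask and the
    ``top_n_per_hemi`` most color-biased voxels are kept.  Left/right
    patches whose centers mirror each other are collapsed into bilateral
    patches.  An empty suprathreshold map returns an empty list.
    """
    tmap = np.asarray(tmap, dtype=float)
    if tmap.ndim != 3:
        raise ValueError("tmap must be 3-D")
    if threshold_t is None:
        if dof is None:
            raise ValueError("give either threshold_t or dof for the p threshold")
        threshold_t = sps.t.isf(threshold_p, dof)
    if brain_mask is None:
        brain_mask = np.ones_like(tmap, dtype=bool)
    supra = (tmap > threshold_t) & brain_mask
    if not supra.any():
        return []

    coords = voxel_table[["x", "y", "z"]].to_numpy().reshape(*tmap.shape, 3)
    flat_t = tmap.ravel()
    patches: list[ROI] = []
    for ci, center_ijk in enumerate(_cluster_centers(tmap, supra)):
        # nearest-voxel world position of the fractional center of mass
        cidx = np.clip(np.round(center_ijk).astype(int), 0, np.array(tmap.shape) - 1)
        center_xyz = coords[tuple(cidx)]
        d = np.linalg.norm(coords - center_xyz, axis=-1)
        sphere = (d <= radius_mm) & brain_mask
        n_in = int(sphere.sum())
        if n_in < top_n_per_hemi:
            log.warning(
                "patch %d: sphere holds %d voxels (< %d); keeping all",
                ci, n_in, top_n_per_hemi,
            )
        vox = top_n_voxels(flat_t, sphere.ravel(), min(top_n_per_hemi, max(n_in, 1)),
                           name=f"patch{ci}")
        hemi = "left" if center_xyz[0] < 0 else "right"
        patches.append(
            ROI(f"patch{ci}_{hemi}", hemi, vox, tuple(np.round(center_xyz, 3)))
        )

    return _collapse_bilateral(patches)


def _collapse_bilateral(patches: list[ROI]) -> list[ROI]:
    """Pair left/right patches by nearest mirrored centers and merge them."""
    left = [p for p in patches if p.hemisphere == "left"]
    right = [p for p in patches if p.hemisphere == "right"]
    used_right: set[int] = set()
    merged: list[ROI] = []
    for li, lp in enumerate(left):
        mirrored = np.array([-lp.center[0], lp.center[1], lp.center[2]])
        best, best_d = None, np.inf
        for ri, rp in enumerate(right):
            if ri in used_right:
                continue
            d = np.linalg.norm(mirrored - np.array(rp.center))
            if d < best_d:
                best, best_d = ri, d
        if best is None:
            merged.append(lp)
            continue
        used_right.add(best)
        rp = right[best]
        center = tuple(np.round((np.array(lp.center) + np.array(rp.center)) / 2, 3))
        merged.append(
            ROI(f"patch{len(merged)}_bilateral", "bilateral",
                np.concatenate([lp.voxels, rp.voxels]), center)
        )
    merged.extend(rp for ri, rp in enumerate(right) if ri not in used_right)
    return merged


# --------------------------------------------------------------------------
# true/false ROIs (anti-double-dipping combinations)


@dataclass(frozen=True)
class CombinationScheme:
    """Disjoint condition subsets for ROI definition vs measurement."""

    define_conditions: tuple[str, ...]
    test_conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.define_conditions) & set(self.test_conditions):
            raise ValueError("define and test conditions overlap (double dipping)")


def enumerate_combinations(categories: dict[str, list[str]]) -> list[CombinationScheme]:
    """The four define/measure splits of the 2-color x 2-exemplar layout.

    One exemplar per color (true and false variants) defines the ROI;
    the left-out exemplars' conditions are measured.  Deterministic order.
    """
    colors = sorted(categories)
    if len(colors) != 2 or any(len(categories[c]) != 2 for c in colors):
        raise ValueError("layout must be exactly 2 colors x 2 exemplars")
    schemes = []
    for choice in itertools.product((0, 1), repeat=2):
        define_objs = [categories[c][i] for c, i in zip(colors, choice)]
        test_objs = [categories[c][1 - i] for c, i in zip(colors, choice)]
        schemes.append(
            CombinationScheme(
                tuple(f"{o}_{tf}" for o in define_objs for tf in ("true", "false")),
                tuple(f"{o}_{tf}" for o in test_objs for tf in ("true", "false")),
            )
        )
    return schemes


def truefalse_contrast_t(pattern: PatternMatrix, conditions: tuple[str, ...]) -> np.ndarray:
    """Across-run true-minus-false t per voxel, using the given conditions."""
    true_conds = [c for c in conditions if c.endswith("_true")]
    false_conds = [c for c in conditions if c.endswith("_false")]
    if not true_conds or not false_conds:
        raise ValueError("need both true and false conditions")
    weights = {c: 1.0 / len(true_conds) for c in true_conds}
    weights.update({c: -1.0 / len(false_conds) for c in false_conds})
    _, t = contrast_map(pattern, weights)
    return t


def define_truefalse_roi(
    pattern: PatternMatrix,
    anatomical_mask: np.ndarray,
    scheme: CombinationScheme,
    top_n: int = 10,
) -> ROI:
    """Sub-ROI of one combination: top true-false voxels in the mask.

    Ranks by the true-minus-false t computed from the scheme's *define*
    conditions only; the returned ROI carries the ranking map so
    sub-ROIs can later be combined.
    """
    mask = np.asarray(anatomical_mask).ravel().astype(bool)
    if not mask.any():
        raise ValueError("anatomical mask is empty")
    present = set(pattern.samples["condition"])
    missing = set(scheme.define_conditions) - present
    if missing:
        raise ValueError(f"define conditions missing from pattern: {sorted(missing)}")
    t = truefalse_contrast_t(pattern, scheme.define_conditions)
    vox = top_n_voxels(t, mask, top_n, name="truefalse_subroi")
    name = "tf_" + "+".join(sorted(scheme.define_conditions))
    return ROI(name, "bilateral", vox, (0.0, 0.0, 0.0), ranking_stat=t)


def combine_subrois(
    subrois: list[ROI],
    top_n_combined: int = 50,
    grid_shape: tuple[int, int, int] | None = None,
) -> ROI:
    """Collapse combination sub-ROIs and keep the top true-false voxels.

    The sub-ROI union is turned into a continuous combined mask — with
    ``grid_shape`` given, every voxel 6-adjacent to two or more distinct
    sub-ROIs is added as a bridge (four top-10 sub-ROIs alone can never
    supply 50 voxels); otherwise the plain union is used.  Voxels are
    ranked by their mean ranking statistic across combinations; if fewer
    than ``top_n_combined`` survive, all of them are used (warning).
    """
    if not subrois:
        raise ValueError("no sub-ROIs to combine")
    union = np.unique(np.concatenate([r.voxels for r in subrois]))
    stats = [r.ranking_stat for r in subrois if r.ranking_stat is not None]
    if not stats:
        raise ValueError("sub-ROIs carry no ranking statistic")
    mean_stat = np.mean(np.vstack(stats), axis=0)
    mask = np.zeros(mean_stat.size, dtype=bool)
    mask[union] = True
    if grid_shape is not None:
        structure = ndi.generate_binary_structure(3, 1)
        touch_count = np.zeros(grid_shape, dtype=int)
        for roi in subrois:
            sub = np.zeros(mean_stat.size, dtype=bool)
            sub[roi.voxels] = True
            touch_count += ndi.binary_dilation(
                sub.reshape(grid_shape), structure=structure
            )
        mask |= (touch_count >= 2).ravel()
    vox = top_n_voxels(mean_stat, mask, top_n_combined, name="truefalse_combined")
    return ROI("tf_combined", "bilateral", vox, (0.0, 0.0, 0.0), ranking_stat=mean_stat)


def roi_condition_means(
    pattern: PatternMatrix, roi: ROI, conditions: list[str]
) -> pd.DataFrame:
    """Run-resolved ROI-mean responses for the given conditions.

    One row per (condition, run) with the ROI-averaged response — the
    measurement side of a combination scheme (pass its test conditions
    to honor the double-dipping guard).
    """
    sub = pattern.select(condition=conditions)
    means = sub.values[:, roi.voxels].mean(axis=1)
    out = sub.samples.copy()
    out["roi_mean"] = means
    return out
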