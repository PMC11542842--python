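"""ROI procedures: equiluminant pair, top-N selection, patches, combinations."""

import logging

import numpy as np
import pandas as pd
import pytest

import memcolor as mc
from tests.conftest import build_pattern


def test_equiluminant_pair_selection():
    chrom, ach = mc.select_equiluminant_pair(
        {"red": 1.2, "green": 0.4, "yellow": 0.9},
        {"red": 2.5, "green": 2.0, "yellow": 2.2},
        {"ach25": 1.1, "ach50": 1.9, "ach75": 2.8},
    )
    assert (chrom, ach) == ("green", "ach50")
    with pytest.raises(ValueError, match="missing"):
        mc.select_equiluminant_pair({"red": 1.0}, {"red": 1.0}, {"ach25": 1.0})


def test_equiluminant_tie_breaks_by_label_order(caplog):
    with caplog.at_level(logging.WARNING, logger="memcolor"):
        chrom, _ = mc.select_equiluminant_pair(
            {"red": 0.5, "green": 0.5, "yellow": 0.9},
            {"red": 2.0, "green": 2.0, "yellow": 2.0},
            {"ach25": 1.0, "ach50": 2.0, "ach75": 3.0},
        )
    assert chrom == "red"
    assert any("tie" in r.message for r in caplog.records)


def test_top_n_voxels_oracle_and_invariances():
    rng = np.random.default_rng(1)
    for _ in range(20):
        stat = rng.standard_normal(60)
        mask = rng.random(60) < 0.7
        n = int(rng.integers(1, mask.sum() + 1))
        got = mc.top_n_voxels(stat, mask, n)
        # full-sort oracle: stable sort on (-stat, index) within the mask
        idx = np.flatnonzero(mask)
        oracle = idx[np.lexsort((idx, -stat[idx]))][:n]
        assert set(got) == set(oracle)
        kept, dropped = set(got), set(idx) - set(got)
        if dropped:
            assert min(stat[list(kept)]) >= max(stat[list(dropped)]) - 1e-12
    assert set(mc.top_n_voxels(stat, mask, int(mask.sum()))) == set(np.flatnonzero(mask))


def test_top_n_small_mask_warns(caplog):
    with caplog.at_level(logging.WARNING, logger="memcolor"):
        got = mc.top_n_voxels(np.arange(10.0), np.arange(10) < 3, n=5)
    assert set(got) == {0, 1, 2}
    assert any("keeping all" in r.message for r in caplog.records)


def _two_cluster_tmap(shape=(22, 14, 14)):
    rng = np.random.default_rng(0)
    t = np.zeros(shape)
    t[3:8, 4:9, 4:9] = 5 + rng.random((5, 5, 5))    # 125 voxels, left (x < 0)
    t[14:19, 4:9, 4:9] = 5 + rng.random((5, 5, 5))  # 125 voxels, right
    return t


def test_color_patch_geometry_and_ranking():
    from memcolor.roi import _cluster_centers

    shape = (22, 14, 14)
    t = _two_cluster_tmap(shape)
    vt = mc.default_voxel_table(shape)
    rois = mc.define_color_patches(t, vt, threshold_t=2.0)
    assert len(rois) == 1
    roi = rois[0]
    assert roi.hemisphere == "bilateral"
    assert roi.n_voxels == 100  # 50 per hemisphere, collapsed
    flat = t.ravel()
    assert (flat[roi.voxels] > 2.0).all()
    # every kept voxel beats every discarded voxel inside the same sphere
    coords = vt[["x", "y", "z"]].to_numpy().reshape(*shape, 3)
    for center_ijk in _cluster_centers(t, t > 2.0):
        cidx = np.round(center_ijk).astype(int)
        center_xyz = coords[tuple(cidx)]
        d = np.linalg.norm(coords.reshape(-1, 3) - center_xyz, axis=1)
        sphere = np.flatnonzero(d <= 3.5)
        kept = np.intersect1d(sphere, roi.voxels)
        discarded = np.setdiff1d(sphere, roi.voxels)
        assert len(kept) == 50
        assert flat[kept].min() >= flat[discarded].max() - 1e-12


def test_color_patch_empty_threshold():
    shape = (10, 8, 8)
    vt = mc.default_voxel_table(shape)
    assert mc.define_color_patches(np.zeros(shape), vt, threshold_t=2.0) == []


def test_enumerate_combinations():
    cats = {"red": ["strawberry", "watermelon"], "green": ["cabbage", "kiwi"]}
    schemes = mc.enumerate_combinations(cats)
    assert len(schemes) == 4
    all_conds = {f"{o}_{tf}" for o in sum(cats.values(), []) for tf in ("true", "false")}
    for s in schemes:
        assert not set(s.define_conditions) & set(s.test_conditions)
        assert set(s.define_conditions) | set(s.test_conditions) == all_conds
    with pytest.raises(ValueError):
        mc.enumerate_combinations({"red": ["strawberry"], "green": ["kiwi", "cabbage"]})


def _planted_truefalse_pattern(n_vox=30, n_mod=10, delta=1.0, noise=0.1, n_runs=8, seed=0):
    """Patterns where only the first ``n_mod`` voxels carry a true>false effect."""
    rng = np.random.default_rng(seed)
    conds = [f"{o}_{tf}" for o in ("strawberry", "watermelon", "cabbage", "kiwi")
             for tf in ("true", "false")]
    values = rng.normal(0, noise, size=(n_runs * len(conds), n_vox))
    is_true = np.array([c.endswith("_true") for c in conds * n_runs])
    values[np.ix_(is_true, np.arange(n_mod))] += delta
    return build_pattern(values, conds, experiment="EXP3", n_runs=n_runs), n_mod


def test_truefalse_subroi_recovers_modulated_voxels():
    pattern, n_mod = _planted_truefalse_pattern()
    scheme = mc.enumerate_combinations(
        {"red": ["strawberry", "watermelon"], "green": ["cabbage", "kiwi"]}
    )[0]
    mask = np.ones(pattern.n_voxels, dtype=bool)
    roi = mc.define_truefalse_roi(pattern, mask, scheme, top_n=10)
    recall = len(set(roi.voxels) & set(range(n_mod))) / n_mod
    assert recall >= 0.9


def test_truefalse_roi_small_mask_and_combination():
    pattern, _ = _planted_truefalse_pattern()
    schemes = mc.enumerate_combinations(
        {"red": ["strawberry", "watermelon"], "green": ["cabbage", "kiwi"]}
    )
    small_mask = np.zeros(pattern.n_voxels, dtype=bool)
    small_mask[:7] = True
    roi = mc.define_truefalse_roi(pattern, small_mask, schemes[0], top_n=10)
    assert roi.n_voxels == 7
    subrois = [
        mc.define_truefalse_roi(pattern, np.ones(pattern.n_voxels, bool), s, top_n=10)
        for s in schemes
    ]
    combined = mc.combine_subrois(subrois, top_n_combined=50)
    union = set(np.concatenate([r.voxels for r in subrois]))
    assert set(combined.voxels) <= union
    assert combined.n_voxels == min(50, len(union))
    with pytest.raises(ValueError, match="mask"):
        mc.define_truefalse_roi(pattern, np.zeros(pattern.n_voxels, bool), schemes[0])


def test_combined_mask_bridges_adjacent_subrois():
    """Bridging makes the combined mask continuous.

    Two sub-ROIs flanking a one-voxel gap: the gap voxel touches both,
    so the combined selection can exceed the plain union.
    """
    shape = (7, 3, 3)
    n = int(np.prod(shape))
    stat = np.zeros(n)
    grid = np.arange(n).reshape(shape)
    left = grid[1:3, 1, 1].ravel()
    right = grid[4:6, 1, 1].ravel()
    gap = grid[3, 1, 1]
    stat[np.concatenate([left, right])] = 2.0
    stat[gap] = 1.0
    a = mc.ROI("a", "bilateral", left, (0, 0, 0), ranking_stat=stat)
    b = mc.ROI("b", "bilateral", right, (0, 0, 0), ranking_stat=stat)
    merged = mc.combine_subrois([a, b], top_n_combined=5, grid_shape=shape)
    assert gap in merged.voxels
    plain = mc.combine_subrois([a, b], top_n_combined=5)
    assert gap not in plain.voxels


def test_measurement_never_uses_define_conditions():
    """The double-dipping guard: measured samples exclude defining conditions."""
    pattern, _ = _planted_truefalse_pattern()
    scheme = mc.enumerate_combinations(
        {"red": ["strawberry", "watermelon"], "green": ["cabbage", "kiwi"]}
    )[0]
    roi = mc.define_truefalse_roi(pattern, np.ones(pattern.n_voxels, bool), scheme)
    measured = mc.roi_condition_means(pattern, roi, list(scheme.test_conditions))
    assert set(measured["condition"]) == set(scheme.test_conditions)
    assert not set(measured["condition"]) & set(scheme.define_conditions)
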