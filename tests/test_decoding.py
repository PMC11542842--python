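"""Fold schemes, transfer decoding, confound exclusion and searchlight."""

import numpy as np
import pytest

import memcolor as mc
from memcolor.pipeline import RED_GREEN_CATEGORIES, TRUEFALSE_LABELS
from tests.conftest import build_pattern

THREE_CATEGORIES = {
    "red": ["strawberry", "watermelon"],
    "green": ["cabbage", "kiwi"],
    "yellow": ["banana", "corn"],
}


# ----------------------------------------------------------- fold enumeration


def test_exemplar_split_fold_counts():
    assert len(mc.exemplar_split_folds(THREE_CATEGORIES).folds) == 8
    assert len(mc.exemplar_split_folds(RED_GREEN_CATEGORIES).folds) == 4
    with pytest.raises(ValueError, match="exactly 2"):
        mc.exemplar_split_folds({"red": ["strawberry"], "green": ["kiwi", "cabbage"]})


def test_each_exemplar_trains_in_half_the_folds():
    scheme = mc.exemplar_split_folds(THREE_CATEGORIES)
    for exemplars in THREE_CATEGORIES.values():
        for ex in exemplars:
            n_train = sum(ex in f.train_exemplars for f in scheme.folds)
            assert n_train == len(scheme.folds) // 2
    for f in scheme.folds:
        assert not set(f.train_exemplars) & set(f.test_exemplars)


# ------------------------------------------------------- confound exclusion


def test_confound_cases_match_the_counter_diagnostic_example():
    """Train cabbage+watermelon, test kiwi+strawberry: only strawberry kept.

    Strawberry is closer in shape to cabbage (the wrong color class) than
    to watermelon, so correct classification cannot be shape-driven; kiwi
    resembles cabbage in both color and shape and is excluded.
    """
    scheme = mc.exemplar_split_folds(RED_GREEN_CATEGORIES)
    marked = mc.confound_excluded_cases(scheme, mc.DEFAULT_SHAPE_SIMILARITY)
    fold = next(
        f for f in marked.folds
        if set(f.train_exemplars) == {"cabbage", "watermelon"}
    )
    assert "strawberry" in fold.kept_test
    assert "kiwi" not in fold.kept_test


def test_confound_cases_degenerate_and_layout_errors():
    import pandas as pd

    scheme = mc.exemplar_split_folds(RED_GREEN_CATEGORIES)
    flat = pd.DataFrame(
        np.ones((4, 4)),
        index=list(scheme.label_map), columns=list(scheme.label_map),
    )
    marked = mc.confound_excluded_cases(scheme, flat)
    assert all(len(f.kept_test) == 0 for f in marked.folds)
    with pytest.raises(ValueError, match="2-category"):
        mc.confound_excluded_cases(
            mc.exemplar_split_folds(THREE_CATEGORIES), mc.DEFAULT_SHAPE_SIMILARITY
        )


# ----------------------------------------------------------- leave-one-run-out


def test_loro_fold_count_and_separable_limit(small_designs):
    params = mc.GeneratorParams(noise_sd=1e-4)
    truth = mc.plant_codes(40, "TEOlike", params, seed=2)
    betas = mc.simulate_betas(small_designs, truth)
    exp3 = betas.select(experiment="EXP3")
    res = mc.leave_one_run_out(exp3, list(mc.CONDITIONS["EXP3"]), TRUEFALSE_LABELS)
    assert len(res.fold_names) == len(exp3.runs())
    assert res.accuracy == 1.0
    assert res.chance_level == 0.5
    with pytest.raises(ValueError, match="3 runs"):
        mc.leave_one_run_out(exp3.select(run=[1, 2]), list(mc.CONDITIONS["EXP3"]),
                             TRUEFALSE_LABELS)


def test_exemplar_split_separable_limit(small_designs):
    params = mc.GeneratorParams(gamma=5.0, shape_strength=0.0, noise_sd=1e-3)
    truth = mc.plant_codes(40, "V4like", params, seed=6)
    betas = mc.simulate_betas(small_designs, truth).select(experiment="EXP2")
    res = mc.run_exemplar_split(betas, mc.exemplar_split_folds(RED_GREEN_CATEGORIES))
    assert res.accuracy == 1.0


def test_aggregate_matches_pooled_counts_for_equal_folds(small_designs):
    truth = mc.plant_codes(30, "V4like", seed=14)
    betas = mc.simulate_betas(small_designs, truth).select(experiment="EXP2")
    res = mc.run_exemplar_split(betas, mc.exemplar_split_folds(RED_GREEN_CATEGORIES))
    assert len(set(res.fold_total)) == 1
    assert res.accuracy == pytest.approx(res.correct / res.total, abs=1e-12)


# ------------------------------------------------------------------ transfer


def test_transfer_separable_limit_and_negative_control(small_designs):
    params = mc.GeneratorParams(gamma=5.0, shape_strength=0.0, noise_sd=1e-3)
    truth = mc.plant_codes(40, "V4like", params, seed=4)
    betas = mc.simulate_betas(small_designs, truth)
    res = mc.transfer_decode(
        betas.select(experiment="EXP1"), betas.select(experiment="EXP2")
    )
    assert res.accuracy == 1.0
    assert res.chance_level == pytest.approx(1 / 3)
    # shuffling the memory-color map destroys the transfer
    shuffled = {
        "strawberry": "green", "watermelon": "yellow", "cabbage": "red",
        "kiwi": "yellow", "banana": "green", "corn": "red",
    }
    res_bad = mc.transfer_decode(
        betas.select(experiment="EXP1"), betas.select(experiment="EXP2"), shuffled
    )
    assert res_bad.accuracy < 0.5


def test_transfer_voxel_mismatch_rejected(small_designs):
    truth = mc.plant_codes(30, "V4like", seed=4)
    betas = mc.simulate_betas(small_designs, truth)
    with pytest.raises(ValueError, match="voxel"):
        mc.transfer_decode(
            betas.select(experiment="EXP1").take_voxels(np.arange(10)),
            betas.select(experiment="EXP2"),
        )


# ---------------------------------------------------------------- searchlight


def test_searchlight_neighborhood_sizes_and_order_invariance():
    vt = mc.default_voxel_table((6, 6, 6))
    coords = vt[["x", "y", "z"]].to_numpy()
    nbrs = mc.searchlight_neighborhoods(coords, sphere_n=50)
    assert all(len(n) == 50 for n in nbrs)
    # permuting storage order selects the same world coordinates
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(coords))
    nbrs_p = mc.searchlight_neighborhoods(coords[perm], sphere_n=50)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    for v in (0, 100, 215):
        got = set(perm[nbrs_p[inv[v]]])
        assert got == set(nbrs[v])
    with pytest.raises(ValueError, match="fewer"):
        mc.searchlight_neighborhoods(coords[:30], sphere_n=50)


def test_searchlight_localizes_a_planted_blob():
    """Accuracy peaks inside the signal blob; far voxels stay near chance."""
    shape = (8, 6, 6)
    vt = mc.default_voxel_table(shape)
    n_vox = len(vt)
    rng = np.random.default_rng(3)
    n_runs, conds = 10, ["a", "b"]
    blob = np.flatnonzero(vt["i"] < 2)  # one end of the grid
    axis = np.zeros(n_vox)
    axis[blob] = rng.standard_normal(len(blob))
    axis /= np.linalg.norm(axis)
    values = rng.standard_normal((n_runs * 2, n_vox))
    sign = np.where(np.arange(n_runs * 2) % 2 == 0, 1.0, -1.0)
    values += 3.0 * sign[:, None] * axis[None, :]
    pattern = build_pattern(values, conds, n_runs=n_runs)
    pattern.voxels = vt
    run = lambda p: mc.leave_one_run_out(p, conds, shrinkage=1.0)
    res = mc.searchlight(pattern, run, sphere_n=20)
    acc = res.set_index("voxel")["accuracy"]
    far = np.flatnonzero(vt["i"] >= 6)
    assert acc.idxmax() in set(blob)  # the peak sits inside the blob
    assert acc.loc[blob].mean() > 0.75
    # centers far from the blob stay inside the pooled 99 % chance band
    far_total = int(res.loc[res.voxel.isin(far), "total"].sum())
    lo, hi = mc.binomial_chance_band(far_total, 0.5)
    assert lo <= acc.loc[far].mean() <= hi


def test_scheme_type_one_error_calibrated():
    """Label-permutation null of the leave-one-run-out scheme rejects at ~5 %.

    For each null dataset the decoding accuracy is compared with its own
    permutation distribution (condition labels shuffled within runs, the
    exchangeability unit); the rejection rate at alpha = 0.05 must be
    calibrated.  Replicates are reduced from the nominal 1,000 with a
    fixed seed to keep the run short.
    """
    rng = np.random.default_rng(0)
    n_runs, n_vox, n_perm, reps = 10, 6, 19, 400
    conds = ["a1", "a2", "b1", "b2", "c1", "c2"]
    lmap = {c: c[0] for c in conds}  # 3 classes, 60 test cases per dataset

    def accuracy(p):
        return mc.leave_one_run_out(p, conds, lmap, shrinkage=1.0).accuracy

    def permute(prng, p):
        values = p.values.copy()
        for run in p.runs():
            rows = np.flatnonzero((p.samples["run"] == run).to_numpy())
            values[rows] = values[prng.permutation(rows)]
        return mc.PatternMatrix(values, p.samples, p.voxels)

    hits = 0
    for rep in range(reps):
        values = rng.standard_normal((n_runs * len(conds), n_vox))
        pattern = build_pattern(values, conds, n_runs=n_runs)
        res = mc.permutation_test(
            accuracy, pattern, permute, n_perm=n_perm, seed=rep, tail="one"
        )
        hits += res.p <= 0.05
    assert 0.03 <= hits / reps <= 0.07
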