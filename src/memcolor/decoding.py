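"""Cross-validated pattern decoding with the study's fold schemes.

Four scheme families are implemented:

* leave-one-run-out (grating 3-way, true/false 2-way, identity 4-way);
* exemplar-split folds for grayscale objects: train on one exemplar per
  color category over all runs, test on the left-out exemplars per run
  (8 folds for 3 categories, 4 for 2);
* confound-excluded fold cases: within a 2-category exemplar split, keep
  only test exemplars whose shape similarity favors the *wrong* color
  class, so above-chance accuracy cannot be shape-driven;
* cross-experiment transfer: train a 3-way color classifier on all
  chromatic-grating runs, test per run on grayscale objects labeled by
  their memory color;

plus a whole-volume searchlight that slides any of these over
50-voxel nearest-neighbor spheres.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .designs import CHROMATIC, MEMORY_COLOR
from .lda import ShrinkageLDA, zscore_fit_apply
from .patterns import PatternMatrix

log = logging.getLogger("memcolor")


@dataclass
class DecodingResult:
    """Per-fold accuracies and their mean for one decoding analysis."""

    scheme: str
    chance_level: float
    fold_names: list[str]
    fold_correct: np.ndarray
    fold_total: np.ndarray

    def __post_init__(self) -> None:
        self.fold_correct = np.asarray(self.fold_correct, dtype=int)
        self.fold_total = np.asarray(self.fold_total, dtype=int)

    @property
    def fold_accuracies(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.fold_total > 0, self.fold_correct / self.fold_total, np.nan
            )

    @property
    def accuracy(self) -> float:
        """Mean over folds that produced at least one test case."""
        acc = self.fold_accuracies
        valid = ~np.isnan(acc)
        return float(acc[valid].mean()) if valid.any() else float("nan")

    @property
    def correct(self) -> int:
        return int(self.fold_correct.sum())

    @property
    def total(self) -> int:
        return int(self.fold_total.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": self.fold_names,
                "correct": self.fold_correct,
                "total": self.fold_total,
                "accuracy": self.fold_accuracies,
            }
        )


# --------------------------------------------------------------------------
# exemplar-split fold schemes


@dataclass(frozen=True)
class ExemplarFold:
    """One train/test assignment of exemplars to color categories."""

    train_exemplars: tuple[str, ...]  # one per category, category order fixed
    test_exemplars: tuple[str, ...]
    kept_test: frozenset[str] | None = None  # None = no confound restriction


@dataclass(frozen=True)
class FoldScheme:
    """Enumerated exemplar-split folds with their label map."""

    categories: tuple[str, ...]
    category_map: dict[str, tuple[str, ...]] = field(hash=False)
    folds: tuple[ExemplarFold, ...] = ()

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.categories)

    @property
    def label_map(self) -> dict[str, str]:
        return {
            ex: cat for cat, exemplars in self.category_map.items() for ex in exemplars
        }


def exemplar_split_folds(category_map: dict[str, list[str]]) -> FoldScheme:
    """All 2^k ways to train on one exemplar per category and test the rest.

    Requires exactly two exemplars per category; fold order is
    deterministic (categories sorted, binary choice enumerated in order).
    """
    categories = tuple(sorted(category_map))
    for cat in categories:
        if len(category_map[cat]) != 2:
            raise ValueError(f"category {cat!r} must have exactly 2 exemplars")
    folds = []
    for choice in itertools.product((0, 1), repeat=len(categories)):
        train = tuple(category_map[cat][c] for cat, c in zip(categories, choice))
        test = tuple(category_map[cat][1 - c] for cat, c in zip(categories, choice))
        folds.append(ExemplarFold(train, test))
    return FoldScheme(
        categories=categories,
        category_map={c: tuple(category_map[c]) for c in categories},
        folds=tuple(folds),
    )


def confound_excluded_cases(
    scheme: FoldScheme,
    shape_similarity: pd.DataFrame,
    category_map: dict[str, list[str]] | None = None,
) -> FoldScheme:
    """Mark, per fold, the test exemplars on which shape cannot help.

    A test exemplar is kept iff its shape similarity to the wrong-color
    training exemplar strictly exceeds its similarity to the same-color
    training exemplar — correct classification of a kept case therefore
    cannot be shape-driven.  Exemplars with equal similarities are
    dropped as uninformative.  Only 2-category schemes are supported.
    """
    if category_map is not None and tuple(sorted(category_map)) != scheme.categories:
        raise ValueError("category_map does not match the scheme")
    if len(scheme.categories) != 2:
        raise ValueError("confound-excluded cases are defined for 2-category schemes")
    label = scheme.label_map
    new_folds = []
    for fold in scheme.folds:
        kept = set()
        for test_ex in fold.test_exemplars:
            same = next(t for t in fold.train_exemplars if label[t] == label[test_ex])
            wrong = next(t for t in fold.train_exemplars if label[t] != label[test_ex])
            s_same = float(shape_similarity.loc[test_ex, same])
            s_wrong = float(shape_similarity.loc[test_ex, wrong])
            if s_wrong > s_same:
                kept.add(test_ex)
            elif s_wrong == s_same:
                log.warning(
                    "confound case %s: equal shape similarity to %s and %s; dropped",
                    test_ex, same, wrong,
                )
        if not kept:
            log.warning(
                "fold train=%s has no confound-excluded test case", fold.train_exemplars
            )
        new_folds.append(replace(fold, kept_test=frozenset(kept)))
    return replace(scheme, folds=tuple(new_folds))


def run_exemplar_split(
    pattern: PatternMatrix,
    scheme: FoldScheme,
    shrinkage: float | str = "auto",
    restrict_to_kept: bool = False,
) -> DecodingResult:
    """Execute an exemplar-split scheme on run-resolved patterns.

    Training uses all runs of the training exemplars; testing is per run
    of the left-out exemplars.  With ``restrict_to_kept`` only the
    confound-excluded cases contribute to the counts (folds without any
    kept case yield no test cases and are skipped in the aggregate).
    """
    label = scheme.label_map
    names, correct, total = [], [], []
    for fold in scheme.folds:
        train = pattern.select(condition=list(fold.train_exemplars))
        test_ex = fold.test_exemplars
        if restrict_to_kept:
            if fold.kept_test is None:
                raise ValueError("scheme has no confound-excluded case masks")
            test_ex = tuple(e for e in test_ex if e in fold.kept_test)
        names.append("train:" + "+".join(fold.train_exemplars))
        if not test_ex:
            correct.append(0)
            total.append(0)
            continue
        test = pattern.select(condition=list(test_ex))
        train_z, test_z, _ = zscore_fit_apply(train.values, test.values)
        clf = ShrinkageLDA(shrinkage).fit(
            train_z, [label[c] for c in train.samples["condition"]]
        )
        pred = clf.predict(test_z)
        truth = np.array([label[c] for c in test.samples["condition"]])
        correct.append(int((pred == truth).sum()))
        total.append(len(truth))
    kind = "exemplar_split_confound_excluded" if restrict_to_kept else "exemplar_split"
    return DecodingResult(
        scheme=f"{kind}_{len(scheme.categories)}way",
        chance_level=scheme.chance_level,
        fold_names=names,
        fold_correct=np.array(correct),
        fold_total=np.array(total),
    )


# --------------------------------------------------------------------------
# leave-one-run-out


def leave_one_run_out(
    pattern: PatternMatrix,
    conditions: list[str],
    label_map: dict[str, str] | None = None,
    shrinkage: float | str = "auto",
) -> DecodingResult:
    """One fold per run: train on the other runs, test on the left-out run.

    ``label_map`` collapses conditions to classes (e.g. the eight
    true/false conditions to the two classes true and false); by default
    each condition is its own class.  Z-scoring and the classifier are
    refit within every fold from the training runs only.
    """
    if label_map is None:
        label_map = {c: c for c in conditions}
    classes = sorted(set(label_map.values()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    data = pattern.select(condition=conditions)
    runs = data.runs()
    if len(runs) < 3:
        raise ValueError("leave-one-run-out needs at least 3 runs")

    values = data.values
    run_arr = data.samples["run"].to_numpy()
    cond_arr = data.samples["condition"].to_numpy()
    labels = np.array([label_map[c] for c in cond_arr])

    names, correct, total = [], [], []
    for run in runs:
        test_m = run_arr == run
        train_m = ~test_m
        usable = set(cond_arr[train_m]) & set(cond_arr[test_m])
        if usable != set(conditions):
            dropped = set(conditions) - usable
            log.warning("run %s: condition(s) %s missing; dropped from fold", run, dropped)
            keep = np.isin(cond_arr, list(usable))
            test_m = test_m & keep
            train_m = train_m & keep
        train_z, test_z, _ = zscore_fit_apply(values[train_m], values[test_m])
        clf = ShrinkageLDA(shrinkage).fit(train_z, labels[train_m])
        pred = clf.predict(test_z)
        names.append(f"leave_out_run{run}")
        correct.append(int((pred == labels[test_m]).sum()))
        total.append(int(test_m.sum()))
    return DecodingResult(
        scheme=f"leave_one_run_out_{len(classes)}way",
        chance_level=1.0 / len(classes),
        fold_names=names,
        fold_correct=np.array(correct),
        fold_total=np.array(total),
    )


# --------------------------------------------------------------------------
# cross-experiment transfer


def transfer_decode(
    train_pattern: PatternMatrix,
    test_pattern: PatternMatrix,
    memory_color_map: dict[str, str] | None = None,
    shrinkage: float | str = "auto",
) -> DecodingResult:
    """Grating-trained color decoding of grayscale objects.

    A single 3-way classifier is fit on the chromatic-grating samples of
    all training runs and tested on the object samples of each test run
    (one fold per run), labeled by the objects' memory colors.  Because
    response baselines differ between experiments, each experiment's
    samples are z-scored within the experiment before fit/test.
    """
    if memory_color_map is None:
        memory_color_map = MEMORY_COLOR
    if train_pattern.n_voxels != test_pattern.n_voxels:
        raise ValueError("train and test patterns use different voxel sets")
    train = train_pattern.select(condition=list(CHROMATIC))
    objects = sorted(set(test_pattern.samples["condition"]) & set(memory_color_map))
    if not objects:
        raise ValueError("no test condition appears in the memory color map")
    test = test_pattern.select(condition=objects)

    train_z, _, _ = zscore_fit_apply(train.values, train.values)
    test_z, _, _ = zscore_fit_apply(test.values, test.values)
    clf = ShrinkageLDA(shrinkage).fit(
        train_z, list(train.samples["condition"])
    )
    names, correct, total = [], [], []
    for run in test.runs():
        rows = np.flatnonzero((test.samples["run"] == run).to_numpy())
        pred = clf.predict(test_z[rows])
        truth = np.array(
            [memory_color_map[c] for c in test.samples["condition"].iloc[rows]]
        )
        names.append(f"test_run{run}")
        correct.append(int((pred == truth).sum()))
        total.append(len(truth))
    return DecodingResult(
        scheme="transfer_grating_to_object_3way",
        chance_level=1.0 / len(set(memory_color_map[o] for o in objects)),
        fold_names=names,
        fold_correct=np.array(correct),
        fold_total=np.array(total),
    )


def permute_conditions_within_runs(
    pattern: PatternMatrix,
    rng: np.random.Generator,
    conditions: list[str] | None = None,
) -> PatternMatrix:
    """One draw from the label-permutation null.

    Samples are exchanged among the given conditions *within each run*
    (the run is the exchangeability unit: under the null of no condition
    information, which response pattern got which label within a run is
    arbitrary, while run- and session-level structure is preserved).
    """
    values = pattern.values.copy()
    run_arr = pattern.samples["run"].to_numpy()
    cond_arr = pattern.samples["condition"].to_numpy()
    sel = (
        np.ones(len(run_arr), dtype=bool)
        if conditions is None
        else np.isin(cond_arr, list(conditions))
    )
    for run in np.unique(run_arr):
        rows = np.flatnonzero(sel & (run_arr == run))
        values[rows] = values[rng.permutation(rows)]
    return PatternMatrix(values, pattern.samples, pattern.voxels)


# --------------------------------------------------------------------------
# searchlight


def searchlight_neighborhoods(
    coords: np.ndarray, sphere_n: int = 50, mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """The ``sphere_n`` nearest in-mask voxels of every in-mask center.

    Distance ties are broken lexicographically on the world coordinates
    (the grid-index order), so the neighborhoods are independent of voxel
    storage order.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    candidates = np.arange(n) if mask is None else np.flatnonzero(np.asarray(mask))
    if len(candidates) < sphere_n:
        raise ValueError(
            f"mask has {len(candidates)} voxels, fewer than sphere_n={sphere_n}"
        )
    out = []
    sub = coords[candidates]
    for c in candidates:
        d = np.linalg.norm(sub - coords[c], axis=1)
        order = np.lexsort((sub[:, 2], sub[:, 1], sub[:, 0], d))
        out.append(candidates[order[:sphere_n]])
    return out


def searchlight(
    pattern: PatternMatrix,
    scheme_runner,
    sphere_n: int = 50,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run a decoding scheme in every voxel's 50-voxel neighborhood.

    ``scheme_runner`` maps a voxel-subset PatternMatrix to a
    DecodingResult (e.g. ``lambda p: leave_one_run_out(p, conds, lmap)``).
    Returns one row per center voxel with columns voxel (linear index),
    accuracy, correct and total — counts feed the binomial map test.
    """
    if pattern.voxels is None:
        raise ValueError("pattern has no voxel coordinates")
    coords = pattern.voxels[["x", "y", "z"]].to_numpy()
    neighborhoods = searchlight_neighborhoods(coords, sphere_n, mask)
    centers = np.arange(pattern.n_voxels) if mask is None else np.flatnonzero(mask)
    rows = []
    for center, nbr in zip(centers, neighborhoods):
        res = scheme_runner(pattern.take_voxels(nbr))
        rows.append(
            {
                "voxel": int(center),
                "accuracy": res.accuracy,
                "correct": res.correct,
                "total": res.total,
            }
        )
    return pd.DataFrame(rows)
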