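"""Synthetic voxel patterns and time series with planted, recoverable codes.

The generator emulates the latent structure the three experiments probe:

* a *color code* — one voxel-loading axis per hue (red, green, yellow)
  driven directly by chromatic gratings;
* a *memory-color transfer*: grayscale objects load their diagnostic
  color's axis with strength ``gamma``, the effect a grating-trained
  classifier can pick up;
* an *exemplar shape code*: each object loads its own shape axis; the
  axes are correlated across objects according to the package's default
  shape-similarity matrix, so shape can act as a graded confound exactly
  the way the confound-excluded fold logic assumes;
* an *object identity code* (one axis per true/false-experiment object);
* a *true/false effect*, either a uniform amplitude difference that can
  decay between session halves (temporal-pole-like familiarity) or a
  multivoxel pattern axis (TEO-like);

and i.i.d. Gaussian voxel noise on top.  Region profiles switch codes on
or off, mimicking a V4-like color patch, a TEO-like patch and a
temporal-pole-like familiarity region.  Every sample is tagged with run,
session and period so session-half analyses work downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import designs as dz
from .designs import (
    ACHROMATIC, CHROMATIC, EXP1, EXP2, EXP3, EXP3_OBJECTS, MEMORY_COLOR, OBJECTS,
    ExperimentDesign, assign_sessions, displayed_color, exp3_is_true, exp3_object,
)
from .glm import condition_regressors, mion_irf
from .patterns import PatternMatrix


@dataclass(frozen=True)
class RegionProfile:
    """Which latent codes a simulated region carries."""

    name: str
    includes_color_code: bool = False
    includes_transfer: bool = False
    includes_truefalse_pattern: bool = False
    includes_identity_pattern: bool = False
    includes_familiarity_amplitude: bool = False
    includes_shape_code: bool = True


PROFILES = {
    "V4like": RegionProfile("V4like", includes_color_code=True, includes_transfer=True),
    "TEOlike": RegionProfile(
        "TEOlike",
        includes_color_code=True,
        includes_transfer=True,
        includes_truefalse_pattern=True,
    ),
    "TPlike": RegionProfile(
        "TPlike",
        includes_identity_pattern=True,
        includes_familiarity_amplitude=True,
        includes_shape_code=False,
    ),
}


# Pairwise shape similarity of the six objects, used both to correlate the
# planted shape axes and as the default input to the confound-excluded fold
# logic.  Values encode the qualitative ordering of the stimulus set:
# within-category shapes are similar, strawberry is slightly *more* similar
# in shape to cabbage than to watermelon (the classic counter-diagnostic
# case), kiwi resembles cabbage more than watermelon, and the elongated
# yellow objects sit apart from everything else.
_SHAPE_SIM = np.array(
    [
        # straw  melon  cabb   kiwi   banana corn
        [1.00, 0.70, 0.72, 0.55, 0.30, 0.30],  # strawberry
        [0.70, 1.00, 0.50, 0.45, 0.30, 0.30],  # watermelon
        [0.72, 0.50, 1.00, 0.80, 0.30, 0.30],  # cabbage
        [0.55, 0.45, 0.80, 1.00, 0.30, 0.30],  # kiwi
        [0.30, 0.30, 0.30, 0.30, 1.00, 0.80],  # banana
        [0.30, 0.30, 0.30, 0.30, 0.80, 1.00],  # corn
    ]
)
DEFAULT_SHAPE_SIMILARITY = pd.DataFrame(_SHAPE_SIM, index=OBJECTS, columns=OBJECTS)


@dataclass(frozen=True)
class GeneratorParams:
    """Effect sizes of the planted codes, in beta units.

    gamma
        loading of a grayscale object on its memory-color axis.
    shape_strength
        loading of every object on its (correlated) shape axis; twice the
        transfer loading by default, reflecting that shape drives ventral
        visual patterns more strongly than memory color.
    grating_strength
        loading of a chromatic grating on its own color axis, and of a
        colored object on its displayed color's axis.
    truefalse_amplitude
        uniform response increment for true-colored objects in the first
        and second experiment halves; the default decays to zero in the
        second half (a short-term familiarization of the false stimuli).
    truefalse_pattern_strength
        antisymmetric loading (+/-) of true/false samples on the
        true-false pattern axis.
    identity_strength
        loading of each true/false-experiment object on its identity axis.
    noise_sd
        i.i.d. Gaussian voxel noise per sample.
    """

    gamma: float = 1.0
    shape_strength: float = 2.0
    grating_strength: float = 1.0
    truefalse_amplitude: tuple[float, float] = (0.3, 0.0)
    truefalse_pattern_strength: float = 1.0
    identity_strength: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        for name in ("gamma", "shape_strength", "grating_strength",
                     "truefalse_pattern_strength", "identity_strength", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def null(cls, noise_sd: float = 1.0) -> "GeneratorParams":
        """No planted effects: every decoder should sit at chance."""
        return cls(
            gamma=0.0,
            shape_strength=0.0,
            grating_strength=0.0,
            truefalse_amplitude=(0.0, 0.0),
            truefalse_pattern_strength=0.0,
            identity_strength=0.0,
            noise_sd=noise_sd,
        )


@dataclass
class GroundTruth:
    """Planted latent axes and effect magnitudes of one synthetic dataset."""

    n_voxels: int
    profile: RegionProfile
    params: GeneratorParams
    seed: int
    color_axes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    shape_axes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    identity_axes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    truefalse_axis: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_voxels": self.n_voxels,
            "profile": asdict(self.profile),
            "params": asdict(self.params),
            "seed": self.seed,
            "color_axes": {k: v.tolist() for k, v in self.color_axes.items()},
            "shape_axes": {k: v.tolist() for k, v in self.shape_axes.items()},
            "identity_axes": {k: v.tolist() for k, v in self.identity_axes.items()},
            "truefalse_axis": self.truefalse_axis.tolist(),
        }
        Path(path).write_text(json.dumps(doc))

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        params = doc["params"]
        params["truefalse_amplitude"] = tuple(params["truefalse_amplitude"])
        return GroundTruth(
            n_voxels=doc["n_voxels"],
            profile=RegionProfile(**doc["profile"]),
            params=GeneratorParams(**params),
            seed=doc["seed"],
            color_axes={k: np.array(v) for k, v in doc["color_axes"].items()},
            shape_axes={k: np.array(v) for k, v in doc["shape_axes"].items()},
            identity_axes={k: np.array(v) for k, v in doc["identity_axes"].items()},
            truefalse_axis=np.array(doc["truefalse_axis"]),
        )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def plant_codes(
    n_voxels: int,
    profile: RegionProfile | str,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw the latent axes of one synthetic region.

    Axes are independent Gaussian-random unit vectors (not orthogonalized),
    except the shape axes, which are drawn with pairwise correlations from
    :data:`DEFAULT_SHAPE_SIMILARITY` and then normalized.  Axes switched
    off by the region profile are zero vectors.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    if params is None:
        params = GeneratorParams()
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    zeros = np.zeros(n_voxels)
    color_axes = {}
    for color in CHROMATIC:
        axis = _unit(rng.standard_normal(n_voxels))
        color_axes[color] = axis if profile.includes_color_code else zeros.copy()

    chol = np.linalg.cholesky(_SHAPE_SIM)
    raw = chol @ rng.standard_normal((len(OBJECTS), n_voxels))
    shape_axes = {}
    for i, obj in enumerate(OBJECTS):
        axis = _unit(raw[i])
        shape_axes[obj] = axis if profile.includes_shape_code else zeros.copy()

    identity_axes = {}
    for obj in EXP3_OBJECTS:
        axis = _unit(rng.standard_normal(n_voxels))
        identity_axes[obj] = axis if profile.includes_identity_pattern else zeros.copy()

    tf_axis = _unit(rng.standard_normal(n_voxels))
    if not profile.includes_truefalse_pattern:
        tf_axis = zeros.copy()

    return GroundTruth(
        n_voxels=n_voxels,
        profile=profile,
        params=params,
        seed=int(seed),
        color_axes=color_axes,
        shape_axes=shape_axes,
        identity_axes=identity_axes,
        truefalse_axis=tf_axis,
    )


def condition_signal(
    truth: GroundTruth, experiment: str, condition: str, period: str = "first"
) -> np.ndarray:
    """Noise-free mean pattern of one condition (baseline excluded)."""
    p = truth.params
    prof = truth.profile
    sig = np.full(truth.n_voxels, p.baseline, dtype=float)
    if condition == dz.BASELINE:
        return sig
    if experiment == EXP1:
        if condition in CHROMATIC:
            sig += p.grating_strength * truth.color_axes[condition]
        elif condition not in ACHROMATIC:
            raise ValueError(f"unknown EXP1 condition {condition!r}")
        return sig
    if experiment == EXP2:
        if condition not in OBJECTS:
            raise ValueError(f"unknown EXP2 condition {condition!r}")
        if prof.includes_transfer:
            sig += p.gamma * truth.color_axes[MEMORY_COLOR[condition]]
        sig += p.shape_strength * truth.shape_axes[condition]
        return sig
    if experiment == EXP3:
        obj = exp3_object(condition)
        if obj not in EXP3_OBJECTS:
            raise ValueError(f"unknown EXP3 condition {condition!r}")
        shown = displayed_color(EXP3, condition)
        sig += p.grating_strength * truth.color_axes[shown]
        sig += p.shape_strength * truth.shape_axes[obj]
        sig += p.identity_strength * truth.identity_axes[obj]
        is_true = exp3_is_true(condition)
        if prof.includes_truefalse_pattern:
            s = 1.0 if is_true else -1.0
            sig += s * p.truefalse_pattern_strength * truth.truefalse_axis
        if prof.includes_familiarity_amplitude and is_true:
            delta = p.truefalse_amplitude[0 if period == "first" else 1]
            sig += delta
        return sig
    raise ValueError(f"unknown experiment {experiment!r}")


def simulate_betas(
    design_set: list[ExperimentDesign],
    truth: GroundTruth,
    profile: RegionProfile | None = None,
    n_sessions: int = 4,
    noise_seed: int | None = None,
) -> PatternMatrix:
    """One noisy sample per (condition, run) for every design in the set.

    Runs of each experiment are tagged with sessions (default 4, split
    2 / 2 into first and second periods).  The noise stream is derived
    from the truth's seed unless ``noise_seed`` is given, so a fixed
    (truth, designs) pair reproduces the data bit-identically.
    """
    if profile is not None and profile != truth.profile:
        raise ValueError("profile does not match the planted ground truth")
    if noise_seed is None:
        noise_seed = truth.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(noise_seed), 23]))

    by_exp: dict[str, list[ExperimentDesign]] = {}
    for d in design_set:
        by_exp.setdefault(d.experiment_id, []).append(d)

    values, meta = [], []
    for exp, exp_designs in by_exp.items():
        exp_designs = sorted(exp_designs, key=lambda d: d.run_index)
        sessions, periods = assign_sessions(len(exp_designs), n_sessions)
        for r, design in enumerate(exp_designs):
            present = sorted({b[0] for b in design.stimulus_blocks()})
            for cond in present:
                mean = condition_signal(truth, exp, cond, period=periods[r])
                noise = truth.params.noise_sd * rng.standard_normal(truth.n_voxels)
                values.append(mean + noise)
                meta.append(
                    {
                        "experiment": exp,
                        "condition": cond,
                        "run": design.run_index,
                        "session": int(sessions[r]),
                        "period": str(periods[r]),
                    }
                )
    return PatternMatrix(np.vstack(values), pd.DataFrame(meta))


def simulate_timeseries(
    design: ExperimentDesign,
    truth: GroundTruth,
    profile: RegionProfile | None = None,
    irf: np.ndarray | None = None,
    irf_dt: float | None = None,
    grid_shape: tuple[int, int, int] | None = None,
    baseline_level: float = 100.0,
    drift: np.ndarray | None = None,
    noise_sd: float = 0.0,
    period: str = "first",
    noise_seed: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw-polarity MION time series for one run plus its event table.

    Voxel time courses are the condition boxcars convolved with the MION
    kernel, weighted by each condition's planted pattern and *subtracted*
    from the baseline level: the raw agent signal decreases with
    activation, matching the sign convention :func:`memcolor.glm.fit_glm`
    inverts.  Returns a (n_volumes, n_voxels) array, reshaped to 4-D
    (x, y, z, t) when ``grid_shape`` is given, and a BIDS-style events
    table (onset, duration, condition).
    """
    if profile is not None and profile != truth.profile:
        raise ValueError("profile does not match the planted ground truth")
    if grid_shape is not None and int(np.prod(grid_shape)) != truth.n_voxels:
        raise ValueError("grid_shape does not match the number of voxels")
    regs, conds = condition_regressors(design, irf, irf_dt)
    patterns = np.vstack(
        [condition_signal(truth, design.experiment_id, c, period) for c in conds]
    )
    ts = np.full((design.n_volumes, truth.n_voxels), float(baseline_level))
    ts -= regs @ patterns
    if drift is not None:
        drift = np.asarray(drift, dtype=float)
        if drift.shape != (design.n_volumes,):
            raise ValueError("drift must have one value per volume")
        ts += drift[:, None]
    if noise_sd > 0:
        if noise_seed is None:
            noise_seed = truth.seed
        rng = np.random.default_rng(
            np.random.SeedSequence([int(noise_seed), 29, design.run_index])
        )
        ts = ts + noise_sd * rng.standard_normal(ts.shape)
    events = pd.DataFrame(
        [{"onset": on, "duration": dur, "condition": c} for c, on, dur in design.blocks]
    )
    if grid_shape is not None:
        ts = ts.T.reshape(*grid_shape, design.n_volumes)
    return ts, events


def make_design_set(
    experiments: tuple[str, ...] = (EXP1, EXP2, EXP3),
    n_runs: int = 20,
    seed: int = 0,
) -> list[ExperimentDesign]:
    """Default study layout: ``n_runs`` pseudorandom runs per experiment."""
    return [
        dz.make_design(exp, run, seed)
        for exp in experiments
        for run in range(1, n_runs + 1)
    ]
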