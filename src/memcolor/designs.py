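"""Block-design timing for the three experiments.

Exp 1 presents drifting chromatic (red, green, yellow) and achromatic
(25/50/75 % luminance contrast) gratings in 15 s blocks separated by 10 s
neutral-gray baseline blocks.  Exp 2 presents grayscale images of six
color-diagnostic fruits and vegetables (red: strawberry, watermelon;
green: cabbage, kiwi; yellow: banana, corn).  Exp 3 presents the red and
green objects in their natural hue ("true") and with the hues swapped
between color categories ("false"), eight conditions in total.  Every
stimulus block lasts 15 s, every baseline block 10 s, runs begin and end
with a baseline block, and each condition appears three times per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

TR = 2.5  # volume repetition time, seconds
STIM_BLOCK_S = 15.0
BASELINE_BLOCK_S = 10.0
REPS_PER_RUN = 3
BASELINE = "baseline"

EXP1 = "EXP1"
EXP2 = "EXP2"
EXP3 = "EXP3"
EXPERIMENTS = (EXP1, EXP2, EXP3)

CHROMATIC = ("red", "green", "yellow")
ACHROMATIC = ("ach25", "ach50", "ach75")

OBJECTS = ("strawberry", "watermelon", "cabbage", "kiwi", "banana", "corn")

#: diagnostic ("memory") color of each familiar object
MEMORY_COLOR = {
    "strawberry": "red",
    "watermelon": "red",
    "cabbage": "green",
    "kiwi": "green",
    "banana": "yellow",
    "corn": "yellow",
}

#: objects used in the true/false-color experiment (red and green categories only)
EXP3_OBJECTS = ("strawberry", "watermelon", "cabbage", "kiwi")

CONDITIONS = {
    EXP1: CHROMATIC + ACHROMATIC,
    EXP2: OBJECTS,
    EXP3: tuple(f"{o}_{tf}" for o in EXP3_OBJECTS for tf in ("true", "false")),
}

#: the four true-colored conditions used for object-identity decoding
IDENTITY_CONDITIONS = tuple(f"{o}_true" for o in EXP3_OBJECTS)

_EXP_CODE = {EXP1: 1, EXP2: 2, EXP3: 3}


def exp3_object(condition: str) -> str:
    """Object label of an Exp 3 condition (``'kiwi_false' -> 'kiwi'``)."""
    return condition.rsplit("_", 1)[0]


def exp3_is_true(condition: str) -> bool:
    return condition.endswith("_true")


def displayed_color(experiment: str, condition: str) -> str | None:
    """Physically displayed hue of a condition, or None if achromatic.

    Grating conditions display their own hue; grayscale objects display no
    hue; true-colored objects display their memory color and false-colored
    objects the color of the other category (red<->green swap).
    """
    if experiment == EXP1:
        return condition if condition in CHROMATIC else None
    if experiment == EXP2:
        return None
    obj = exp3_object(condition)
    color = MEMORY_COLOR[obj]
    if exp3_is_true(condition):
        return color
    return {"red": "green", "green": "red"}[color]


@dataclass
class ExperimentDesign:
    """Ordered block timing and scan geometry for one run."""

    experiment_id: str
    run_index: int
    tr: float
    n_volumes: int
    blocks: list[tuple[str, float, float]]  # (condition, onset s, duration s)
    baseline_label: str = BASELINE

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.experiment_id not in EXPERIMENTS:
            raise ValueError(f"unknown experiment_id {self.experiment_id!r}")
        if self.run_index < 1:
            raise ValueError("run_index must be a positive integer")
        if not self.blocks:
            raise ValueError("design has no blocks")
        prev_end = -np.inf
        for label, onset, dur in self.blocks:
            if onset < prev_end - 1e-9:
                raise ValueError("blocks overlap or are out of order")
            prev_end = onset + dur
        if self.blocks[0][0] != self.baseline_label or self.blocks[-1][0] != self.baseline_label:
            raise ValueError("runs must begin and end with a baseline block")

    @property
    def duration(self) -> float:
        label, onset, dur = self.blocks[-1]
        return onset + dur

    def stimulus_blocks(self) -> list[tuple[str, float, float]]:
        return [b for b in self.blocks if b[0] != self.baseline_label]

    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS[self.experiment_id]


def make_design(experiment_id: str, run_index: int, seed: int) -> ExperimentDesign:
    """Build the pseudorandom block sequence of one run.

    The condition order is drawn from a generator seeded by
    ``(seed, experiment, run_index)``, so the same triple always reproduces
    the same design while different runs get different orders.
    """
    if experiment_id not in EXPERIMENTS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")
    if run_index < 1:
        raise ValueError("run_index must be a positive integer")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), _EXP_CODE[experiment_id], int(run_index)])
    )
    sequence = list(CONDITIONS[experiment_id]) * REPS_PER_RUN
    order = rng.permutation(len(sequence))
    sequence = [sequence[i] for i in order]

    blocks: list[tuple[str, float, float]] = []
    t = 0.0
    blocks.append((BASELINE, t, BASELINE_BLOCK_S))
    t += BASELINE_BLOCK_S
    for cond in sequence:
        blocks.append((cond, t, STIM_BLOCK_S))
        t += STIM_BLOCK_S
        blocks.append((BASELINE, t, BASELINE_BLOCK_S))
        t += BASELINE_BLOCK_S
    n_volumes = math.ceil(t / TR)
    return ExperimentDesign(
        experiment_id=experiment_id,
        run_index=run_index,
        tr=TR,
        n_volumes=n_volumes,
        blocks=blocks,
    )


def assign_sessions(n_runs: int, n_sessions: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Tag runs 1..n with a session index and an experiment half.

    Runs are split as evenly as possible into sessions; the first half of
    sessions is the "first" period and the rest the "second" period (the
    session split used when probing short-term familiarization effects).
    Returns (session index array, period label array), both length n_runs.
    """
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions to define periods")
    bounds = np.linspace(0, n_runs, n_sessions + 1).round().astype(int)
    sessions = np.empty(n_runs, dtype=int)
    for s in range(n_sessions):
        sessions[bounds[s]:bounds[s + 1]] = s + 1
    periods = np.where(sessions <= n_sessions // 2, "first", "second")
    return sessions, periods
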