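"""Shared fixtures: small synthetic datasets built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import memcolor as mc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> mc.GeneratorParams:
    return mc.GeneratorParams()


@pytest.fixture(scope="session")
def small_designs():
    """Six runs of each experiment (enough for leave-one-run-out)."""
    return mc.make_design_set(n_runs=6, seed=11)


@pytest.fixture(scope="session")
def v4_pattern(small_designs):
    """Planted V4-like betas at the default SNR, 80 voxels, 6 runs."""
    truth = mc.plant_codes(80, "V4like", mc.GeneratorParams(), seed=11)
    return mc.simulate_betas(small_designs, truth), truth


def build_pattern(
    values: np.ndarray,
    conditions: list[str],
    experiment: str = "EXP2",
    n_runs: int | None = None,
) -> mc.PatternMatrix:
    """PatternMatrix from a (runs * conditions, voxels) array, row-major by run."""
    n_cond = len(conditions)
    if n_runs is None:
        n_runs = values.shape[0] // n_cond
    meta = pd.DataFrame(
        {
            "experiment": experiment,
            "condition": conditions * n_runs,
            "run": np.repeat(np.arange(1, n_runs + 1), n_cond),
            "session": 1,
            "period": "first",
        }
    )
    return mc.PatternMatrix(values, meta)
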