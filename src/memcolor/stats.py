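"""Significance machinery: exact binomial tests, permutations, FDR, effect sizes.

Decoding accuracies are compared with chance by exact binomial tests on
the pooled correct/total counts (one-tailed for above-chance claims).
Group-level amplitude questions — in particular whether the true-vs-false
response difference decays from the first to the second half of sessions —
are answered by run-level permutation tests, which respect the same
exchangeability structure a mixed model with run-level random effects
would.  Multiple ROIs are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("memcolor")


@dataclass
class StatResult:
    statistic: float
    p: float
    tail: str  # "one" | "two"
    n: int
    q: float | None = None
    effect_size: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")


def binomial_test_vs_chance(
    correct: int, total: int, chance: float, tail: str = "one"
) -> StatResult:
    """Exact binomial test of a decoding count against its chance level.

    One-tailed tests the above-chance direction (P[X >= correct]);
    two-tailed uses the exact two-sided binomial probability.
    """
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must be in (0, 1)")
    if tail == "one":
        p = float(sps.binom.sf(correct - 1, total, chance))
    elif tail == "two":
        p = float(sps.binomtest(correct, total, chance).pvalue)
    else:
        raise ValueError("tail must be 'one' or 'two'")
    return StatResult(statistic=correct / total if total else np.nan,
                      p=min(p, 1.0), tail=tail, n=total)


def binomial_chance_band(
    total: int, chance: float, level: float = 0.99
) -> tuple[float, float]:
    """Central two-sided accuracy band expected under chance performance."""
    alpha = (1.0 - level) / 2.0
    lo = sps.binom.ppf(alpha, total, chance) / total
    hi = sps.binom.ppf(1.0 - alpha, total, chance) / total
    return float(lo), float(hi)


def permutation_test(
    statistic,
    data,
    permute,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "two",
) -> StatResult:
    """Generic seeded permutation test.

    ``statistic(data)`` maps the data to a scalar; ``permute(rng, data)``
    returns one resampled dataset under the null (the caller declares the
    exchangeability unit there, e.g. shuffling run labels within session).
    p = (1 + #{perm >= observed}) / (1 + n_perm); the two-tailed variant
    compares absolute values.
    """
    if n_perm < 99:
        log.warning("n_perm=%d is very small; p-values are coarse", n_perm)
    rng = np.random.default_rng(seed)
    obs = float(statistic(data))
    null = np.array([float(statistic(permute(rng, data))) for _ in range(n_perm)])
    if tail == "one":
        hits = int((null >= obs).sum())
    elif tail == "two":
        hits = int((np.abs(null) >= abs(obs)).sum())
    else:
        raise ValueError("tail must be 'one' or 'two'")
    p = (1 + hits) / (1 + n_perm)
    return StatResult(statistic=obs, p=p, tail=tail, n=n_perm, seed=seed)


def interaction_period_truefalse(
    roi_means: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> StatResult:
    """Period x true/false interaction by permuting the period labels of runs.

    ``roi_means`` has one row per (run, condition) with columns ``run``,
    ``period`` ("first"/"second"), ``tf`` ("true"/"false") and
    ``roi_mean``.  The statistic is the first-half true-minus-false
    difference minus the second-half difference; its null distribution
    comes from reassigning whole runs to periods (two-tailed).
    """
    required = {"run", "period", "tf", "roi_mean"}
    if not required <= set(roi_means.columns):
        raise ValueError(f"roi_means must have columns {sorted(required)}")
    per_run = (
        roi_means.pivot_table(index=["run", "period"], columns="tf", values="roi_mean")
        .reset_index()
    )
    if not {"true", "false"} <= set(per_run.columns):
        raise ValueError("both true and false conditions must be present")
    diffs = (per_run["true"] - per_run["false"]).to_numpy()
    periods = per_run["period"].to_numpy()
    n_first = int((periods == "first").sum())
    n_second = int((periods == "second").sum())
    if n_first < 2 or n_second < 2:
        raise ValueError("each period needs at least 2 runs")

    def stat(d):
        return d[periods == "first"].mean() - d[periods == "second"].mean()

    obs = stat(diffs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    idx = np.arange(len(diffs))
    for i in range(n_perm):
        perm = rng.permutation(idx)
        first = perm[:n_first]
        mask = np.zeros(len(diffs), dtype=bool)
        mask[first] = True
        null[i] = diffs[mask].mean() - diffs[~mask].mean()
    hits = int((np.abs(null) >= abs(obs)).sum())
    p = (1 + hits) / (1 + n_perm)
    return StatResult(statistic=float(obs), p=p, tail="two",
                      n=len(diffs), seed=seed)


def bh_fdr(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``family_size`` can be larger than the number of supplied p-values
    (the remaining family members count as nonsignificant), matching the
    fixed family sizes used for the ROI tables (7 color patches, 2
    anterior-temporal ROIs).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < len(p):
        raise ValueError("family_size smaller than the number of p-values")
    padded = np.concatenate([p, np.ones(m - len(p))])
    _, q, _, _ = multipletests(padded, method="fdr_bh")
    return q[: len(p)]


def cohens_d(group_a, group_b) -> float:
    """Mean difference in pooled-standard-deviation units."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def stats_table(rows: list[dict]) -> pd.DataFrame:
    """Stack StatResult-shaped dicts into the standard output table."""
    cols = ["analysis", "roi", "statistic", "p", "q", "tail", "effect_size", "n", "seed"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]
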