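"""Per-condition response estimation for MION block-design time series.

The hemodynamic impulse response of the iron-oxide contrast agent (MION)
is slower and longer-tailed than BOLD and its raw signal *decreases* with
activation, so fitted betas are sign-inverted by default: a positive beta
always means more activation.  Condition regressors are block boxcars
convolved with a unit-area gamma-variate MION kernel; nuisance regressors
are Legendre drift polynomials (plus optional user columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import ExperimentDesign
from .patterns import PatternMatrix, default_voxel_table

# Gamma-variate MION impulse response: t^(k-1) exp(-t/theta).
# Shape 3 / scale 3 s puts the mode at (k-1)*theta = 6 s with a long tail,
# within the slow 5-8 s peak range expected for MION dynamics.
MION_SHAPE = 3.0
MION_SCALE_S = 3.0
MION_DEFAULT_DURATION_S = 40.0
_MIN_KERNEL_SUPPORT_S = 15.0

OVERSAMPLE = 10  # regressor construction time grid = TR / OVERSAMPLE


def mion_irf(dt: float, duration: float = MION_DEFAULT_DURATION_S) -> np.ndarray:
    """Sampled unit-area MION impulse response.

    Nonnegative gamma-variate sampled every ``dt`` seconds on
    [0, duration); normalized so that sum(kernel) * dt == 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < _MIN_KERNEL_SUPPORT_S:
        raise ValueError(
            f"duration {duration} s shorter than the kernel support "
            f"({_MIN_KERNEL_SUPPORT_S} s minimum)"
        )
    t = np.arange(0.0, duration, dt)
    with np.errstate(divide="ignore"):
        h = t ** (MION_SHAPE - 1.0) * np.exp(-t / MION_SCALE_S)
    h[~np.isfinite(h)] = 0.0
    area = h.sum() * dt
    return h / area


@dataclass
class DesignMatrix:
    """Labeled regressor matrix for one run."""

    values: np.ndarray  # (n_volumes, n_regressors)
    columns: list[str]
    condition_columns: list[str]
    tr: float

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column labels do not match matrix width")
        for c in self.condition_columns:
            j = self.columns.index(c)
            if not np.any(self.values[:, j]):
                raise ValueError(f"all-zero condition column {c!r}")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


def condition_regressors(
    design: ExperimentDesign, irf: np.ndarray | None = None, irf_dt: float | None = None
) -> tuple[np.ndarray, list[str]]:
    """Convolved boxcar regressor per non-baseline condition.

    Boxcars are built on a fine grid (TR / OVERSAMPLE), convolved with the
    kernel and sampled at volume-acquisition times.  The kernel must be
    sampled on the same fine grid; by default it is generated here.
    """
    dt = design.tr / OVERSAMPLE
    if irf is None:
        irf = mion_irf(dt)
        irf_dt = dt
    if irf_dt is None or abs(irf_dt - dt) > 1e-9:
        raise ValueError(
            f"kernel sampling interval {irf_dt} does not match the design grid {dt}"
        )
    conditions = [c for c in design.conditions()
                  if any(b[0] == c for b in design.blocks)]
    n_fine = int(round(design.n_volumes * design.tr / dt))
    t_fine = np.arange(n_fine) * dt
    cols = np.zeros((design.n_volumes, len(conditions)))
    vol_idx = (np.arange(design.n_volumes) * design.tr / dt).round().astype(int)
    for j, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        for label, onset, dur in design.blocks:
            if label == cond:
                box[(t_fine >= onset) & (t_fine < onset + dur)] = 1.0
        conv = np.convolve(box, irf)[:n_fine] * dt
        cols[:, j] = conv[vol_idx]
    return cols, conditions


def legendre_drift(n_volumes: int, order: int) -> np.ndarray:
    """Legendre polynomial drift regressors of degree 0..order on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    cols = [np.polynomial.legendre.Legendre.basis(d)(x) for d in range(order + 1)]
    return np.column_stack(cols)


def build_design_matrix(
    design: ExperimentDesign,
    irf: np.ndarray | None = None,
    irf_dt: float | None = None,
    drift_order: int = 2,
    extra: dict[str, np.ndarray] | None = None,
) -> DesignMatrix:
    """One convolved regressor per condition plus drift (and motion) columns."""
    cond_cols, cond_names = condition_regressors(design, irf, irf_dt)
    drift = legendre_drift(design.n_volumes, drift_order)
    drift_names = [f"drift{d}" for d in range(drift_order + 1)]
    values = np.column_stack([cond_cols, drift])
    columns = cond_names + drift_names
    if extra:
        for name, col in extra.items():
            col = np.asarray(col, dtype=float)
            if col.shape != (design.n_volumes,):
                raise ValueError(f"extra regressor {name!r} has wrong length")
            values = np.column_stack([values, col])
            columns.append(name)
    return DesignMatrix(values, columns, cond_names, design.tr)


@dataclass
class GLMFit:
    """OLS result of one run: condition betas, t-stats, noise variance."""

    betas: np.ndarray          # (n_conditions, n_voxels), sign convention applied
    conditions: list[str]
    tstats: np.ndarray         # same shape as betas
    sigma2: np.ndarray         # (n_voxels,) residual variance
    dof: int
    run_mean: np.ndarray | None  # per-voxel normalization scale, if applied
    cond_cov: np.ndarray | None = None  # (X'X)^-1 restricted to condition columns

    def beta(self, condition: str) -> np.ndarray:
        return self.betas[self.conditions.index(condition)]


def fit_glm(
    timeseries: np.ndarray,
    X: DesignMatrix,
    invert_sign: bool = True,
    normalize: bool = True,
) -> GLMFit:
    """Per-voxel OLS on one run.

    ``timeseries`` may be 4-D (x, y, z, t) or 2-D (t, voxels).  When
    ``normalize`` each voxel is first scaled to percent of its run mean
    (betas then measure percent signal change and are invariant to
    multiplying the raw run by any positive constant).  With
    ``invert_sign`` betas and t's are multiplied by -1 so activation,
    which decreases the raw MION signal, comes out positive.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim == 4:
        ts = ts.reshape(-1, ts.shape[-1]).T  # (t, voxels)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 4-D or 2-D (t, voxels)")
    n_vol, n_vox = ts.shape
    if n_vol != X.values.shape[0]:
        raise ValueError("volume count does not match design matrix")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.values.shape[1]:
        bad = _suspect_columns(X)
        raise ValueError(f"design matrix is rank deficient (suspect columns: {bad})")

    run_mean = None
    if normalize:
        run_mean = ts.mean(axis=0)
        if np.any(run_mean <= 0):
            raise ValueError("non-positive run mean; cannot normalize")
        ts = ts / run_mean * 100.0

    coef, _, _, _ = np.linalg.lstsq(X.values, ts, rcond=None)
    resid = ts - X.values @ coef
    dof = n_vol - X.values.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / max(dof, 1)
    xtx_inv = np.linalg.inv(X.values.T @ X.values)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, coef / se, 0.0)

    idx = [X.columns.index(c) for c in X.condition_columns]
    sign = -1.0 if invert_sign else 1.0
    return GLMFit(
        betas=sign * coef[idx],
        conditions=list(X.condition_columns),
        tstats=sign * t_all[idx],
        sigma2=sigma2,
        dof=dof,
        run_mean=run_mean,
        cond_cov=xtx_inv[np.ix_(idx, idx)],
    )


def _suspect_columns(X: DesignMatrix) -> list[str]:
    """Name columns that are collinear with the rest of the matrix."""
    bad = []
    for j, name in enumerate(X.columns):
        others = np.delete(X.values, j, axis=1)
        proj, _, _, _ = np.linalg.lstsq(others, X.values[:, j], rcond=None)
        resid = X.values[:, j] - others @ proj
        if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(X.values[:, j]), 1e-30):
            bad.append(name)
    return bad


def estimate_patterns(
    runs: list[tuple[np.ndarray, ExperimentDesign]],
    drift_order: int = 2,
    invert_sign: bool = True,
    normalize: bool = True,
    sessions: np.ndarray | None = None,
    periods: np.ndarray | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> PatternMatrix:
    """Fit one GLM per run and stack betas into a PatternMatrix.

    One sample per (condition, run), the granularity leave-one-run-out
    decoding needs.  ``sessions``/``periods`` optionally tag each run.
    """
    values, meta = [], []
    for r, (ts, design) in enumerate(runs):
        X = build_design_matrix(design, drift_order=drift_order)
        fit = fit_glm(ts, X, invert_sign=invert_sign, normalize=normalize)
        for c, cond in enumerate(fit.conditions):
            values.append(fit.betas[c])
            meta.append(
                {
                    "experiment": design.experiment_id,
                    "condition": cond,
                    "run": design.run_index,
                    "session": int(sessions[r]) if sessions is not None else 1,
                    "period": str(periods[r]) if periods is not None else "first",
                }
            )
    voxels = None
    if grid_shape is not None:
        voxels = default_voxel_table(grid_shape)
    return PatternMatrix(np.vstack(values), pd.DataFrame(meta), voxels)


def contrast_map(
    source: GLMFit | PatternMatrix, weights: dict[str, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise weighted combination of condition responses and its t map.

    For a single-run ``GLMFit`` the t statistic uses the OLS residual
    variance.  For a ``PatternMatrix`` the contrast is computed per run
    and a one-sample t across runs is returned (the form used to define
    regions of interest from run-resolved response estimates).  Weights
    need not sum to zero.
    """
    if isinstance(source, GLMFit):
        missing = [c for c in weights if c not in source.conditions]
        if missing:
            raise ValueError(f"no condition matching weight label(s) {missing}")
        w = np.zeros(len(source.conditions))
        for c, x in weights.items():
            w[source.conditions.index(c)] = x
        con = w @ source.betas
        se = np.sqrt((w @ source.cond_cov @ w) * source.sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, con / se, 0.0)
        return con, t

    pattern = source
    present = set(pattern.samples["condition"])
    missing = [c for c in weights if c not in present]
    if missing:
        raise ValueError(f"no condition matching weight label(s) {missing}")
    per_run = []
    for run in pattern.runs():
        sub = pattern.select(run=run)
        con = np.zeros(pattern.n_voxels)
        for cond, w in weights.items():
            rows = sub.select(condition=cond)
            if rows.n_samples:
                con += w * rows.values.mean(axis=0)
        per_run.append(con)
    per_run = np.asarray(per_run)
    con = per_run.mean(axis=0)
    if all(w == 0 for w in weights.values()):
        return con, np.zeros_like(con)
    sem = per_run.std(axis=0, ddof=1) / np.sqrt(per_run.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sem > 0, con / sem, 0.0)
    return con, t
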