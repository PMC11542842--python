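"""The samples-by-voxels response container shared by all analysis stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("experiment", "condition", "run", "session", "period")


@dataclass
class PatternMatrix:
    """Per-(condition, run) voxel response estimates with metadata.

    ``values`` is an (n_samples, n_voxels) float array of response
    amplitudes (for measured data: sign-inverted MION betas, so larger
    means more activation).  ``samples`` carries one row per sample with
    columns experiment/condition/run/session/period; ``voxels`` optionally
    carries one row per voxel with grid indices ``i,j,k`` and world
    coordinates ``x,y,z`` in mm.
    """

    values: np.ndarray
    samples: pd.DataFrame
    voxels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x voxels)")
        if len(self.samples) != self.values.shape[0]:
            raise ValueError("sample metadata does not match values")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata missing column {col!r}")
        if self.voxels is not None and len(self.voxels) != self.values.shape[1]:
            raise ValueError("voxel metadata does not match values")
        dup = self.samples.duplicated(subset=["experiment", "condition", "run"])
        if dup.any():
            raise ValueError("duplicated (experiment, condition, run) samples")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def select(self, **criteria) -> "PatternMatrix":
        """Subset samples by metadata equality; list values mean membership.

        ``pattern.select(experiment="EXP2", condition=["kiwi", "corn"])``
        """
        mask = np.ones(self.n_samples, dtype=bool)
        for col, want in criteria.items():
            if col not in self.samples.columns:
                raise KeyError(col)
            col_vals = self.samples[col]
            if isinstance(want, (list, tuple, set, np.ndarray)):
                mask &= col_vals.isin(list(want)).to_numpy()
            else:
                mask &= (col_vals == want).to_numpy()
        return self.take(np.flatnonzero(mask))

    def take(self, idx) -> "PatternMatrix":
        idx = np.asarray(idx)
        return PatternMatrix(
            self.values[idx], self.samples.iloc[idx].reset_index(drop=True), self.voxels
        )

    def take_voxels(self, vox_idx) -> "PatternMatrix":
        vox_idx = np.asarray(vox_idx)
        vox = None if self.voxels is None else self.voxels.iloc[vox_idx].reset_index(drop=True)
        return PatternMatrix(self.values[:, vox_idx], self.samples.copy(), vox)

    def runs(self) -> np.ndarray:
        return np.unique(self.samples["run"].to_numpy())

    def condition_means(self, conditions=None) -> pd.DataFrame:
        """Mean pattern per condition (averaged over runs), voxels as columns."""
        df = pd.DataFrame(self.values)
        df["condition"] = self.samples["condition"].to_numpy()
        out = df.groupby("condition", sort=True).mean()
        if conditions is not None:
            out = out.loc[list(conditions)]
        return out

    @staticmethod
    def concat(parts: list["PatternMatrix"]) -> "PatternMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        n_vox = {p.n_voxels for p in parts}
        if len(n_vox) != 1:
            raise ValueError("voxel counts differ")
        values = np.vstack([p.values for p in parts])
        samples = pd.concat([p.samples for p in parts], ignore_index=True)
        return PatternMatrix(values, samples, parts[0].voxels)

    # ------------------------------------------------------------------ I/O

    def save(self, path: str | Path) -> None:
        """Write values as TSV with a JSON sidecar of sample/voxel metadata."""
        path = Path(path)
        pd.DataFrame(self.values).to_csv(path, sep="\t", index=False, header=False)
        sidecar = {
            "samples": self.samples.to_dict(orient="list"),
            "voxels": None if self.voxels is None else self.voxels.to_dict(orient="list"),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @staticmethod
    def load(path: str | Path) -> "PatternMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        samples = pd.DataFrame(sidecar["samples"])
        voxels = None if sidecar["voxels"] is None else pd.DataFrame(sidecar["voxels"])
        return PatternMatrix(values, samples, voxels)


def default_voxel_table(shape: tuple[int, int, int], voxel_mm: float = 1.5) -> pd.DataFrame:
    """Voxel metadata for a full rectangular grid, x centered on the midline.

    World coordinates put x = 0 at the grid center so the two hemispheres
    are the negative-x (left) and positive-x (right) halves.
    """
    nx, ny, nz = shape
    i, j, k = np.unravel_index(np.arange(nx * ny * nz), shape)
    x = (i - (nx - 1) / 2.0) * voxel_mm
    y = (j - (ny - 1) / 2.0) * voxel_mm
    z = (k - (nz - 1) / 2.0) * voxel_mm
    return pd.DataFrame({"i": i, "j": j, "k": k, "x": x, "y": y, "z": z})
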