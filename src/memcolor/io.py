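"""Reading and writing the on-disk dataset layout.

Volumes are NIfTI-1 (1.5 mm isotropic, TR in the header); block timing
is a BIDS-style events TSV (onset, duration, condition in seconds from
run start); ROIs are NIfTI label volumes with a JSON manifest; ground
truth serializes to JSON next to the dataset.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .designs import TR, ExperimentDesign
from .roi import ROI

VOXEL_MM = 1.5


def write_nifti(
    data: np.ndarray, path: str | Path, voxel_mm: float = VOXEL_MM, tr: float = TR
) -> None:
    data = np.asarray(data, dtype=np.float32)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = [voxel_mm] * 3 + ([tr] if data.ndim == 4 else [])
    img.header.set_zooms(zooms)
    if data.ndim == 4:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[["onset", "duration", "condition"]].to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def design_from_events(
    events: pd.DataFrame,
    experiment_id: str,
    run_index: int,
    tr: float = TR,
    n_volumes: int | None = None,
) -> ExperimentDesign:
    """Rebuild a run design from its events table."""
    blocks = [
        (str(r.condition), float(r.onset), float(r.duration))
        for r in events.itertuples()
    ]
    end = max(on + dur for _, on, dur in blocks)
    if n_volumes is None:
        n_volumes = math.ceil(end / tr)
    return ExperimentDesign(
        experiment_id=experiment_id,
        run_index=run_index,
        tr=tr,
        n_volumes=n_volumes,
        blocks=blocks,
    )


def save_roi(
    roi: ROI, grid_shape: tuple[int, int, int], path_prefix: str | Path
) -> None:
    """ROI as a NIfTI label volume plus a JSON manifest."""
    vol = np.zeros(int(np.prod(grid_shape)), dtype=np.float32)
    vol[roi.voxels] = 1.0
    write_nifti(vol.reshape(grid_shape), f"{path_prefix}.nii.gz")
    manifest = {
        "name": roi.name,
        "hemisphere": roi.hemisphere,
        "center": list(roi.center),
        "n_voxels": roi.n_voxels,
        "voxels": roi.voxels.tolist(),
    }
    Path(f"{path_prefix}.json").write_text(json.dumps(manifest))


def load_roi(path_prefix: str | Path) -> ROI:
    manifest = json.loads(Path(f"{path_prefix}.json").read_text())
    return ROI(
        name=manifest["name"],
        hemisphere=manifest["hemisphere"],
        voxels=np.array(manifest["voxels"], dtype=int),
        center=tuple(manifest["center"]),
    )
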