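"""File formats: 4-D NIfTI runs, 6-column realignment-parameter text files,
atlas NIfTI + centroid CSV, hub CSVs.

The affine places the template origin at the grid centre so that the
midsagittal plane (x = 0 mm) falls exactly between the two central voxel
columns of an even-x grid, matching the package's flip convention.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .preprocess import BoldRun


def _affine(dims, voxel_mm) -> np.ndarray:
    vm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    aff = np.diag(list(vm) + [1.0])
    aff[:3, 3] = -(np.asarray(dims, dtype=float) - 1) / 2.0 * vm
    return aff


def save_bold(bold: BoldRun, nifti_path, motion_path=None) -> None:
    """Write a run as 4-D NIfTI plus an optional realignment-parameter text
    file (3 translations in mm, 3 rotations in radians, one row per
    volume)."""
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32),
                          _affine(bold.data.shape[:3], bold.voxel_mm))
    img.header.set_zooms(tuple(bold.voxel_mm) + (bold.tr_seconds,))
    nib.save(img, str(nifti_path))
    if motion_path is not None:
        if bold.motion_params is None:
            raise ValueError("run has no realignment parameters to save")
        np.savetxt(motion_path, bold.motion_params, fmt="%.8f")


def load_bold(nifti_path, motion_path=None, subject_id: str = "",
              site_id: str = "") -> BoldRun:
    """Read a 4-D NIfTI run (TR from the header's 4th zoom) and, when given,
    its whitespace-delimited 6-column realignment-parameter file."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()
    motion = np.loadtxt(motion_path, ndmin=2) if motion_path is not None else None
    return BoldRun(
        data=data,
        tr_seconds=float(zooms[3]) if len(zooms) > 3 else 1.0,
        voxel_mm=tuple(float(z) for z in zooms[:3]),
        motion_params=motion,
        subject_id=subject_id,
        site_id=site_id,
    )


def save_atlas(atlas: RoiAtlas, nifti_path, centroid_csv=None) -> None:
    """Write the label field as integer NIfTI and, optionally, the per-ROI
    centroids (template mm) as CSV."""
    img = nib.Nifti1Image(atlas.labels.astype(np.int32),
                          _affine(atlas.labels.shape, atlas.voxel_mm))
    nib.save(img, str(nifti_path))
    if centroid_csv is not None:
        cents = atlas.centroids_mm()
        pd.DataFrame(
            dict(roi_id=np.arange(1, atlas.n_rois + 1),
                 x=cents[:, 0], y=cents[:, 1], z=cents[:, 2])
        ).to_csv(centroid_csv, index=False)


def load_mask(nifti_path) -> np.ndarray:
    """Read a NIfTI mask as a boolean array."""
    img = nib.load(str(nifti_path))
    return np.asarray(img.dataobj) > 0


def save_nuisance(nuisance, csv_path) -> None:
    """Write the CSF/WM/soft-tissue traces as a 3-column CSV (the motion
    half of the nuisance set lives in the realignment-parameter file)."""
    pd.DataFrame(dict(csf=nuisance.csf, wm=nuisance.wm,
                      soft_tissue=nuisance.soft_tissue)).to_csv(csv_path, index=False)


def load_nuisance(csv_path, motion: np.ndarray):
    """Read nuisance traces written by :func:`save_nuisance` and combine
    them with the run's realignment parameters."""
    from .preprocess import NuisanceSet

    df = pd.read_csv(csv_path)
    return NuisanceSet(df["csf"].to_numpy(), df["wm"].to_numpy(),
                       df["soft_tissue"].to_numpy(), motion)


def append_qc(qc_row: dict, csv_path) -> None:
    """Append one run's QC row to a run-level QC CSV (header written once)."""
    path = Path(csv_path)
    df = pd.DataFrame([qc_row])
    df.to_csv(path, mode="a", header=not path.exists(), index=False)
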