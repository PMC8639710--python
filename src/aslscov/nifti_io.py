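"""NIfTI reading/writing for phantom maps and ASL data (via nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .kinetic import ASLDataset, AcquisitionParams

__all__ = [
    "save_map",
    "load_map",
    "save_asl_dataset",
    "load_asl_dataset",
    "save_phantom",
]


def save_map(values: np.ndarray, path, affine=None) -> Path:
    """Write a 3-D (or 4-D) map as NIfTI-1."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_map(path):
    """Read a NIfTI map; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj, dtype=np.float64), img.affine


def save_phantom(phantom, outdir) -> dict:
    """Write every phantom map as one NIfTI per map; returns name -> path."""
    outdir = Path(outdir)
    paths = {}
    for name in (
        "pv_gm",
        "pv_wm",
        "pv_csf",
        "cbf_true",
        "att_true",
        "m0_tissue",
    ):
        paths[name] = save_map(
            getattr(phantom, name), outdir / f"{name}.nii.gz", phantom.affine
        )
    paths["roi_labels"] = save_map(
        phantom.roi_labels.astype(np.float64),
        outdir / "roi_labels.nii.gz",
        phantom.affine,
    )
    return paths


def save_asl_dataset(ds: ASLDataset, outdir, affine=None) -> dict:
    """Write difference repeats as 4-D NIfTI (repeats last) plus 3-D M0."""
    outdir = Path(outdir)
    diff4d = np.moveaxis(ds.diff_volumes, 0, -1)
    return {
        "asl_diff": save_map(diff4d, outdir / "asl_diff.nii.gz", affine),
        "m0": save_map(ds.m0_volume, outdir / "m0.nii.gz", affine),
    }


def load_asl_dataset(diff_path, m0_path, params: AcquisitionParams) -> ASLDataset:
    diff4d, _ = load_map(diff_path)
    m0, _ = load_map(m0_path)
    return ASLDataset(
        diff_volumes=np.moveaxis(diff4d, -1, 0), m0_volume=m0, params=params
    )
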