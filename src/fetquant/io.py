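"""NIfTI and table I/O.

Volumes and masks are written as .nii.gz with an axis-aligned affine
carrying spacing and origin; each study gets a JSON sidecar with subject
id, timepoint, method labels and the injected bias parameters, and a
cohort-level manifest CSV with one row per written study volume.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import StudyRecord
from .volume import GridMismatchError, VolumeImage

__all__ = [
    "volume_to_nifti",
    "nifti_to_volume",
    "write_mask",
    "read_mask",
    "write_study",
    "write_cohort",
    "read_study",
]

_MASK_NAMES = (
    "brain_mask",
    "skull_mask",
    "tumor_truth_mask",
    "exclusion_mask",
    "background_roi_mask",
)


def volume_to_nifti(vol: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def nifti_to_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0, atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned volumes are supported")
    spacing = tuple(float(abs(x)) for x in np.diag(aff[:3, :3]))
    origin = tuple(float(x) for x in aff[:3, 3])
    return VolumeImage(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def write_mask(mask: np.ndarray, like: VolumeImage, path: str | Path) -> Path:
    return volume_to_nifti(like.copy_with(mask.astype(np.float64)), path)


def read_mask(path: str | Path, like: VolumeImage | None = None) -> np.ndarray:
    vol = nifti_to_volume(path)
    if like is not None and not like.same_grid(vol):
        raise GridMismatchError(
            f"mask {path} grid {vol.shape}@{vol.spacing} does not match the "
            f"PET grid {like.shape}@{like.spacing}"
        )
    return vol.values > 0.5


def write_study(record: StudyRecord, study_dir: str | Path) -> list[dict]:
    """Write all volumes/masks of one study; return manifest rows."""
    study_dir = Path(study_dir)
    study_dir.mkdir(parents=True, exist_ok=True)
    scene = record.scene
    rows = []

    volume_to_nifti(scene.truth_activity, study_dir / "truth_activity.nii.gz")
    for name in _MASK_NAMES:
        write_mask(getattr(scene, name), scene.truth_activity, study_dir / f"{name}.nii.gz")
    for label, img in scene.biased_images.items():
        fname = f"pet_{label}.nii.gz"
        volume_to_nifti(img, study_dir / fname)
        rows.append(
            {
                "subject_id": record.subject_id,
                "study_id": record.study_id,
                "timepoint": record.timepoint,
                "method": label,
                "path": str(study_dir / fname),
            }
        )

    sidecar = {
        "subject_id": record.subject_id,
        "study_id": record.study_id,
        "timepoint": record.timepoint,
        "seed": record.scene.spec.seed,
        "noise_sd": record.scene.spec.noise_sd,
        "methods": sorted(scene.biased_images),
        "injected": record.injected,
    }
    (study_dir / "study.json").write_text(json.dumps(sidecar, indent=2))
    return rows


def write_cohort(records: Sequence[StudyRecord], out_dir: str | Path) -> pd.DataFrame:
    """Write every study plus a cohort manifest CSV; return the manifest."""
    out_dir = Path(out_dir)
    rows: list[dict] = []
    for record in records:
        rows.extend(write_study(record, out_dir / record.study_id))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_study(study_dir: str | Path) -> dict:
    """Load one written study back: images, masks and the sidecar record.

    Grid incompatibility between the PET volumes and their masks is a hard
    error naming both grids.
    """
    study_dir = Path(study_dir)
    sidecar = json.loads((study_dir / "study.json").read_text())
    truth = nifti_to_volume(study_dir / "truth_activity.nii.gz")
    masks = {
        name: read_mask(study_dir / f"{name}.nii.gz", like=truth)
        for name in _MASK_NAMES
    }
    images = {}
    for label in sidecar["methods"]:
        img = nifti_to_volume(study_dir / f"pet_{label}.nii.gz")
        truth.require_same_grid(img, f"pet_{label}")
        images[label] = img
    return {"sidecar": sidecar, "truth": truth, "masks": masks, "images": images}
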