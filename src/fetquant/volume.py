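"""Axis-aligned 3-D scalar volumes.

Every image in this package lives on a regular, axis-aligned grid described
by a voxel spacing (mm per axis) and the world coordinate (mm) of the first
voxel centre. Two images are grid-compatible only when shape, spacing and
origin all match exactly; pairwise operations check this rather than
resample, because the clinical acquisitions being emulated are inherently
co-registered (simultaneous PET/MR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeImage", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two volumes do not share shape, spacing and origin."""


@dataclass
class VolumeImage:
    """A 3-D scalar lattice with voxel spacing and origin.

    Parameters
    ----------
    values
        3-D array of activity (SUV-like, arbitrary units) or bias-field
        multipliers. Stored as float64.
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        World coordinate in mm of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    # -- grid -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (axis-aligned, voxel-centre convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def require_same_grid(self, other: "VolumeImage", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch with {what}: "
                f"{self.shape}@{self.spacing}+{self.origin} vs "
                f"{other.shape}@{other.spacing}+{other.origin}"
            )

    def require_mask(self, mask: np.ndarray, what: str = "mask") -> np.ndarray:
        """Validate that ``mask`` lives on this grid; return it as bool."""
        mask = np.asarray(mask)
        if mask.shape != self.shape:
            raise GridMismatchError(
                f"{what} shape {mask.shape} does not match volume shape {self.shape}"
            )
        return mask.astype(bool)

    # -- coordinates -------------------------------------------------------

    def index_to_world(self, index) -> np.ndarray:
        """World coordinate (mm) of a voxel index (voxel-centre convention)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def copy_with(self, values: np.ndarray) -> "VolumeImage":
        """New image on the same grid with different values."""
        return VolumeImage(np.asarray(values, dtype=np.float64), self.spacing, self.origin)

    def scaled(self, factor: float) -> "VolumeImage":
        return self.copy_with(self.values * float(factor))
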