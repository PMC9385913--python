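"""Shared containers and array conventions.

Volumes and masks are stored in (x, y, z) voxel order, matching the ijk axis
order of a NIfTI file; voxel indices are 0-based.  Binary masks are plain
``bool`` NumPy arrays — every public function validates binarity at the
boundary instead of wrapping masks in a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default voxel spacing in mm, mirroring a typical axial T2-weighted
#: prostate acquisition (0.59 x 0.59 mm in-plane, 3.3 mm slices).
DEFAULT_SPACING: tuple[float, float, float] = (0.59, 0.59, 3.3)


@dataclass
class Volume:
    """A 3D grayscale image with voxel spacing metadata.

    Parameters
    ----------
    data
        Float array of shape (nx, ny, nz).
    spacing
        Voxel edge lengths in mm, (sx, sy, sz).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = field(default=DEFAULT_SPACING)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing)


def as_mask(arr: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate and coerce an array to a boolean mask.

    Accepts bool arrays or numeric arrays whose values are strictly 0/1.
    """
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{name} must be 3D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} is not binary: values {uniq[:10]}")
    return arr.astype(bool)


def check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
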