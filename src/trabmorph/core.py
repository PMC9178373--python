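"""Voxel-volume container and the package-wide anatomical axis convention.

All volumes are 3D arrays with isotropic voxel spacing.  The anatomical
convention, fixed package-wide, is:

* axis 0 — proximodistal; the slice index increases distally,
* axis 1 — dorsopalmar; the index increases palmarly,
* axis 2 — radioulnar.

Physical coordinates are in millimetres: ``x_mm = index * voxel_size``
(voxel centres sit at integer indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_PROXIMODISTAL = 0
AXIS_DORSOPALMAR = 1
AXIS_RADIOULNAR = 2


@dataclass
class VoxelVolume:
    """A 3D scalar or binary image with isotropic voxel size in mm.

    Parameters
    ----------
    data:
        3D array.  Binary volumes hold exactly the values {0, 1} (any
        integer or boolean dtype).
    voxel_size:
        Isotropic voxel edge length in mm.
    origin:
        Voxel-index offset of ``data[0, 0, 0]`` relative to the parent
        volume this one was cropped from.  Purely bookkeeping; physical
        coordinates returned by helpers include it.
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[int, int, int] = field(default=(0, 0, 0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        if self.data.dtype == bool:
            return True
        vals = np.unique(self.data)
        return vals.size <= 2 and np.isin(vals, (0, 1)).all()

    def as_bool(self) -> np.ndarray:
        """Binary data as a boolean array (raises if not binary)."""
        if not self.is_binary:
            raise ValueError("volume is not binary")
        return self.data.astype(bool)

    def physical_extent(self) -> np.ndarray:
        """Physical size of the volume per axis in mm."""
        return np.array(self.shape) * self.voxel_size

    def like(self, data: np.ndarray) -> "VoxelVolume":
        """New volume sharing this one's geometry."""
        return VoxelVolume(data, self.voxel_size, self.origin)
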