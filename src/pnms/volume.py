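"""Lightweight 3D volume container used throughout the pipeline.

All images, tissue probability maps, label volumes and binary masks are
carried as :class:`Volume`: a 3D scalar lattice with voxel spacing in mm
and a flag marking that the lattice lives in a left-right symmetric space
(the midsagittal plane is the lattice's x-midplane, i.e. halfway between
columns ``Nx/2 - 1`` and ``Nx/2`` for even ``Nx``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "AIMap"]


@dataclass
class Volume:
    """A 3D scalar lattice with voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (Nx, Ny, Nz)
        Voxel values. The first axis is left-right.
    voxel_mm : tuple of 3 floats
        Voxel edge lengths in millimetres; all strictly positive.
    symmetric_space : bool
        True when the midsagittal plane coincides with the lattice
        x-midplane, so a left-right flip is a pure index reversal.
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    symmetric_space: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D lattice, got ndim={self.values.ndim}")
        self.voxel_mm = tuple(float(v) for v in self.voxel_mm)
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel_mm must be 3 positive lengths, got {self.voxel_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def like(self, values: np.ndarray) -> "Volume":
        """A new Volume on the same lattice with different values."""
        return Volume(values, self.voxel_mm, self.symmetric_space)

    def check_same_lattice(self, other: "Volume") -> None:
        if self.shape != other.shape:
            raise ValueError(f"lattice shape mismatch: {self.shape} vs {other.shape}")
        if self.voxel_mm != other.voxel_mm:
            raise ValueError(f"voxel size mismatch: {self.voxel_mm} vs {other.voxel_mm}")


@dataclass
class AIMap:
    """Voxel-wise interhemispheric asymmetry-index map.

    ``values`` holds AI = (i1 - i2) / ((i1 + i2) * 0.5) where i2 is the
    midsagittally flipped image; ``valid_mask`` marks voxels where the
    denominator is safely away from zero (and, when a brain mask was
    supplied, where both the voxel and its mirror lie in the mask).
    Outside ``valid_mask`` the values are NaN.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape
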