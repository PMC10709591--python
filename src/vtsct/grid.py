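"""Voxel-grid carrier shared by every pipeline stage.

Conventions (fixed project-wide):

* ``voxels`` is indexed ``[x, y, z]`` where x = left-right, y =
  antero-posterior, z = craniocaudal; slices are planes perpendicular
  to z and z is the slice-stacking axis.
* Voxel indices are 0-based; the world position of voxel centre
  ``(i, j, k)`` is ``origin_mm + (i, j, k) * spacing_mm``.
* All distances are millimetres, all intensities Hounsfield units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeGrid", "empty_like_template"]


@dataclass
class VolumeGrid:
    """A 3D HU volume with anisotropic voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Attenuation values in HU.  Must be finite.
    spacing_mm : sequence of 3 floats
        Per-axis voxel spacing, all strictly positive.
    origin_mm : sequence of 3 floats, optional
        World coordinate of voxel (0, 0, 0)'s centre.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"voxels must be a 3D array, got ndim={self.voxels.ndim}"
            )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or len(self.origin_mm) != 3:
            raise ValueError("spacing_mm and origin_mm must have length 3")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be > 0, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite HU values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge-to-edge extent along each axis (n * spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))

    def z_centers_mm(self) -> np.ndarray:
        """World z coordinate of every slice centre."""
        nz = self.shape[2]
        return self.origin_mm[2] + self.spacing_mm[2] * np.arange(nz)

    def coordinate_axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def with_voxels(self, voxels: np.ndarray) -> "VolumeGrid":
        """Same grid geometry, different voxel data."""
        return replace(self, voxels=voxels)

    def allclose(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
            and np.allclose(self.voxels, other.voxels, atol=atol)
        )


def empty_like_template(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    fill_hu: float = -850.0,
) -> VolumeGrid:
    """Build a uniform template grid (used as a phantom canvas)."""
    return VolumeGrid(
        np.full(shape, fill_hu, dtype=np.float32),
        spacing_mm=spacing_mm,
        origin_mm=origin_mm,
    )
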