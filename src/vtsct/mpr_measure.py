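"""Multiplanar reconstruction (MPR) extraction and nodule size measurement.

The measurement procedure automates a manual radiologist workflow:
binarize at a threshold, keep the largest 26-connected 3D component,
then for each of the three axis-aligned orientations (axial, coronal,
sagittal) take the maximum over planes of the in-plane maximum Feret
diameter of the component's cross-section, and report the maximum over
orientations.  The solid component uses ``solid_threshold_hu``
(default -300, between the phantom solid and ground-glass
attenuations) and the total extent uses ``total_threshold_hu``
(default -700, between ground glass and lung).

Feret diameters are computed on the convex hull of pixel *centre*
points scaled by the plane's (possibly anisotropic) pixel spacing —
the distance between the farthest pair of voxel centres, matching a
caliper placed on the rendered voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .grid import VolumeGrid

__all__ = [
    "Orientation",
    "SizeMeasurement",
    "ObserverModel",
    "extract_mpr",
    "measure_size",
    "simulate_observer",
]


class Orientation(str, Enum):
    AXIAL = "axial"  # planes perpendicular to z
    CORONAL = "coronal"  # planes perpendicular to y
    SAGITTAL = "sagittal"  # planes perpendicular to x


# volume axis sliced through, and the two in-plane axes, per orientation
_ORIENT_AXES = {
    Orientation.AXIAL: (2, (0, 1)),
    Orientation.CORONAL: (1, (0, 2)),
    Orientation.SAGITTAL: (0, (1, 2)),
}


@dataclass(frozen=True)
class SizeMeasurement:
    """Measured total and solid nodule size (mm)."""

    solid_mm: float
    total_mm: float
    solid_plane: Orientation | None
    thresholds_hu: tuple[float, float]
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.solid_mm < 0 or self.total_mm < 0:
            raise ValueError("sizes must be non-negative")
        if self.solid_mm > self.total_mm + 1e-9:
            raise ValueError(
                f"solid_mm ({self.solid_mm}) exceeds total_mm ({self.total_mm})"
            )


@dataclass(frozen=True)
class ObserverModel:
    """Additive-noise + rounding model of a human reader."""

    additive_sd_mm: float = 1.0
    rounding_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd_mm < 0:
            raise ValueError("additive_sd_mm must be >= 0")
        if self.rounding_mm < 0:
            raise ValueError("rounding_mm must be >= 0")


def extract_mpr(
    volume: VolumeGrid, orientation: Orientation | str
) -> tuple[np.ndarray, tuple[float, float]]:
    """Return the ordered plane stack for one orientation.

    Axis-aligned planes need no resampling.  Returns ``(planes,
    pixel_spacing)`` where ``planes`` has shape (n_planes, a, b) and
    ``pixel_spacing`` gives the in-plane mm spacing along (a, b).

    Axial planes are (x, y) slabs stacked along z; coronal are (x, z)
    stacked along y; sagittal are (y, z) stacked along x.
    """
    try:
        orientation = Orientation(orientation)
    except ValueError:
        raise ValueError(f"unknown orientation {orientation!r}") from None
    slice_axis, plane_axes = _ORIENT_AXES[orientation]
    planes = np.moveaxis(volume.voxels, slice_axis, 0)
    spacing = (volume.spacing_mm[plane_axes[0]], volume.spacing_mm[plane_axes[1]])
    return planes, spacing


def _max_feret_mm(mask2d: np.ndarray, spacing: tuple[float, float]) -> float:
    """Maximum Feret diameter of a 2D pixel mask, in mm.

    Maximum distance between foreground pixel centres, via the convex
    hull, with anisotropic pixel spacing.
    """
    idx = np.argwhere(mask2d)
    if idx.size == 0:
        return 0.0
    pts = idx * np.asarray(spacing, dtype=float)
    if len(idx) > 2:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) point set: brute force below
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component; ties broken by lowest
    lexicographic centroid."""
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())[1:]
    best = counts.max()
    candidates = np.flatnonzero(counts == best) + 1
    if len(candidates) > 1:
        cents = ndimage.center_of_mass(mask, labels, candidates)
        candidates = [c for _, c in sorted(zip(map(tuple, cents), candidates))]
    return labels == candidates[0]


def _component_max_size(
    volume: VolumeGrid, threshold_hu: float
) -> tuple[float, Orientation | None]:
    mask = volume.voxels >= threshold_hu
    if not mask.any():
        return 0.0, None
    comp = _largest_component(mask)
    best = 0.0
    best_orient: Orientation | None = None
    for orient in Orientation:
        slice_axis, plane_axes = _ORIENT_AXES[orient]
        planes = np.moveaxis(comp, slice_axis, 0)
        spacing = (
            volume.spacing_mm[plane_axes[0]],
            volume.spacing_mm[plane_axes[1]],
        )
        for plane in planes:
            if not plane.any():
                continue
            d = _max_feret_mm(plane, spacing)
            if d > best:
                best = d
                best_orient = orient
    return best, best_orient


def measure_size(
    volume: VolumeGrid,
    solid_threshold_hu: float = -300.0,
    total_threshold_hu: float = -700.0,
    source: str = "unknown",
) -> SizeMeasurement:
    """Measure maximal solid and total nodule size across MPR planes.

    See the module docstring for the procedure.  An empty mask at a
    threshold yields size 0 (e.g. solid size of a pure ground-glass
    nodule).
    """
    if solid_threshold_hu <= total_threshold_hu:
        raise ValueError(
            "thresholds must satisfy solid_threshold_hu > total_threshold_hu, "
            f"got {solid_threshold_hu} <= {total_threshold_hu}"
        )
    solid_mm, solid_plane = _component_max_size(volume, solid_threshold_hu)
    total_mm, _ = _component_max_size(volume, total_threshold_hu)
    # the total-extent component can only be larger, but guard discretization
    total_mm = max(total_mm, solid_mm)
    return SizeMeasurement(
        solid_mm=solid_mm,
        total_mm=total_mm,
        solid_plane=solid_plane,
        thresholds_hu=(solid_threshold_hu, total_threshold_hu),
        source=source,
    )


def simulate_observer(
    truth: SizeMeasurement,
    model: ObserverModel,
    rng: np.random.Generator | None = None,
) -> SizeMeasurement:
    """Perturb a measurement like a human reader would.

    Adds seeded Gaussian noise (sd ``additive_sd_mm``) independently to
    solid and total size, rounds to ``rounding_mm`` (0 disables
    rounding), floors at 0, and clamps solid <= total.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    solid = truth.solid_mm + (
        rng.normal(0.0, model.additive_sd_mm) if model.additive_sd_mm > 0 else 0.0
    )
    total = truth.total_mm + (
        rng.normal(0.0, model.additive_sd_mm) if model.additive_sd_mm > 0 else 0.0
    )
    if model.rounding_mm > 0:
        solid = np.round(solid / model.rounding_mm) * model.rounding_mm
        total = np.round(total / model.rounding_mm) * model.rounding_mm
    solid = max(0.0, float(solid))
    total = max(0.0, float(total))
    solid = min(solid, total)
    return SizeMeasurement(
        solid_mm=solid,
        total_mm=total,
        solid_plane=truth.solid_plane,
        thresholds_hu=truth.thresholds_hu,
        source=truth.source,
    )
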