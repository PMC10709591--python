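"""Thick-slice CT simulation from thin-slice volumes.

A thick slice is modelled as the overlap-weighted average (box filter
along z) of the thin slices it spans.  Slabs are half-open intervals
``[start, start + thickness)`` so boundary slices are never counted
twice.  The first slab starts at the physical top edge of the volume
(origin_z - thin_spacing/2) unless a random phase is requested, and
successive slab starts advance by the reconstruction interval.
An optional Gaussian z-kernel is available behind ``kernel=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

__all__ = ["SliceCondition", "degrade", "sample_condition", "slice_count_ratio"]


@dataclass(frozen=True)
class SliceCondition:
    """Slice thickness and reconstruction interval of a thick volume."""

    thickness_mm: float
    interval_mm: float
    source_thin_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.interval_mm <= 0:
            raise ValueError(f"interval_mm must be > 0, got {self.interval_mm}")
        if self.thickness_mm < self.source_thin_mm:
            raise ValueError(
                f"thickness_mm ({self.thickness_mm}) must be >= source thin "
                f"slice spacing ({self.source_thin_mm})"
            )

    def to_dict(self) -> dict:
        return {
            "thickness_mm": self.thickness_mm,
            "interval_mm": self.interval_mm,
            "source_thin_mm": self.source_thin_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SliceCondition":
        return cls(**d)


def _slab_weights(
    z_edges: np.ndarray, slab_lo: float, slab_hi: float
) -> np.ndarray:
    """Overlap length of each thin slice [edge_k, edge_k+1) with a slab."""
    lo = np.maximum(z_edges[:-1], slab_lo)
    hi = np.minimum(z_edges[1:], slab_hi)
    return np.clip(hi - lo, 0.0, None)


def degrade(
    thin: VolumeGrid,
    cond: SliceCondition,
    kernel: str = "box",
    phase_mm: float = 0.0,
) -> VolumeGrid:
    """Simulate a thick-slice volume from a thin-slice volume.

    Output slice ``k`` is centred at ``top_edge + phase + k*interval +
    thickness/2`` and averages the thin slices overlapping the
    half-open slab, weighted by overlap fraction.  The in-plane grid is
    unchanged; the output z-spacing equals ``cond.interval_mm``.

    Parameters
    ----------
    kernel : {"box", "gaussian"}
        Slab profile.  "box" (default) weights by geometric overlap;
        "gaussian" weights by a Gaussian of FWHM = thickness centred on
        the slab centre, truncated to +/- thickness.
    phase_mm : float
        Extra z offset of the first slab start (seeded random phase is
        the caller's responsibility).
    """
    dz = thin.spacing_mm[2]
    if dz > cond.thickness_mm + 1e-9:
        raise ValueError(
            f"thin z-spacing ({dz} mm) exceeds slab thickness ({cond.thickness_mm} mm)"
        )
    if kernel not in ("box", "gaussian"):
        raise ValueError(f"unknown kernel {kernel!r}")
    nz = thin.shape[2]
    top_edge = thin.origin_mm[2] - dz / 2.0
    z_extent = nz * dz
    if z_extent + 1e-9 < cond.thickness_mm:
        raise ValueError(
            f"z-extent ({z_extent} mm) shorter than one slab "
            f"({cond.thickness_mm} mm)"
        )
    avail = z_extent - phase_mm
    n_out = int(np.floor((avail - cond.thickness_mm) / cond.interval_mm + 1e-9)) + 1
    if n_out < 1:
        raise ValueError("degradation produced an empty output volume")
    z_edges = top_edge + dz * np.arange(nz + 1)
    out = np.empty(thin.shape[:2] + (n_out,), dtype=np.float64)
    vox = thin.voxels.astype(np.float64, copy=False)
    for k in range(n_out):
        slab_lo = top_edge + phase_mm + k * cond.interval_mm
        slab_hi = slab_lo + cond.thickness_mm
        w = _slab_weights(z_edges, slab_lo, slab_hi)
        if kernel == "gaussian":
            centers = top_edge + dz * (np.arange(nz) + 0.5)
            c = 0.5 * (slab_lo + slab_hi)
            sigma = cond.thickness_mm / 2.354820045030949  # FWHM -> sigma
            w = w * np.exp(-0.5 * ((centers - c) / sigma) ** 2)
        total = w.sum()
        if total <= 0:
            raise ValueError("slab overlaps no thin slices")
        out[:, :, k] = np.tensordot(vox, w / total, axes=([2], [0]))
    origin = (
        thin.origin_mm[0],
        thin.origin_mm[1],
        top_edge + phase_mm + cond.thickness_mm / 2.0,
    )
    spacing = (thin.spacing_mm[0], thin.spacing_mm[1], cond.interval_mm)
    return VolumeGrid(out.astype(thin.voxels.dtype), spacing, origin)


def sample_condition(
    rng: np.random.Generator,
    lo: float = 3.0,
    hi: float = 8.0,
    step_mm: float | None = 0.5,
    source_thin_mm: float = 1.0,
) -> SliceCondition:
    """Draw thickness and interval independently uniform on [lo, hi].

    Thickness and interval are rounded to ``step_mm`` steps (set
    ``step_mm=None`` to disable rounding).
    """
    if lo > hi:
        raise ValueError(f"lo must be <= hi, got ({lo}, {hi})")
    t = rng.uniform(lo, hi)
    i = rng.uniform(lo, hi)
    if step_mm:
        t = float(np.clip(np.round(t / step_mm) * step_mm, lo, hi))
        i = float(np.clip(np.round(i / step_mm) * step_mm, lo, hi))
    return SliceCondition(
        thickness_mm=t, interval_mm=i, source_thin_mm=source_thin_mm
    )


def slice_count_ratio(
    thin_interval_mm: float, thick_interval_mm: float, z_extent_mm: float
) -> float:
    """Fold increase in contiguous slice count when reconstructing at
    the thin instead of the thick interval over a fixed z extent."""
    for name, v in (
        ("thin_interval_mm", thin_interval_mm),
        ("thick_interval_mm", thick_interval_mm),
        ("z_extent_mm", z_extent_mm),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return (z_extent_mm / thin_interval_mm) / (z_extent_mm / thick_interval_mm)
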