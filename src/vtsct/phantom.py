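"""Seeded synthetic lung-nodule phantoms with exact ground truth.

A nodule is modelled as two concentric spheres: an outer ground-glass
sphere (total size) and an inner solid sphere (solid size).  Component
attenuations default to -50 HU (solid), -450 HU (ground glass) and
-850 HU (lung background); these are chosen so that single thresholds
cleanly separate the components, and all are configurable.  Voxels at
sphere boundaries get partial-volume HU by sub-voxel volume-fraction
mixing at 2x supersampling per axis, so sub-voxel size recovery is
meaningful.

Cohorts emulate a validation population of 93 nodules with type mix
27 solid / 55 part-solid / 11 pure ground-glass, solid size
~ N(11.3, 9.6^2) truncated to (0, 36] for nodules with a solid
component, and total size ~ N(19.6, 9.1^2) truncated to [5, 45].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .grid import VolumeGrid

__all__ = [
    "NoduleType",
    "NoduleSpec",
    "NoduleGroundTruth",
    "CohortParams",
    "generate_phantom",
    "generate_cohort",
    "write_ground_truth_table",
]


class NoduleType(str, Enum):
    SOLID = "solid"
    PART_SOLID = "part_solid"
    PURE_GGN = "pure_ggn"


@dataclass(frozen=True)
class NoduleSpec:
    """Geometric and attenuation description of one phantom nodule."""

    nodule_type: NoduleType
    total_diameter_mm: float
    solid_diameter_mm: float
    center_mm: tuple[float, float, float]
    solid_hu: float = -50.0
    ggo_hu: float = -450.0
    lung_hu: float = -850.0
    noise_sd_hu: float = 20.0
    elongation_z: float = 1.0

    def semi_axes_mm(self, diameter_mm: float) -> tuple[float, float, float]:
        """Ellipsoid semi-axes for a component of given *maximal* diameter.

        ``elongation_z`` is the craniocaudal-to-in-plane axis ratio; the
        stated diameter is always the longest axis (the clinical
        maximal-diameter convention), so in-plane axes shrink when the
        nodule is z-elongated and the z axis shrinks when flattened.
        """
        e = self.elongation_z
        a = diameter_mm / 2.0 / max(1.0, e)
        return (a, a, a * e)

    def __post_init__(self) -> None:
        t = NoduleType(self.nodule_type)
        object.__setattr__(self, "nodule_type", t)
        if self.total_diameter_mm <= 0:
            raise ValueError(
                f"total_diameter_mm must be positive, got {self.total_diameter_mm}"
            )
        if self.solid_diameter_mm < 0:
            raise ValueError(
                f"solid_diameter_mm must be non-negative, got {self.solid_diameter_mm}"
            )
        if self.solid_diameter_mm > self.total_diameter_mm + 1e-9:
            raise ValueError(
                "solid_diameter_mm exceeds total_diameter_mm "
                f"({self.solid_diameter_mm} > {self.total_diameter_mm})"
            )
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.elongation_z <= 0:
            raise ValueError("elongation_z must be positive")
        if not (self.solid_hu > self.ggo_hu > self.lung_hu):
            raise ValueError(
                "attenuations must satisfy solid_hu > ggo_hu > lung_hu, got "
                f"{self.solid_hu}, {self.ggo_hu}, {self.lung_hu}"
            )
        if t is NoduleType.PURE_GGN and self.solid_diameter_mm != 0:
            raise ValueError("pure_ggn nodules must have solid_diameter_mm == 0")
        if t is not NoduleType.PURE_GGN and self.solid_diameter_mm == 0:
            raise ValueError("only pure_ggn nodules may have solid_diameter_mm == 0")
        if t is NoduleType.SOLID and not np.isclose(
            self.solid_diameter_mm, self.total_diameter_mm
        ):
            raise ValueError("solid nodules must have solid == total diameter")
        if t is NoduleType.PART_SOLID and np.isclose(
            self.solid_diameter_mm, self.total_diameter_mm
        ):
            raise ValueError("part_solid nodules must have solid < total diameter")


@dataclass(frozen=True)
class NoduleGroundTruth:
    """Exact truth attached to a generated phantom."""

    spec: NoduleSpec
    true_total_mm: float
    true_solid_mm: float
    invasive_size_mm: float

    def __post_init__(self) -> None:
        if not np.isclose(self.true_solid_mm, self.spec.solid_diameter_mm):
            raise ValueError("true_solid_mm must equal spec.solid_diameter_mm")
        if self.invasive_size_mm < 0:
            raise ValueError("invasive_size_mm must be non-negative")


def _ellipsoid_fraction(
    grid: VolumeGrid,
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    supersample: int = 2,
) -> np.ndarray:
    """Per-voxel fraction of voxel volume inside an axis-aligned ellipsoid.

    Estimated by counting subvoxel sample points (``supersample`` per
    axis, cell-centred) inside the surface.  Returns a float array over
    the full grid; computed only inside the ellipsoid's bounding box.
    """
    if min(semi_axes_mm) <= 0:
        return np.zeros(grid.shape, dtype=np.float64)
    ax = grid.coordinate_axes_mm()
    frac = np.zeros(grid.shape, dtype=np.float64)
    # bounding box with one voxel of slack
    lo, hi = [], []
    for a in range(3):
        lo.append(
            int(
                np.clip(
                    np.searchsorted(ax[a], center_mm[a] - semi_axes_mm[a]) - 1,
                    0,
                    grid.shape[a],
                )
            )
        )
        hi.append(
            int(
                np.clip(
                    np.searchsorted(ax[a], center_mm[a] + semi_axes_mm[a]) + 1,
                    0,
                    grid.shape[a],
                )
            )
        )
    if any(l >= h for l, h in zip(lo, hi)):
        return frac
    s = supersample
    # cell-centred subvoxel offsets in units of spacing
    off = (np.arange(s) + 0.5) / s - 0.5
    sub = np.zeros(tuple(h - l for l, h in zip(lo, hi)), dtype=np.int32)
    coords = [
        (ax[a][lo[a] : hi[a]] - center_mm[a]) for a in range(3)
    ]
    for ox in off:
        dx2 = ((coords[0] + ox * grid.spacing_mm[0]) / semi_axes_mm[0]) ** 2
        for oy in off:
            dy2 = ((coords[1] + oy * grid.spacing_mm[1]) / semi_axes_mm[1]) ** 2
            for oz in off:
                dz2 = ((coords[2] + oz * grid.spacing_mm[2]) / semi_axes_mm[2]) ** 2
                inside = (
                    dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
                ) <= 1.0
                sub += inside
    frac[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub / float(s**3)
    return frac


def generate_phantom(
    spec: NoduleSpec,
    grid: VolumeGrid,
    seed: int,
    margin_mm: float = 2.0,
    supersample: int = 2,
) -> tuple[VolumeGrid, NoduleGroundTruth]:
    """Rasterize a nodule into a template grid.

    The template's voxel values are ignored; geometry (shape, spacing,
    origin) is reused.  Background is ``lung_hu``, the ground-glass
    sphere ``ggo_hu``, the solid core ``solid_hu``; boundary voxels are
    volume-fraction mixtures.  Zero-mean Gaussian noise with sd
    ``noise_sd_hu`` is added afterwards; the result is deterministic
    under a fixed ``seed``.

    Raises
    ------
    ValueError
        If the nodule (plus ``margin_mm``) does not fit in the grid,
        if in-plane spacing is not isotropic, or if z-spacing is
        outside the thin-section range [0.5, 1.0] mm.
    """
    sx, sy, sz = grid.spacing_mm
    if not np.isclose(sx, sy):
        raise ValueError(f"in-plane spacing must be isotropic, got ({sx}, {sy})")
    if not (0.5 - 1e-9 <= sz <= 1.0 + 1e-9):
        raise ValueError(f"thin-section z-spacing must be in [0.5, 1.0] mm, got {sz}")
    semi_total = spec.semi_axes_mm(spec.total_diameter_mm)
    ax = grid.coordinate_axes_mm()
    for a in range(3):
        lo_edge = ax[a][0] - grid.spacing_mm[a] / 2.0
        hi_edge = ax[a][-1] + grid.spacing_mm[a] / 2.0
        if (
            spec.center_mm[a] - semi_total[a] - margin_mm < lo_edge
            or spec.center_mm[a] + semi_total[a] + margin_mm > hi_edge
        ):
            raise ValueError(
                f"nodule (diameter {spec.total_diameter_mm} mm + {margin_mm} mm "
                f"margin) exceeds grid extent along axis {a}"
            )

    frac_total = _ellipsoid_fraction(grid, spec.center_mm, semi_total, supersample)
    frac_solid = _ellipsoid_fraction(
        grid,
        spec.center_mm,
        spec.semi_axes_mm(spec.solid_diameter_mm),
        supersample,
    )
    hu = (
        spec.lung_hu
        + (spec.ggo_hu - spec.lung_hu) * frac_total
        + (spec.solid_hu - spec.ggo_hu) * frac_solid
    )
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)
    volume = grid.with_voxels(hu.astype(np.float32))
    truth = NoduleGroundTruth(
        spec=spec,
        true_total_mm=spec.total_diameter_mm,
        true_solid_mm=spec.solid_diameter_mm,
        invasive_size_mm=spec.solid_diameter_mm,
    )
    return volume, truth


@dataclass(frozen=True)
class CohortParams:
    """Distribution settings for :func:`generate_cohort`.

    Defaults emulate the reference population: type proportions
    27/55/11 over 93, solid size truncated-normal (11.3, 9.6) on
    (0, 36], total size truncated-normal (19.6, 9.1) on [5, 45], and an
    invasive-size pathology proxy = solid + N(2.4, 3^2) floored at 0.
    """

    type_proportions: tuple[float, float, float] = (27 / 93, 55 / 93, 11 / 93)
    solid_mean_mm: float = 11.3
    solid_sd_mm: float = 9.6
    solid_bounds_mm: tuple[float, float] = (0.0, 36.0)
    total_mean_mm: float = 19.6
    total_sd_mm: float = 9.1
    total_bounds_mm: tuple[float, float] = (5.0, 45.0)
    invasive_bias_mm: float = 2.4
    invasive_sd_mm: float = 3.0
    noise_sd_hu: float = 20.0
    # craniocaudal-to-in-plane axis ratio (1 = sphere); nodules are
    # drawn with random z-elongation so the maximal diameter is not
    # always axial and craniocaudal resolution matters
    elongation_range: tuple[float, float] = (0.8, 1.5)

    def __post_init__(self) -> None:
        p = self.type_proportions
        if len(p) != 3 or any(x < 0 for x in p) or not np.isclose(sum(p), 1.0):
            raise ValueError(f"type_proportions must be >= 0 and sum to 1, got {p}")
        for name, (lo, hi) in (
            ("solid_bounds_mm", self.solid_bounds_mm),
            ("total_bounds_mm", self.total_bounds_mm),
        ):
            if lo >= hi:
                raise ValueError(f"{name} must satisfy lo < hi, got ({lo}, {hi})")
        if self.solid_sd_mm <= 0 or self.total_sd_mm <= 0:
            raise ValueError("size sds must be positive")
        elo, ehi = self.elongation_range
        if elo <= 0 or elo > ehi:
            raise ValueError(
                f"elongation_range must satisfy 0 < lo <= hi, got {self.elongation_range}"
            )


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Analytic mean of a normal truncated (renormalised) to [lo, hi]."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(mean + sd * stats.norm.ppf(u))


def generate_cohort(
    n: int,
    cohort_params: CohortParams | None = None,
    seed: int = 0,
) -> list[NoduleGroundTruth]:
    """Draw ``n`` nodule specs + ground truths from the cohort model.

    Types are multinomial with the configured proportions.  Pure
    ground-glass nodules get solid size 0; solid nodules get
    solid == total; part-solid nodules draw solid from the solid-size
    truncated normal and total from the total-size truncated normal
    constrained to total > solid.  ``invasive_size_mm`` is
    solid + N(bias, sd^2), floored at 0.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    p = cohort_params or CohortParams()
    rng = np.random.default_rng(seed)
    type_order = (NoduleType.SOLID, NoduleType.PART_SOLID, NoduleType.PURE_GGN)
    type_idx = rng.choice(3, size=n, p=list(p.type_proportions))
    out: list[NoduleGroundTruth] = []
    slo, shi = p.solid_bounds_mm
    tlo, thi = p.total_bounds_mm
    for ti in type_idx:
        t = type_order[ti]
        if t is NoduleType.PURE_GGN:
            solid = 0.0
            total = _draw_truncnorm(rng, p.total_mean_mm, p.total_sd_mm, tlo, thi)
        elif t is NoduleType.SOLID:
            solid = _draw_truncnorm(
                rng, p.solid_mean_mm, p.solid_sd_mm, max(slo, 1e-3), shi
            )
            total = solid
        else:
            solid = _draw_truncnorm(
                rng, p.solid_mean_mm, p.solid_sd_mm, max(slo, 1e-3), shi
            )
            total = _draw_truncnorm(
                rng, p.total_mean_mm, p.total_sd_mm, max(tlo, solid + 0.5), thi
            )
        spec = NoduleSpec(
            nodule_type=t,
            total_diameter_mm=total,
            solid_diameter_mm=solid,
            center_mm=(0.0, 0.0, 0.0),
            noise_sd_hu=p.noise_sd_hu,
            elongation_z=float(rng.uniform(*p.elongation_range)),
        )
        invasive = max(0.0, solid + rng.normal(p.invasive_bias_mm, p.invasive_sd_mm))
        out.append(
            NoduleGroundTruth(
                spec=spec,
                true_total_mm=total,
                true_solid_mm=solid,
                invasive_size_mm=invasive,
            )
        )
    return out


def write_ground_truth_table(
    truths: Sequence[NoduleGroundTruth], path: str | Path, seed: int | None = None
) -> None:
    """Write cohort ground truth as a comma-delimited table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "nodule_type", "total_mm", "solid_mm", "invasive_mm", "seed"])
        for i, t in enumerate(truths):
            w.writerow(
                [
                    i,
                    t.spec.nodule_type.value,
                    f"{t.true_total_mm:.4f}",
                    f"{t.true_solid_mm:.4f}",
                    f"{t.invasive_size_mm:.4f}",
                    "" if seed is None else seed,
                ]
            )
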