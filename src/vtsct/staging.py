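"""Clinical/pathological T-category assignment from nodule sizes.

Size-based categories for stage 0-I lung adenocarcinoma, eighth-edition
TNM size cut-points (5 / 10 / 20 / 30 / 40 mm, inclusive upper bounds):

* solid 0 and total <= 30 mm        -> Tis
* 0 < solid <= 5 mm and total <= 30 -> T1mi
* otherwise, by solid size: <= 10 -> T1a, <= 20 -> T1b, <= 30 -> T1c,
  <= 40 -> T2a
* solid 0 with total > 30 mm falls through to T1a (documented
  convention: staged by its zero solid component).

Pathological T uses the same table applied to (pathological total,
invasive) size.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = ["TCategory", "assign_t"]


class TCategory(IntEnum):
    """Ordered clinical T categories (Tis < T1mi < T1a < T1b < T1c < T2a)."""

    Tis = 0
    T1mi = 1
    T1a = 2
    T1b = 3
    T1c = 4
    T2a = 5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def assign_t(
    total_mm: float, solid_mm: float, max_total_mm: float = 40.0
) -> TCategory:
    """Map (total size, solid size) in mm to a T category.

    Parameters
    ----------
    max_total_mm : float
        Upper validity bound on total size (default 40 mm, the stage 0-I
        ceiling).  Larger cohorts may relax it; the category itself is
        driven by solid size.
    """
    if not (0 <= solid_mm <= total_mm + 1e-12):
        raise ValueError(
            f"need 0 <= solid_mm <= total_mm, got solid={solid_mm}, total={total_mm}"
        )
    if total_mm > max_total_mm + 1e-12:
        raise ValueError(
            f"total_mm ({total_mm}) exceeds the supported maximum ({max_total_mm})"
        )
    if solid_mm > 40.0 + 1e-12:
        raise ValueError(f"solid_mm ({solid_mm}) above the T2a cut-point (40 mm)")
    if solid_mm == 0 and total_mm <= 30.0:
        return TCategory.Tis
    if 0 < solid_mm <= 5.0 and total_mm <= 30.0:
        return TCategory.T1mi
    if solid_mm <= 10.0:
        return TCategory.T1a
    if solid_mm <= 20.0:
        return TCategory.T1b
    if solid_mm <= 30.0:
        return TCategory.T1c
    return TCategory.T2a
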