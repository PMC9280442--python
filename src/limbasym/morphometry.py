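"""Element lengths from landmark pairs and per-specimen bilateral measurements.

An element length is the Euclidean distance between its two defining landmarks,
rounded half-to-even to two decimal places (mm).  Rounding is applied exactly
once, here, and every downstream statistic consumes the rounded values — this
matters because specimens whose left and right lengths round to the same value
are classified as symmetric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmarks import ELEMENT_ROLES, SIDES, SpecimenLandmarkSet

__all__ = ["ElementMeasurement", "element_length", "measure_specimen", "EXCLUSION_REASONS"]

EXCLUSION_REASONS = ("none", "broken", "outlier_length", "outlier_asymmetry", "missing_side")


def round2(x: float) -> float:
    """Round to 2 decimal places, ties to even (numpy convention)."""
    return float(np.round(x, 2))


@dataclass
class ElementMeasurement:
    """Left and right lengths (mm) of one skeletal element on one specimen.

    Either length may be ``None`` when the corresponding side could not be
    measured.  ``excluded`` records always carry a reason other than ``"none"``.
    """

    taxon: str
    specimen_id: str
    element: str
    left_length: float | None
    right_length: float | None
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        for side, v in (("left", self.left_length), ("right", self.right_length)):
            if v is not None and v < 0:
                raise ValueError(f"{self.specimen_id}/{self.element}: negative {side} length {v}")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded and self.exclusion_reason == "none":
            raise ValueError("excluded measurement must carry an exclusion reason")

    @property
    def complete(self) -> bool:
        return self.left_length is not None and self.right_length is not None


def element_length(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Euclidean distance between two 3D points, rounded to 2 dp (mm)."""
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("points must be 3D")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinate in landmark point")
    return round2(float(np.linalg.norm(a - b)))


def measure_specimen(lset: SpecimenLandmarkSet) -> list[ElementMeasurement]:
    """One :class:`ElementMeasurement` per element present on the specimen.

    An element measurable on both sides yields a complete record.  An element
    measurable on only one side is emitted excluded with reason
    ``missing_side``.  A specimen flagged broken (from the metadata sidecar —
    the landmark file cannot express breakage) has all its records excluded
    with reason ``broken``.  A specimen with no measurable sides yields an
    empty list and a warning.
    """
    out: list[ElementMeasurement] = []
    for element in lset.elements_present():
        lengths: dict[str, float | None] = {}
        for side in SIDES:
            if lset.measurable(element, side):
                a, b = lset.side_points(element, side)
                lengths[side] = element_length(a.coords, b.coords)
            else:
                lengths[side] = None
        if lengths["left"] is None and lengths["right"] is None:
            continue
        if lset.broken:
            excluded, reason = True, "broken"
        elif lengths["left"] is None or lengths["right"] is None:
            excluded, reason = True, "missing_side"
        else:
            excluded, reason = False, "none"
        out.append(
            ElementMeasurement(
                taxon=lset.taxon,
                specimen_id=lset.specimen_id,
                element=element,
                left_length=lengths["left"],
                right_length=lengths["right"],
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    if not out:
        warnings.warn(f"specimen {lset.specimen_id}: no measurable element-sides", stacklevel=2)
    return out
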