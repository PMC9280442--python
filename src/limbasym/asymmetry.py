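"""Signed percent asymmetry, direction classes, and 3-SD outlier screens.

Percent asymmetry (PA) for a bilateral element is

    PA = 100 * (right - left) / (right + left)

rounded to two decimal places; negative PA means the left side is larger.
Individuals whose PA rounds to 0.00 are "symmetric": they count toward N but
are uninformative for the left-versus-right frequency test.

Two quality screens operate on a per-taxon, per-element sample:

* a length screen flagging records whose left or right length lies more than
  3 sample SDs from its side's mean (sides are screened separately, since a
  real directional bias would inflate a pooled SD), and
* an optional post hoc screen on the PA values themselves, off by default
  because the primary analysis runs without it.

Both screens are single-pass: mean and SD come from all currently non-excluded
values, and flagging does not trigger re-estimation.  Flagged records are
excluded whole (both sides) — asymmetry needs both sides — but the same
specimen's other element is untouched.  Flagging is advisory: a human should
check flagged digitizations, and an override can un-exclude a record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .morphometry import ElementMeasurement, round2

__all__ = [
    "percent_asymmetry",
    "classify_direction",
    "AsymmetryRecord",
    "TaxonTraitSample",
    "flag_length_outliers",
    "flag_asymmetry_outliers",
    "build_samples",
]

LEFT_LARGER = "left_larger"
RIGHT_LARGER = "right_larger"
SYMMETRIC = "symmetric"


def percent_asymmetry(left: float, right: float) -> float:
    """Signed percent asymmetry, 100*(right-left)/(right+left), at 2 dp."""
    if left + right <= 0:
        raise ValueError(f"percent asymmetry undefined for left+right = {left + right}")
    return round2(100.0 * (right - left) / (right + left))


def classify_direction(pa: float) -> str:
    """Direction class of a rounded PA value: sign decides; 0.00 is symmetric."""
    if pa < 0:
        return LEFT_LARGER
    if pa > 0:
        return RIGHT_LARGER
    return SYMMETRIC


@dataclass
class AsymmetryRecord(ElementMeasurement):
    """An :class:`ElementMeasurement` annotated with PA and direction class."""

    percent_asymmetry: float | None = None
    direction: str | None = None

    @classmethod
    def from_measurement(cls, m: ElementMeasurement) -> "AsymmetryRecord":
        rec = cls(**vars(m))
        if m.complete:
            rec.percent_asymmetry = percent_asymmetry(m.left_length, m.right_length)
            rec.direction = classify_direction(rec.percent_asymmetry)
        return rec


@dataclass
class TaxonTraitSample:
    """All asymmetry records for one taxon x element: the unit of inference."""

    taxon: str
    element: str
    records: list[AsymmetryRecord] = field(default_factory=list)

    @property
    def active_records(self) -> list[AsymmetryRecord]:
        return [r for r in self.records if not r.excluded]

    @property
    def n_total(self) -> int:
        return len(self.active_records)

    @property
    def n_left_larger(self) -> int:
        return sum(r.direction == LEFT_LARGER for r in self.active_records)

    @property
    def n_right_larger(self) -> int:
        return sum(r.direction == RIGHT_LARGER for r in self.active_records)

    @property
    def n_symmetric(self) -> int:
        return sum(r.direction == SYMMETRIC for r in self.active_records)


def build_samples(records: Iterable[AsymmetryRecord]) -> dict[tuple[str, str], TaxonTraitSample]:
    """Group records into per-(taxon, element) samples, in first-seen order."""
    samples: dict[tuple[str, str], TaxonTraitSample] = {}
    for rec in records:
        key = (rec.taxon, rec.element)
        if key not in samples:
            samples[key] = TaxonTraitSample(taxon=rec.taxon, element=rec.element)
        samples[key].records.append(rec)
    return samples


def _flag_three_sd(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values strictly more than 3 sample SDs from the mean.

    Single pass: statistics come from all supplied values.  Fewer than 3
    values, or zero SD, flags nothing.
    """
    if values.size < 3:
        return np.zeros(values.shape, dtype=bool)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - values.mean()) > 3 * sd


def flag_length_outliers(sample: TaxonTraitSample) -> TaxonTraitSample:
    """Flag records whose left or right length is a 3-SD outlier within its side.

    Returns a new sample; flagged records are excluded with reason
    ``outlier_length``.
    """
    active = sample.active_records
    flagged_ids: set[int] = set()
    for attr in ("left_length", "right_length"):
        group = [(i, getattr(r, attr)) for i, r in enumerate(active) if getattr(r, attr) is not None]
        if not group:
            continue
        idx, vals = zip(*group)
        mask = _flag_three_sd(np.asarray(vals, dtype=float))
        flagged_ids.update(i for i, m in zip(idx, mask) if m)
    flagged = {id(active[i]) for i in flagged_ids}
    new_records = [
        replace(r, excluded=True, exclusion_reason="outlier_length") if id(r) in flagged else replace(r)
        for r in sample.records
    ]
    return TaxonTraitSample(taxon=sample.taxon, element=sample.element, records=new_records)


def flag_asymmetry_outliers(sample: TaxonTraitSample) -> TaxonTraitSample:
    """Flag records whose PA is a 3-SD outlier within the sample (post hoc screen).

    Off by default in the pipeline; returns a new sample with flagged records
    excluded, reason ``outlier_asymmetry``.
    """
    active = [r for r in sample.active_records if r.percent_asymmetry is not None]
    vals = np.asarray([r.percent_asymmetry for r in active], dtype=float)
    mask = _flag_three_sd(vals)
    flagged = {id(r) for r, m in zip(active, mask) if m}
    new_records = [
        replace(r, excluded=True, exclusion_reason="outlier_asymmetry") if id(r) in flagged else replace(r)
        for r in sample.records
    ]
    return TaxonTraitSample(taxon=sample.taxon, element=sample.element, records=new_records)
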