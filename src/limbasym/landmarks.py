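"""Reading, writing and anatomical mapping of MeshLab picked-points landmark files.

MeshLab exports digitized landmarks as ``*.pp`` files, a small XML dialect with
one ``<point>`` element per landmark carrying ``x``/``y``/``z`` coordinates (mm),
a free-text ``name`` and an ``active`` flag.  Digitizers conventionally
deactivate (rather than delete) misplaced points, so inactive points are parsed
but never mapped to anatomy.

Because exporters do not agree on a naming scheme, the mapping from landmark
names to anatomy — which skeletal element (pelvis or femur), which side (left
or right) and which end of the element — is driven by a small rule table
(:class:`LandmarkNamingConfig`) rather than hard-coded.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Union
from xml.etree import ElementTree as ET
from xml.sax.saxutils import quoteattr

__all__ = [
    "Landmark",
    "SpecimenLandmarkSet",
    "LandmarkNamingConfig",
    "PickedPointsError",
    "LandmarkConflictError",
    "parse_picked_points",
    "write_picked_points",
    "map_landmarks",
    "ELEMENT_ROLES",
]

#: Anatomical elements and the two landmark roles that define each one's length.
ELEMENT_ROLES: dict[str, tuple[str, str]] = {
    "pelvis": ("anterior", "posterior"),
    "femur": ("proximal", "distal"),
}

SIDES = ("left", "right")

_ROLE_ABBREV = {"anterior": "ant", "posterior": "post", "proximal": "prox", "distal": "dist"}


class PickedPointsError(ValueError):
    """Raised when a picked-points document cannot be parsed."""


class LandmarkConflictError(ValueError):
    """Raised when two landmarks map to the same (element, side, role) slot."""


@dataclass(frozen=True)
class Landmark:
    """One named 3D point (mm) digitized on a specimen surface."""

    name: str
    x: float
    y: float
    z: float
    active: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("landmark name must be non-empty")
        for axis, v in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not math.isfinite(v):
                raise ValueError(f"landmark {self.name!r}: non-finite {axis} coordinate")

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class SpecimenLandmarkSet:
    """All anatomically mapped landmarks of one specimen.

    ``assignments`` maps ``(element, side, role)`` to a :class:`Landmark`;
    ``unmatched`` lists landmark names no naming rule claimed (reported, never
    silently dropped).  An element-side is *measurable* when both of its roles
    are assigned, i.e. the element length can be computed on that side.
    """

    specimen_id: str
    taxon: str
    assignments: dict[tuple[str, str, str], Landmark] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)
    broken: bool = False

    def measurable(self, element: str, side: str) -> bool:
        return all((element, side, role) in self.assignments for role in ELEMENT_ROLES[element])

    def elements_present(self) -> list[str]:
        present = {el for (el, _, _) in self.assignments}
        return [el for el in ELEMENT_ROLES if el in present]

    def side_points(self, element: str, side: str) -> tuple[Landmark, Landmark]:
        r1, r2 = ELEMENT_ROLES[element]
        return self.assignments[(element, side, r1)], self.assignments[(element, side, r2)]


@dataclass(frozen=True)
class _NamingRule:
    pattern: re.Pattern
    element: str
    side: str
    role: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_ROLES:
            raise ValueError(f"unknown element {self.element!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.role not in ELEMENT_ROLES[self.element]:
            raise ValueError(
                f"role {self.role!r} invalid for element {self.element!r}; "
                f"expected one of {ELEMENT_ROLES[self.element]}"
            )


class LandmarkNamingConfig:
    """Ordered rule table mapping landmark names to (element, side, role).

    Each rule is a regular expression (matched against the full name,
    case-insensitively) plus the anatomical triple it resolves to.  The first
    matching rule wins; names matched by no rule are reported as unmatched.

    The text-file format is one rule per line, whitespace separated::

        # pattern            element side  role
        pelvis_L_ant         pelvis  left  anterior
        femur_R_dist.*       femur   right distal
    """

    def __init__(self, rules: Iterable[tuple[str, str, str, str]]):
        self.rules = [
            _NamingRule(re.compile(pat, re.IGNORECASE), element, side, role)
            for pat, element, side, role in rules
        ]

    def resolve(self, name: str) -> tuple[str, str, str] | None:
        for rule in self.rules:
            if rule.pattern.fullmatch(name):
                return (rule.element, rule.side, rule.role)
        return None

    @classmethod
    def default(cls) -> "LandmarkNamingConfig":
        """Naming scheme used by the synthetic generator: ``pelvis_L_ant`` etc."""
        rules = []
        for element, roles in ELEMENT_ROLES.items():
            for side, letter in (("left", "L"), ("right", "R")):
                for role in roles:
                    rules.append((f"{element}_{letter}_{_ROLE_ABBREV[role]}", element, side, role))
        return cls(rules)

    @classmethod
    def from_text(cls, text: str) -> "LandmarkNamingConfig":
        rules = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"naming config line {lineno}: expected 'pattern element side role', got {line!r}"
                )
            rules.append(tuple(parts))
        return cls(rules)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "LandmarkNamingConfig":
        return cls.from_text(Path(path).read_text())


def default_landmark_name(element: str, side: str, role: str) -> str:
    """Name for which :meth:`LandmarkNamingConfig.default` resolves (element, side, role)."""
    letter = {"left": "L", "right": "R"}[side]
    return f"{element}_{letter}_{_ROLE_ABBREV[role]}"


def _as_text(source: Union[str, Path, IO[str]]) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        # A string is document content if it looks like markup, else a path.
        if source.lstrip().startswith("<"):
            return source
        return Path(source).read_text()
    raise TypeError(f"cannot read picked points from {type(source)!r}")


def parse_picked_points(source: Union[str, Path, IO[str]]) -> list[Landmark]:
    """Parse a MeshLab picked-points document into a list of :class:`Landmark`.

    ``source`` may be a path, an open text stream, or the XML text itself.
    Unknown sibling elements (e.g. ``<DocumentData>``) and unknown attributes
    are tolerated and ignored; exporter versions vary.

    Raises :class:`PickedPointsError` for malformed XML (naming the line and
    column), for a point missing a coordinate attribute (naming the point), and
    for a document containing no landmarks.
    """
    text = _as_text(source)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        line, col = exc.position
        raise PickedPointsError(f"malformed picked-points XML at line {line}, column {col}: {exc}") from exc

    landmarks: list[Landmark] = []
    for i, point in enumerate(root.iter("point")):
        label = point.get("name") or f"<point #{i}>"
        coords = {}
        for axis in ("x", "y", "z"):
            raw = point.get(axis)
            if raw is None:
                raise PickedPointsError(f"point {label}: missing coordinate attribute {axis!r}")
            try:
                coords[axis] = float(raw)
            except ValueError as exc:
                raise PickedPointsError(f"point {label}: unparseable {axis}={raw!r}") from exc
        name = point.get("name")
        if not name:
            raise PickedPointsError(f"point #{i}: missing or empty name attribute")
        active = point.get("active", "1").strip() not in ("0", "false", "False")
        try:
            landmarks.append(Landmark(name=name, active=active, **coords))
        except ValueError as exc:
            raise PickedPointsError(f"point {name}: {exc}") from exc

    if not landmarks:
        raise PickedPointsError("no landmarks: document contains no point entries")
    return landmarks


def write_picked_points(landmarks: list[Landmark]) -> str:
    """Serialize landmarks to picked-points XML text.

    Coordinates are written with ``repr`` precision so that
    ``parse_picked_points(write_picked_points(L)) == L`` exactly.
    """
    if not landmarks:
        raise ValueError("cannot write an empty landmark list")
    buf = StringIO()
    buf.write("<!DOCTYPE PickedPoints>\n<PickedPoints>\n <DocumentData>\n")
    buf.write("  <DataFileName name=\"\"/>\n  <templateName name=\"\"/>\n </DocumentData>\n")
    for lm in landmarks:
        buf.write(
            " <point x={} y={} z={} active={} name={}/>\n".format(
                quoteattr(repr(lm.x)),
                quoteattr(repr(lm.y)),
                quoteattr(repr(lm.z)),
                quoteattr("1" if lm.active else "0"),
                quoteattr(lm.name),
            )
        )
    buf.write("</PickedPoints>\n")
    return buf.getvalue()


def map_landmarks(
    landmarks: list[Landmark],
    config: LandmarkNamingConfig,
    specimen_id: str,
    taxon: str = "",
    broken: bool = False,
) -> SpecimenLandmarkSet:
    """Assign named landmarks to anatomical slots per the naming config.

    Inactive landmarks are skipped.  Two active landmarks resolving to the same
    slot raise :class:`LandmarkConflictError`.  Names no rule matches are
    collected in ``unmatched``.  A specimen with zero measurable element-sides
    triggers a warning, not an error (it is excluded downstream).
    """
    out = SpecimenLandmarkSet(specimen_id=specimen_id, taxon=taxon, broken=broken)
    for lm in landmarks:
        if not lm.active:
            continue
        triple = config.resolve(lm.name)
        if triple is None:
            out.unmatched.append(lm.name)
            continue
        if triple in out.assignments:
            raise LandmarkConflictError(
                f"specimen {specimen_id}: landmarks {out.assignments[triple].name!r} and "
                f"{lm.name!r} both map to {triple}"
            )
        out.assignments[triple] = lm
    if not any(out.measurable(el, side) for el in ELEMENT_ROLES for side in SIDES):
        warnings.warn(
            f"specimen {specimen_id}: no measurable element-sides after mapping",
            stacklevel=2,
        )
    return out
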