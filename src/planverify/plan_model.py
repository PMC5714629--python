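"""Canonical in-memory representation of a radiotherapy treatment plan.

The model abstracts away source-database schema differences: a plan pulled
from any treatment-management-system (TMS) version is normalised into the
same set of types so that two versions of the same plan can be compared
parameter for parameter.

Design notes
------------
* Angles are normalised on ingest to ``[0, 360)`` degrees; the raw source
  text can be retained on the owning object (``raw`` mapping) so reports can
  show what the database actually held.
* ``couch_position`` is optional rather than zero-filled: a migration can
  *delete* the couch position, which is a different defect from a couch at
  the origin, and the model must be able to represent both.
* Validation never raises: migrated plans may be corrupt by design, and the
  whole point of this package is to detect and report that corruption.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

__all__ = [
    "PlanKey",
    "PlanStatus",
    "CourseStatus",
    "JawSetting",
    "ControlPoint",
    "TreatmentField",
    "Plan",
    "Violation",
    "normalize_angle",
    "validate_plan",
]


def normalize_angle(angle: float) -> float:
    """Normalise an angle in degrees to the half-open interval [0, 360).

    Idempotent: ``normalize_angle(normalize_angle(a)) == normalize_angle(a)``,
    and 360.0 maps to 0.0.
    """
    a = float(angle) % 360.0
    # Python's % can return 360.0 - eps == 360.0 after rounding for negative
    # inputs extremely close to a multiple of 360; clamp defensively.
    if a >= 360.0:
        a = 0.0
    return a


@dataclass(frozen=True, order=True)
class PlanKey:
    """Identity triple of a plan: patient / course / plan."""

    patient_id: str
    course_id: str
    plan_id: str

    def render(self) -> str:
        """Canonical human-readable form, e.g. ``none / C1 / 1.1-1 HN``."""
        return f"{self.patient_id} / {self.course_id} / {self.plan_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


class PlanStatus(enum.Enum):
    """Approval status of a plan in the TMS.

    Unknown source strings are carried through ``OTHER`` plus the raw text on
    the plan (migration QA must ingest anything the database holds).
    """

    UNAPPROVED = "Unapproved"
    PLANNING_APPROVED = "PlanningApproved"
    TREATMENT_APPROVED = "TreatmentApproved"
    COMPLETED = "Completed"
    OTHER = "Other"

    @classmethod
    def from_string(cls, text: str) -> "PlanStatus":
        cleaned = text.strip().replace(" ", "")
        for member in cls:
            if member.value.lower() == cleaned.lower():
                return member
        return cls.OTHER


class CourseStatus(enum.Enum):
    ACTIVE = "Active"
    INACTIVE = "Inactive"

    @classmethod
    def from_string(cls, text: str) -> "CourseStatus":
        return cls.ACTIVE if text.strip().lower() == "active" else cls.INACTIVE


@dataclass(frozen=True)
class JawSetting:
    """The four primary collimator (jaw) edges in cm, collimator coordinates.

    Convention: x1 <= x2 and y1 <= y2 (x1/y1 are the negative-side edges).
    """

    x1: float
    x2: float
    y1: float
    y2: float


@dataclass(frozen=True)
class ControlPoint:
    """One snapshot of MLC state in a delivery sequence.

    ``bank_a`` and ``bank_b`` hold paired leaf positions in cm under the
    convention that, for each leaf pair ``i``, ``bank_a[i] <= bank_b[i]``
    (bank A approaches from the negative side; equality is a closed leaf
    pair).  ``meterset_weight`` is the cumulative fraction of the field
    meterset delivered at this control point, in [0, 1], optional because
    static MLC shapes carry no meterset axis.
    """

    index: int
    bank_a: tuple[float, ...]
    bank_b: tuple[float, ...]
    meterset_weight: Optional[float] = None


@dataclass
class TreatmentField:
    """One treatment beam: machine, geometry and delivery parameters."""

    field_id: str
    field_name: str = ""
    machine_id: str = ""
    field_type: str = "Static"
    technique: str = ""
    energy: str = ""
    mode: str = ""
    dose_rate: Optional[float] = None
    monitor_units: float = 0.0
    treatment_time: Optional[float] = None
    gantry_angle: float = 0.0
    collimator_rotation: float = 0.0
    couch_angle: float = 0.0
    couch_position: Optional[tuple[float, float, float]] = None
    ssd: Optional[float] = None
    tolerance_table: str = ""
    jaws: Optional[JawSetting] = None
    slotted_accessories: frozenset[str] = dc_field(default_factory=frozenset)
    other_accessories: frozenset[str] = dc_field(default_factory=frozenset)
    control_points: tuple[ControlPoint, ...] = ()
    patient_orientation: str = ""  # unused at field level; see Plan

    def __post_init__(self) -> None:
        self.gantry_angle = normalize_angle(self.gantry_angle)
        self.collimator_rotation = normalize_angle(self.collimator_rotation)
        self.couch_angle = normalize_angle(self.couch_angle)
        self.slotted_accessories = frozenset(self.slotted_accessories)
        self.other_accessories = frozenset(self.other_accessories)
        self.control_points = tuple(self.control_points)


@dataclass
class Plan:
    """A radiotherapy plan: identity, status and an ordered field sequence.

    The field sequence may be empty — a migrated plan stripped of all its
    fields must still be representable so that the loss is detectable.
    """

    key: PlanKey
    plan_status: PlanStatus = PlanStatus.UNAPPROVED
    plan_status_text: str = ""  # raw source string, kept for reporting
    course_status: CourseStatus = CourseStatus.ACTIVE
    patient_orientation: str = "HFS"
    fields: list[TreatmentField] = dc_field(default_factory=list)

    def field_by_id(self, field_id: str) -> TreatmentField:
        for f in self.fields:
            if f.field_id == field_id:
                return f
        raise KeyError(field_id)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_plan`."""

    path: str
    message: str

    def __str__(self) -> str:
        return f"{self.path}: {self.message}"


def validate_plan(plan: Plan) -> list[Violation]:
    """Report every invariant violation in *plan*; empty list means valid.

    Never raises on bad data: validation is a report, because migrated plans
    may be corrupt by design and corruption is exactly what must surface.
    """
    out: list[Violation] = []

    for name, value in (
        ("patient_id", plan.key.patient_id),
        ("course_id", plan.key.course_id),
        ("plan_id", plan.key.plan_id),
    ):
        if not value:
            out.append(Violation("plan.key", f"{name} is empty"))

    seen: set[str] = set()
    for f in plan.fields:
        if f.field_id in seen:
            out.append(
                Violation(f"field[{f.field_id}]", "duplicate field_id")
            )
        seen.add(f.field_id)

    for f in plan.fields:
        loc = f"field[{f.field_id}]"
        if f.monitor_units < 0:
            out.append(Violation(loc, f"monitor_units < 0 ({f.monitor_units})"))
        if f.treatment_time is not None and f.treatment_time < 0:
            out.append(
                Violation(loc, f"treatment_time < 0 ({f.treatment_time})")
            )
        if f.ssd is not None and f.ssd <= 0:
            out.append(Violation(loc, f"ssd <= 0 ({f.ssd})"))
        for angle_name in ("gantry_angle", "collimator_rotation", "couch_angle"):
            a = getattr(f, angle_name)
            if not (0.0 <= a < 360.0):
                out.append(
                    Violation(loc, f"{angle_name} not normalised to [0,360) ({a})")
                )
        if f.jaws is not None:
            if f.jaws.x1 > f.jaws.x2:
                out.append(Violation(loc, f"jaws x1 > x2 ({f.jaws.x1} > {f.jaws.x2})"))
            if f.jaws.y1 > f.jaws.y2:
                out.append(Violation(loc, f"jaws y1 > y2 ({f.jaws.y1} > {f.jaws.y2})"))
        out.extend(_validate_control_points(loc, f.control_points))

    return out


def _validate_control_points(
    loc: str, cps: Sequence[ControlPoint]
) -> list[Violation]:
    out: list[Violation] = []
    leaf_count: Optional[int] = None
    prev_index = -1
    for cp in cps:
        cploc = f"{loc}.cp[{cp.index}]"
        if cp.index <= prev_index:
            out.append(
                Violation(cploc, f"control point index not strictly increasing")
            )
        prev_index = cp.index
        if len(cp.bank_a) != len(cp.bank_b):
            out.append(
                Violation(
                    cploc,
                    f"bank length mismatch (A={len(cp.bank_a)}, B={len(cp.bank_b)})",
                )
            )
            continue
        if leaf_count is None:
            leaf_count = len(cp.bank_a)
        elif len(cp.bank_a) != leaf_count:
            out.append(
                Violation(
                    cploc,
                    f"leaf count {len(cp.bank_a)} differs from field's {leaf_count}",
                )
            )
        for i, (a, b) in enumerate(zip(cp.bank_a, cp.bank_b)):
            if a > b:
                out.append(
                    Violation(cploc, f"leaf pair {i} overlaps past closure ({a} > {b})")
                )
        if cp.meterset_weight is not None and not (0.0 <= cp.meterset_weight <= 1.0):
            out.append(
                Violation(cploc, f"meterset_weight outside [0,1] ({cp.meterset_weight})")
            )
    return out
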