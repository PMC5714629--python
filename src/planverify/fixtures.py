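"""Synthetic plan corpora and the mutation suite.

This module stands in for a clinical TMS database.  It generates valid,
realistic-looking external-beam plans (static photon/electron fields and
dynamic IMRT fields with full MLC control-point sequences) and applies the
kinds of damage a faulty database migration can cause: changed energies and
modes, shifted or deleted couch data, deleted or swapped MLC sequences,
perturbed leaves, monitor units, jaws and angles, and flipped patient
orientation.  Each mutation is a deep-copy edit localised to one target
field (patient orientation, a plan-level parameter, is the one exception),
so detection tests can assert exact localisation.

The machine catalogue (energies, wedges, electron cones, add-on
accessories) is configurable; the shipped default holds typical dual-energy
linac values.
"""

from __future__ import annotations

import copy
import enum
import random
from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import yaml

from .plan_io import PlanDocument
from .plan_model import (
    ControlPoint,
    CourseStatus,
    JawSetting,
    Plan,
    PlanKey,
    PlanStatus,
    TreatmentField,
    normalize_angle,
)

__all__ = [
    "MachineCatalogue",
    "MutationKind",
    "MutationSpec",
    "generate_field",
    "generate_plan",
    "generate_corpus",
    "generate_one_of_everything",
    "apply_mutation",
    "apply_mutations",
    "random_mutation",
    "perturb_within_tolerance",
    "make_demo_plan",
    "table2_mutations",
    "make_demo_mutant",
    "SUPRA_TOLERANCE_DELTA",
    "SUB_TOLERANCE_DELTA",
]

# default probe magnitudes relative to the 0.1 linear tolerances
SUPRA_TOLERANCE_DELTA = 0.2
SUB_TOLERANCE_DELTA = 0.05


@dataclass
class MachineCatalogue:
    """Energies, wedges, cones and accessories available on the machines."""

    machines: list[str] = dc_field(default_factory=lambda: ["LINAC1", "LINAC2"])
    photon_energies: list[str] = dc_field(default_factory=lambda: ["6X", "16X"])
    electron_energies: list[str] = dc_field(
        default_factory=lambda: ["6E", "9E", "12E", "16E", "20E"]
    )
    wedges: list[str] = dc_field(
        default_factory=lambda: ["W15", "W30", "W45", "W60"]
    )
    cones: list[str] = dc_field(
        default_factory=lambda: ["A6", "A10", "A14", "A20", "A25"]
    )
    accessories: list[str] = dc_field(
        default_factory=lambda: ["BLOCK_TRAY", "BOLUS_1CM"]
    )
    tolerance_tables: list[str] = dc_field(default_factory=lambda: ["T1", "T2", "IMRT"])
    dose_rates: list[float] = dc_field(default_factory=lambda: [300.0, 400.0, 600.0])

    @classmethod
    def default(cls) -> "MachineCatalogue":
        return cls()

    @classmethod
    def load(cls, path) -> "MachineCatalogue":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                fh,
                sort_keys=False,
            )


# ---------------------------------------------------------------------------
# generation

_ORIENTATIONS = ["HFS", "HFP", "FFS", "FFP"]


def _round1(x: float) -> float:
    return round(x, 1)


def generate_field(
    rng: random.Random,
    field_id: str,
    technique: str = "static",
    catalogue: Optional[MachineCatalogue] = None,
    n_control_points: Optional[int] = None,
    n_leaf_pairs: Optional[int] = None,
) -> TreatmentField:
    """One synthetic treatment field; ``technique`` is static/imrt/electron."""
    cat = catalogue or MachineCatalogue.default()
    gantry = _round1(rng.uniform(0.0, 359.9))
    collimator = _round1(rng.uniform(0.0, 359.9))
    couch = _round1(rng.uniform(350.0, 370.0))  # near-zero couch kicks
    xa, xb = _round1(rng.uniform(1.0, 10.0)), _round1(rng.uniform(1.0, 10.0))
    ya, yb = _round1(rng.uniform(1.0, 10.0)), _round1(rng.uniform(1.0, 10.0))

    if technique == "electron":
        energy = rng.choice(cat.electron_energies)
        mode = "Electron"
        slotted = frozenset({rng.choice(cat.cones)} if cat.cones else ())
        field_type, tech_label = "Static", "STATIC"
        cps: tuple[ControlPoint, ...] = ()
    elif technique == "imrt":
        energy = rng.choice(cat.photon_energies)
        mode = "Photon"
        slotted = frozenset()
        field_type, tech_label = "Dynamic", "IMRT"
        cps = _generate_mlc_sequence(
            rng,
            n_control_points or rng.randint(4, 12),
            n_leaf_pairs or rng.choice([40, 60]),
        )
    else:
        energy = rng.choice(cat.photon_energies)
        mode = "Photon"
        slotted = (
            frozenset({rng.choice(cat.wedges)})
            if cat.wedges and rng.random() < 0.4
            else frozenset()
        )
        field_type, tech_label = "Static", "STATIC"
        cps = ()

    other = (
        frozenset({rng.choice(cat.accessories)})
        if cat.accessories and rng.random() < 0.3
        else frozenset()
    )
    couch_position = None
    if rng.random() < 0.8:
        couch_position = (
            _round1(rng.uniform(-5.0, 5.0)),
            _round1(rng.uniform(-5.0, 5.0)),
            _round1(rng.uniform(-20.0, 20.0)),
        )
    mu = _round1(rng.uniform(50.0, 300.0))
    dose_rate = rng.choice(cat.dose_rates)
    return TreatmentField(
        field_id=field_id,
        field_name=f"Field {field_id}",
        machine_id=rng.choice(cat.machines),
        field_type=field_type,
        technique=tech_label,
        energy=energy,
        mode=mode,
        dose_rate=dose_rate,
        monitor_units=mu,
        treatment_time=round(mu / dose_rate + 0.2, 1),
        gantry_angle=gantry,
        collimator_rotation=collimator,
        couch_angle=couch,
        couch_position=couch_position,
        ssd=_round1(rng.uniform(80.0, 110.0)),
        tolerance_table=rng.choice(cat.tolerance_tables),
        jaws=JawSetting(x1=-xa, x2=xb, y1=-ya, y2=yb),
        slotted_accessories=slotted,
        other_accessories=other,
        control_points=cps,
    )


def _generate_mlc_sequence(
    rng: random.Random, n_cps: int, n_leaf_pairs: int
) -> tuple[ControlPoint, ...]:
    cps = []
    for i in range(n_cps):
        bank_a, bank_b = [], []
        for _ in range(n_leaf_pairs):
            center = round(rng.uniform(-8.0, 8.0), 2)
            gap = round(rng.uniform(0.0, 4.0), 2)
            a = round(center - gap / 2.0, 2)
            b = round(center + gap / 2.0, 2)
            bank_a.append(min(a, b))
            bank_b.append(max(a, b))
        weight = 0.0 if n_cps == 1 else round(i / (n_cps - 1), 4)
        cps.append(
            ControlPoint(
                index=i,
                bank_a=tuple(bank_a),
                bank_b=tuple(bank_b),
                meterset_weight=weight,
            )
        )
    return tuple(cps)


def generate_plan(
    seed: int,
    n_fields: int = 4,
    technique_mix: Sequence[str] = ("static", "imrt", "electron"),
    catalogue: Optional[MachineCatalogue] = None,
    key: Optional[PlanKey] = None,
    plan_status: Optional[PlanStatus] = None,
    course_status: Optional[CourseStatus] = None,
) -> Plan:
    """A reproducible synthetic plan: same seed, same plan, always."""
    rng = random.Random(seed)
    fields = []
    for i in range(n_fields):
        technique = technique_mix[i % len(technique_mix)]
        gantry_tag = int(rng.uniform(0, 360))
        fields.append(
            generate_field(rng, f"{i + 1}-G{gantry_tag:03d}", technique, catalogue)
        )
    if plan_status is None:
        plan_status = rng.choice(
            [
                PlanStatus.UNAPPROVED,
                PlanStatus.PLANNING_APPROVED,
                PlanStatus.TREATMENT_APPROVED,
                PlanStatus.COMPLETED,
            ]
        )
    if course_status is None:
        course_status = (
            CourseStatus.ACTIVE if rng.random() < 0.8 else CourseStatus.INACTIVE
        )
    return Plan(
        key=key or PlanKey(f"PT{seed % 100000:05d}", "C1", f"P{seed}"),
        plan_status=plan_status,
        plan_status_text=plan_status.value,
        course_status=course_status,
        patient_orientation=rng.choice(_ORIENTATIONS),
        fields=fields,
    )


def generate_corpus(
    seed: int,
    n_plans: int,
    source_system: str = "reference-db",
    max_fields: int = 5,
    catalogue: Optional[MachineCatalogue] = None,
) -> list[PlanDocument]:
    """A corpus of *n_plans* distinct synthetic plan documents."""
    rng = random.Random(seed)
    docs = []
    for i in range(n_plans):
        plan_seed = rng.randrange(2**31)
        key = PlanKey(f"PT{i:04d}", f"C{1 + i % 3}", f"{i}.1 Plan")
        plan = generate_plan(
            plan_seed,
            n_fields=1 + rng.randrange(max_fields),
            catalogue=catalogue,
            key=key,
        )
        docs.append(PlanDocument(plan=plan, source_system=source_system))
    return docs


def generate_one_of_everything(
    catalogue: Optional[MachineCatalogue] = None,
    fields_per_plan: int = 20,
) -> list[Plan]:
    """Plans enumerating every energy/wedge, energy/cone and accessory combo.

    Every combination from the catalogue appears in exactly one field: each
    photon energy with each wedge, each electron energy with each cone, and
    each add-on accessory once.  Used to exercise migration of the full
    machine configuration space.
    """
    cat = catalogue or MachineCatalogue.default()
    rng = random.Random(0)  # geometry is arbitrary; combination coverage is the point
    fields: list[TreatmentField] = []
    i = 0
    for energy in cat.photon_energies:
        for wedge in cat.wedges:
            i += 1
            f = generate_field(rng, f"OOE-{i}", "static", cat)
            fields.append(
                replace_field(f, energy=energy, mode="Photon",
                              slotted_accessories=frozenset({wedge}),
                              other_accessories=frozenset())
            )
    for energy in cat.electron_energies:
        for cone in cat.cones:
            i += 1
            f = generate_field(rng, f"OOE-{i}", "electron", cat)
            fields.append(
                replace_field(f, energy=energy, mode="Electron",
                              slotted_accessories=frozenset({cone}),
                              other_accessories=frozenset())
            )
    for acc in cat.accessories:
        i += 1
        f = generate_field(rng, f"OOE-{i}", "static", cat)
        fields.append(
            replace_field(f, slotted_accessories=frozenset(),
                          other_accessories=frozenset({acc}))
        )

    plans: list[Plan] = []
    for start in range(0, len(fields), fields_per_plan):
        chunk = fields[start:start + fields_per_plan]
        plans.append(
            Plan(
                key=PlanKey("QA", "QA1", f"OneOfEverything-{len(plans) + 1}"),
                plan_status=PlanStatus.TREATMENT_APPROVED,
                plan_status_text="Treatment Approved",
                course_status=CourseStatus.ACTIVE,
                patient_orientation="HFS",
                fields=chunk,
            )
        )
    return plans


def replace_field(f: TreatmentField, **kwargs) -> TreatmentField:
    return replace(f, **kwargs)


# ---------------------------------------------------------------------------
# mutations


class MutationKind(enum.Enum):
    CHANGE_ENERGY = "ChangeEnergy"
    CHANGE_MODE = "ChangeMode"
    SHIFT_COUCH_POSITION = "ShiftCouchPosition"
    SHIFT_COUCH_ANGLE = "ShiftCouchAngle"
    DELETE_COUCH_POSITION = "DeleteCouchPosition"
    DELETE_MLC_SEQUENCE = "DeleteMLCSequence"
    ATTACH_FOREIGN_MLC_SEQUENCE = "AttachForeignMLCSequence"
    PERTURB_MLC_LEAF = "PerturbMLCLeaf"
    CHANGE_MONITOR_UNITS = "ChangeMonitorUnits"
    MODIFY_JAWS = "ModifyJaws"
    ZERO_GANTRY_AND_COLLIMATOR = "ZeroGantryAndCollimator"
    ROUND_SSD = "RoundSSD"
    CHANGE_ORIENTATION = "ChangeOrientation"
    SHIFT_GANTRY = "ShiftGantry"
    SHIFT_COLLIMATOR = "ShiftCollimator"


@dataclass(frozen=True)
class MutationSpec:
    """One planned plan modification, targeted at a single field.

    ``delta`` is in the parameter's native unit (cm, degrees, MU);
    ``cp_index``/``leaf_index`` locate an MLC leaf perturbation; ``edge``
    names a jaw (x1/x2/y1/y2); ``source_field_id`` names the field whose
    MLC sequence is attached for the foreign-sequence mutation.
    """

    kind: MutationKind
    target_field_id: str
    delta: float = SUPRA_TOLERANCE_DELTA
    cp_index: int = 0
    leaf_index: int = 0
    edge: str = "x1"
    source_field_id: Optional[str] = None

    def describe(self) -> str:
        extra = ""
        if self.kind is MutationKind.PERTURB_MLC_LEAF:
            extra = f" cp={self.cp_index} leaf={self.leaf_index} delta={self.delta}"
        elif self.kind is MutationKind.MODIFY_JAWS:
            extra = f" edge={self.edge} delta={self.delta}"
        elif self.kind in (
            MutationKind.SHIFT_COUCH_POSITION,
            MutationKind.SHIFT_COUCH_ANGLE,
            MutationKind.CHANGE_MONITOR_UNITS,
            MutationKind.SHIFT_GANTRY,
            MutationKind.SHIFT_COLLIMATOR,
        ):
            extra = f" delta={self.delta}"
        elif self.kind is MutationKind.ATTACH_FOREIGN_MLC_SEQUENCE:
            extra = f" source={self.source_field_id}"
        return f"{self.kind.value} @ {self.target_field_id}{extra}"


def apply_mutation(plan: Plan, spec: MutationSpec) -> Plan:
    """Return a deep copy of *plan* with exactly one mutation applied.

    All fields other than the target are bit-identical to the input.
    Raises ``KeyError`` when the target field does not exist.
    """
    mutated = copy.deepcopy(plan)
    field = mutated.field_by_id(spec.target_field_id)  # KeyError if absent
    k = spec.kind

    if k is MutationKind.CHANGE_ENERGY:
        field.energy = _different_energy(field.energy)
    elif k is MutationKind.CHANGE_MODE:
        field.mode = "Electron" if field.mode != "Electron" else "Photon"
    elif k is MutationKind.SHIFT_COUCH_POSITION:
        if field.couch_position is None:
            field.couch_position = (spec.delta, 0.0, 0.0)
        else:
            x, y, z = field.couch_position
            field.couch_position = (round(x + spec.delta, 4), y, z)
    elif k is MutationKind.SHIFT_COUCH_ANGLE:
        field.couch_angle = normalize_angle(field.couch_angle + spec.delta)
    elif k is MutationKind.DELETE_COUCH_POSITION:
        field.couch_position = None
    elif k is MutationKind.DELETE_MLC_SEQUENCE:
        field.control_points = ()
    elif k is MutationKind.ATTACH_FOREIGN_MLC_SEQUENCE:
        source_id = spec.source_field_id or _first_other_mlc_field(
            plan, spec.target_field_id
        )
        field.control_points = copy.deepcopy(
            plan.field_by_id(source_id).control_points
        )
    elif k is MutationKind.PERTURB_MLC_LEAF:
        field.control_points = _perturb_leaf(
            field.control_points, spec.cp_index, spec.leaf_index, spec.delta
        )
    elif k is MutationKind.CHANGE_MONITOR_UNITS:
        field.monitor_units = round(field.monitor_units + spec.delta, 4)
    elif k is MutationKind.MODIFY_JAWS:
        if field.jaws is None:
            raise ValueError(f"field {spec.target_field_id} has no jaws to modify")
        field.jaws = replace(
            field.jaws, **{spec.edge: round(getattr(field.jaws, spec.edge) + spec.delta, 4)}
        )
    elif k is MutationKind.ZERO_GANTRY_AND_COLLIMATOR:
        field.gantry_angle = 0.0
        field.collimator_rotation = 0.0
    elif k is MutationKind.ROUND_SSD:
        if field.ssd is not None:
            field.ssd = float(round(field.ssd))
    elif k is MutationKind.CHANGE_ORIENTATION:
        # plan-level parameter; the target field only anchors the spec
        order = _ORIENTATIONS
        current = mutated.patient_orientation
        mutated.patient_orientation = order[
            (order.index(current) + 1) % len(order)
        ] if current in order else order[0]
    elif k is MutationKind.SHIFT_GANTRY:
        field.gantry_angle = normalize_angle(field.gantry_angle + spec.delta)
    elif k is MutationKind.SHIFT_COLLIMATOR:
        field.collimator_rotation = normalize_angle(
            field.collimator_rotation + spec.delta
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown mutation kind {k}")
    return mutated


def apply_mutations(plan: Plan, specs: Sequence[MutationSpec]) -> Plan:
    for spec in specs:
        plan = apply_mutation(plan, spec)
    return plan


def _different_energy(current: str) -> str:
    cat = MachineCatalogue.default()
    pool = cat.photon_energies if current.endswith("X") else cat.electron_energies
    for candidate in pool:
        if candidate != current:
            return candidate
    return current + "?"


def _first_other_mlc_field(plan: Plan, exclude: str) -> str:
    for f in plan.fields:
        if f.field_id != exclude and f.control_points:
            return f.field_id
    raise ValueError("no other field with an MLC sequence to borrow from")


def _perturb_leaf(
    cps: tuple[ControlPoint, ...], cp_index: int, leaf_index: int, delta: float
) -> tuple[ControlPoint, ...]:
    if not cps:
        raise ValueError("field has no MLC control points to perturb")
    out = []
    for cp in cps:
        if cp.index == cp_index:
            bank_b = list(cp.bank_b)
            bank_b[leaf_index] = round(bank_b[leaf_index] + abs(delta), 4)
            cp = ControlPoint(
                index=cp.index,
                bank_a=cp.bank_a,
                bank_b=tuple(bank_b),
                meterset_weight=cp.meterset_weight,
            )
        out.append(cp)
    return tuple(out)


def random_mutation(
    plan: Plan, rng: random.Random, supra: bool = True
) -> MutationSpec:
    """Pick a mutation kind applicable to *plan* with a random target field."""
    delta = SUPRA_TOLERANCE_DELTA if supra else SUB_TOLERANCE_DELTA
    candidates: list[MutationSpec] = []
    mlc_fields = [f for f in plan.fields if f.control_points]
    for f in plan.fields:
        fid = f.field_id
        candidates.append(MutationSpec(MutationKind.CHANGE_ENERGY, fid))
        candidates.append(MutationSpec(MutationKind.CHANGE_MODE, fid))
        candidates.append(MutationSpec(MutationKind.SHIFT_COUCH_ANGLE, fid, delta=delta))
        candidates.append(MutationSpec(MutationKind.CHANGE_MONITOR_UNITS, fid, delta=delta))
        candidates.append(MutationSpec(MutationKind.SHIFT_GANTRY, fid, delta=delta))
        candidates.append(MutationSpec(MutationKind.SHIFT_COLLIMATOR, fid, delta=delta))
        candidates.append(MutationSpec(MutationKind.ZERO_GANTRY_AND_COLLIMATOR, fid))
        if f.couch_position is not None:
            candidates.append(
                MutationSpec(MutationKind.SHIFT_COUCH_POSITION, fid, delta=delta)
            )
            candidates.append(MutationSpec(MutationKind.DELETE_COUCH_POSITION, fid))
        if f.jaws is not None:
            candidates.append(
                MutationSpec(
                    MutationKind.MODIFY_JAWS,
                    fid,
                    delta=delta,
                    edge=rng.choice(["x1", "x2", "y1", "y2"]),
                )
            )
        if f.ssd is not None and abs(f.ssd - round(f.ssd)) > 0.1:
            candidates.append(MutationSpec(MutationKind.ROUND_SSD, fid))
        if f.control_points:
            cp = rng.choice(f.control_points)
            candidates.append(
                MutationSpec(
                    MutationKind.PERTURB_MLC_LEAF,
                    fid,
                    delta=delta,
                    cp_index=cp.index,
                    leaf_index=rng.randrange(len(cp.bank_b)),
                )
            )
            candidates.append(MutationSpec(MutationKind.DELETE_MLC_SEQUENCE, fid))
            if len(mlc_fields) > 1:
                source = rng.choice([g for g in mlc_fields if g.field_id != fid])
                candidates.append(
                    MutationSpec(
                        MutationKind.ATTACH_FOREIGN_MLC_SEQUENCE,
                        fid,
                        source_field_id=source.field_id,
                    )
                )
    if plan.fields:
        candidates.append(
            MutationSpec(MutationKind.CHANGE_ORIENTATION, plan.fields[0].field_id)
        )
    return rng.choice(candidates)


def perturb_within_tolerance(plan: Plan, delta: float = SUB_TOLERANCE_DELTA) -> Plan:
    """Shift every tolerance-governed numeric parameter of every field by *delta*.

    Used to probe sub-tolerance immunity: for ``delta`` strictly below the
    0.1 tolerances the perturbed plan must still compare clean against the
    original.
    """
    mutated = copy.deepcopy(plan)
    for f in mutated.fields:
        f.monitor_units = round(f.monitor_units + delta, 6)
        f.gantry_angle = normalize_angle(f.gantry_angle + delta)
        f.collimator_rotation = normalize_angle(f.collimator_rotation + delta)
        f.couch_angle = normalize_angle(f.couch_angle + delta)
        if f.treatment_time is not None:
            f.treatment_time = round(f.treatment_time + delta, 6)
        if f.ssd is not None:
            f.ssd = round(f.ssd + delta, 6)
        if f.couch_position is not None:
            f.couch_position = tuple(round(v + delta, 6) for v in f.couch_position)
        if f.jaws is not None:
            f.jaws = JawSetting(
                x1=round(f.jaws.x1 + delta, 6),
                x2=round(f.jaws.x2 + delta, 6),
                y1=round(f.jaws.y1 + delta, 6),
                y2=round(f.jaws.y2 + delta, 6),
            )
        if f.control_points:
            f.control_points = tuple(
                ControlPoint(
                    index=cp.index,
                    bank_a=tuple(round(v + delta, 6) for v in cp.bank_a),
                    bank_b=tuple(round(v + delta, 6) for v in cp.bank_b),
                    meterset_weight=cp.meterset_weight,
                )
                for cp in f.control_points
            )
    return mutated


# ---------------------------------------------------------------------------
# the worked demonstration plan and its mutant

_DEMO_KEY = PlanKey("none", "C1", "1.1-1 HN")


def make_demo_plan() -> Plan:
    """A seven-field head-and-neck-style plan used throughout the docs/tests.

    Field ids follow the convention ``<plan>-<number>-<label>``; fields 4-7
    are dynamic IMRT fields with MLC sequences, 1-3 static photon fields.
    """
    rng = random.Random(20130)
    cat = MachineCatalogue.default()

    def static(fid: str, gantry: float) -> TreatmentField:
        f = generate_field(rng, fid, "static", cat)
        f.gantry_angle = gantry
        return f

    def imrt(fid: str) -> TreatmentField:
        return generate_field(rng, fid, "imrt", cat, n_control_points=10, n_leaf_pairs=60)

    f1 = static("1.1-1-G250", 250.0)
    f1.collimator_rotation = 10.0
    f1.ssd = 92.4
    f2 = static("1.1-2-G110", 110.0)
    f2.couch_position = (1.5, -0.5, 12.0)
    f3 = static("1.1-3-G030", 30.0)
    fields = [f1, f2, f3, imrt("1.1-4-LAIO"), imrt("1.1-5-RSO"),
              imrt("1.1-6-RAIO"), imrt("1.1-7-SUP")]
    return Plan(
        key=_DEMO_KEY,
        plan_status=PlanStatus.TREATMENT_APPROVED,
        plan_status_text="Treatment Approved",
        course_status=CourseStatus.ACTIVE,
        patient_orientation="HFS",
        fields=fields,
    )


def table2_mutations() -> list[MutationSpec]:
    """The canonical artificial-difference suite applied to the demo plan.

    One field per failure mode, with ``1.1-3-G030`` and ``1.1-6-RAIO`` left
    untouched as negative controls: gantry/collimator zeroed plus SSD
    rounded, couch position deleted, MLC sequence deleted, a different
    field's MLC sequence attached, and IMRT jaws modified.
    """
    return [
        MutationSpec(MutationKind.ZERO_GANTRY_AND_COLLIMATOR, "1.1-1-G250"),
        MutationSpec(MutationKind.ROUND_SSD, "1.1-1-G250"),
        MutationSpec(MutationKind.DELETE_COUCH_POSITION, "1.1-2-G110"),
        MutationSpec(MutationKind.DELETE_MLC_SEQUENCE, "1.1-4-LAIO"),
        MutationSpec(
            MutationKind.ATTACH_FOREIGN_MLC_SEQUENCE,
            "1.1-5-RSO",
            source_field_id="1.1-6-RAIO",
        ),
        MutationSpec(MutationKind.MODIFY_JAWS, "1.1-7-SUP", delta=-0.5, edge="x1"),
    ]


def make_demo_mutant(plan: Optional[Plan] = None) -> Plan:
    return apply_mutations(plan or make_demo_plan(), table2_mutations())
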