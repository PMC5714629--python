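"""Read and write the canonical plan XML schema; import DICOM RT Plans.

The canonical XML document is the contract format of this package: every
source system is translated into it and all comparison happens on it.  The
writer is deterministic (same document -> byte-identical output) and numeric
serialisation is lossless, so a write/read round trip introduces no phantom
differences.

Schema sketch (see docs/methods.md for the full description)::

    <PlanDocument schema_version="1.0" source_system="...">
      <Plan>
        <Key patient_id=".." course_id=".." plan_id=".."/>
        <PlanStatus raw="Treatment Approved">TreatmentApproved</PlanStatus>
        <CourseStatus>Active</CourseStatus>
        <PatientOrientation>HFS</PatientOrientation>
        <Fields>
          <Field id="..">
            ... scalar elements ...
            <CouchPosition x=".." y=".." z=".."/>   <!-- omitted if absent -->
            <Jaws x1=".." x2=".." y1=".." y2=".."/>
            <SlottedAccessories><Accessory>..</Accessory></SlottedAccessories>
            <ControlPoints>
              <ControlPoint index="0" meterset_weight="0">
                <BankA>.. space-separated cm ..</BankA>
                <BankB>..</BankB>
              </ControlPoint>
            </ControlPoints>
          </Field>
        </Fields>
      </Plan>
    </PlanDocument>
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from lxml import etree

from .plan_model import (
    ControlPoint,
    CourseStatus,
    JawSetting,
    Plan,
    PlanKey,
    PlanStatus,
    TreatmentField,
)

__all__ = [
    "PlanDocument",
    "SCHEMA_VERSION",
    "PlanReadError",
    "PlanParseError",
    "SchemaVersionError",
    "SchemaContentError",
    "DicomImportError",
    "fmt_num",
    "write_plan_xml",
    "read_plan_xml",
    "import_dicom_rtplan",
]

SCHEMA_VERSION = "1.0"
_KNOWN_VERSIONS = {"1.0"}


class PlanReadError(Exception):
    """Base class for canonical-XML reading failures."""


class PlanParseError(PlanReadError):
    """Input is not well-formed XML; message names the offending line."""


class SchemaVersionError(PlanReadError):
    """Document declares a schema_version unknown to this reader."""


class SchemaContentError(PlanReadError):
    """Well-formed XML missing a mandatory element; message names the path."""


class DicomImportError(Exception):
    """DICOM input is not an RT Plan or lacks mandatory content."""


@dataclass
class PlanDocument:
    """One canonical plan document: schema tag, provenance, plan."""

    plan: Plan
    source_system: str = "unknown"
    schema_version: str = SCHEMA_VERSION


def fmt_num(x: float) -> str:
    """Render a number losslessly: shortest round-trip decimal, no trailing .0."""
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def _num(text: Optional[str], path: str) -> float:
    if text is None or text.strip() == "":
        raise SchemaContentError(f"missing numeric content at {path}")
    try:
        return float(text)
    except ValueError as exc:
        raise SchemaContentError(f"non-numeric content at {path}: {text!r}") from exc


# ---------------------------------------------------------------------------
# writer


def write_plan_xml(doc: PlanDocument) -> str:
    root = etree.Element(
        "PlanDocument",
        schema_version=doc.schema_version,
        source_system=doc.source_system,
    )
    plan_el = etree.SubElement(root, "Plan")
    p = doc.plan
    etree.SubElement(
        plan_el,
        "Key",
        patient_id=p.key.patient_id,
        course_id=p.key.course_id,
        plan_id=p.key.plan_id,
    )
    status_el = etree.SubElement(plan_el, "PlanStatus")
    status_el.text = p.plan_status.value
    if p.plan_status_text:
        status_el.set("raw", p.plan_status_text)
    etree.SubElement(plan_el, "CourseStatus").text = p.course_status.value
    etree.SubElement(plan_el, "PatientOrientation").text = p.patient_orientation
    fields_el = etree.SubElement(plan_el, "Fields")
    for f in p.fields:
        _write_field(fields_el, f)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _write_field(parent: etree._Element, f: TreatmentField) -> None:
    el = etree.SubElement(parent, "Field", id=f.field_id)

    def scalar(tag: str, text: str) -> None:
        etree.SubElement(el, tag).text = text

    scalar("FieldName", f.field_name)
    scalar("MachineID", f.machine_id)
    scalar("FieldType", f.field_type)
    scalar("Technique", f.technique)
    scalar("Energy", f.energy)
    scalar("Mode", f.mode)
    if f.dose_rate is not None:
        scalar("DoseRate", fmt_num(f.dose_rate))
    scalar("MonitorUnits", fmt_num(f.monitor_units))
    if f.treatment_time is not None:
        scalar("TreatmentTime", fmt_num(f.treatment_time))
    scalar("GantryAngle", fmt_num(f.gantry_angle))
    scalar("CollimatorRotation", fmt_num(f.collimator_rotation))
    scalar("CouchAngle", fmt_num(f.couch_angle))
    if f.couch_position is not None:
        cx, cy, cz = f.couch_position
        etree.SubElement(
            el, "CouchPosition", x=fmt_num(cx), y=fmt_num(cy), z=fmt_num(cz)
        )
    if f.ssd is not None:
        scalar("SSD", fmt_num(f.ssd))
    scalar("ToleranceTable", f.tolerance_table)
    if f.jaws is not None:
        etree.SubElement(
            el,
            "Jaws",
            x1=fmt_num(f.jaws.x1),
            x2=fmt_num(f.jaws.x2),
            y1=fmt_num(f.jaws.y1),
            y2=fmt_num(f.jaws.y2),
        )
    for tag, items in (
        ("SlottedAccessories", f.slotted_accessories),
        ("OtherAccessories", f.other_accessories),
    ):
        acc_el = etree.SubElement(el, tag)
        for item in sorted(items):
            etree.SubElement(acc_el, "Accessory").text = item
    cps_el = etree.SubElement(el, "ControlPoints")
    for cp in f.control_points:
        cp_el = etree.SubElement(cps_el, "ControlPoint", index=str(cp.index))
        if cp.meterset_weight is not None:
            cp_el.set("meterset_weight", fmt_num(cp.meterset_weight))
        etree.SubElement(cp_el, "BankA").text = " ".join(fmt_num(v) for v in cp.bank_a)
        etree.SubElement(cp_el, "BankB").text = " ".join(fmt_num(v) for v in cp.bank_b)


# ---------------------------------------------------------------------------
# reader


def read_plan_xml(text: str | bytes) -> PlanDocument:
    """Parse canonical plan XML; inverse of :func:`write_plan_xml`.

    Raises :class:`PlanParseError` on malformed XML (naming the line),
    :class:`SchemaVersionError` on an unknown schema_version, and
    :class:`SchemaContentError` on a missing mandatory element (naming the
    path).  Never returns a partial plan.
    """
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise PlanParseError(f"malformed XML: {exc}") from exc

    if root.tag != "PlanDocument":
        raise SchemaContentError(f"root element is {root.tag!r}, expected PlanDocument")
    version = root.get("schema_version")
    if version not in _KNOWN_VERSIONS:
        raise SchemaVersionError(f"unknown schema_version {version!r}")
    source = root.get("source_system") or ""
    if not source:
        raise SchemaContentError("PlanDocument/@source_system missing or empty")

    plan_el = _require(root, "Plan")
    key_el = _require(plan_el, "Key")
    key = PlanKey(
        patient_id=key_el.get("patient_id") or "",
        course_id=key_el.get("course_id") or "",
        plan_id=key_el.get("plan_id") or "",
    )
    status_el = _require(plan_el, "PlanStatus")
    plan = Plan(
        key=key,
        plan_status=PlanStatus.from_string(status_el.text or ""),
        plan_status_text=status_el.get("raw", ""),
        course_status=CourseStatus.from_string(
            _require(plan_el, "CourseStatus").text or ""
        ),
        patient_orientation=_require(plan_el, "PatientOrientation").text or "",
        fields=[_read_field(fe) for fe in _require(plan_el, "Fields")],
    )
    return PlanDocument(plan=plan, source_system=source, schema_version=version)


def _require(parent: etree._Element, tag: str) -> etree._Element:
    el = parent.find(tag)
    if el is None:
        raise SchemaContentError(f"missing mandatory element {parent.tag}/{tag}")
    return el


def _opt_text(parent: etree._Element, tag: str) -> str:
    el = parent.find(tag)
    return (el.text or "") if el is not None else ""


def _read_field(el: etree._Element) -> TreatmentField:
    fid = el.get("id") or ""
    path = f"Field[{fid}]"

    def opt_num(tag: str) -> Optional[float]:
        sub = el.find(tag)
        return None if sub is None else _num(sub.text, f"{path}/{tag}")

    couch: Optional[tuple[float, float, float]] = None
    couch_el = el.find("CouchPosition")
    if couch_el is not None:
        couch = tuple(
            _num(couch_el.get(ax), f"{path}/CouchPosition@{ax}") for ax in "xyz"
        )  # type: ignore[assignment]

    jaws: Optional[JawSetting] = None
    jaws_el = el.find("Jaws")
    if jaws_el is not None:
        jaws = JawSetting(
            *(_num(jaws_el.get(e), f"{path}/Jaws@{e}") for e in ("x1", "x2", "y1", "y2"))
        )

    def accessories(tag: str) -> frozenset[str]:
        sub = el.find(tag)
        if sub is None:
            return frozenset()
        return frozenset((a.text or "") for a in sub)

    cps: list[ControlPoint] = []
    cps_el = el.find("ControlPoints")
    if cps_el is not None:
        for cp_el in cps_el:
            idx = int(cp_el.get("index", "0"))
            mw_text = cp_el.get("meterset_weight")
            cps.append(
                ControlPoint(
                    index=idx,
                    bank_a=_read_bank(cp_el, "BankA", f"{path}/ControlPoint[{idx}]"),
                    bank_b=_read_bank(cp_el, "BankB", f"{path}/ControlPoint[{idx}]"),
                    meterset_weight=None if mw_text is None else float(mw_text),
                )
            )

    mu_el = _require(el, "MonitorUnits")
    return TreatmentField(
        field_id=fid,
        field_name=_opt_text(el, "FieldName"),
        machine_id=_opt_text(el, "MachineID"),
        field_type=_opt_text(el, "FieldType"),
        technique=_opt_text(el, "Technique"),
        energy=_opt_text(el, "Energy"),
        mode=_opt_text(el, "Mode"),
        dose_rate=opt_num("DoseRate"),
        monitor_units=_num(mu_el.text, f"{path}/MonitorUnits"),
        treatment_time=opt_num("TreatmentTime"),
        gantry_angle=_num(_require(el, "GantryAngle").text, f"{path}/GantryAngle"),
        collimator_rotation=_num(
            _require(el, "CollimatorRotation").text, f"{path}/CollimatorRotation"
        ),
        couch_angle=_num(_require(el, "CouchAngle").text, f"{path}/CouchAngle"),
        couch_position=couch,
        ssd=opt_num("SSD"),
        tolerance_table=_opt_text(el, "ToleranceTable"),
        jaws=jaws,
        slotted_accessories=accessories("SlottedAccessories"),
        other_accessories=accessories("OtherAccessories"),
        control_points=tuple(cps),
    )


def _read_bank(cp_el: etree._Element, tag: str, path: str) -> tuple[float, ...]:
    el = cp_el.find(tag)
    if el is None:
        raise SchemaContentError(f"missing mandatory element {path}/{tag}")
    text = el.text or ""
    return tuple(float(tok) for tok in text.split())


# ---------------------------------------------------------------------------
# DICOM import


def import_dicom_rtplan(source) -> PlanDocument:
    """Import a DICOM RT Plan into a canonical :class:`PlanDocument`.

    Best-effort and deliberately lossy: the canonical XML schema is the
    contract format, DICOM is an on-ramp for checking real plans.  Beams map
    to treatment fields (beam number -> field_id, nominal energy + modality
    -> energy/mode, beam limiting device positions -> jaws and MLC control
    points); the beam meterset is taken from the referenced fraction scheme
    when present.

    ``source`` is a pydicom ``Dataset``, a path, or a file-like object.
    """
    import pydicom
    from pydicom.dataset import Dataset

    if isinstance(source, Dataset):
        ds = source
    else:
        try:
            ds = pydicom.dcmread(source, force=True)
        except Exception as exc:  # pragma: no cover - defensive
            raise DicomImportError(f"unreadable DICOM input: {exc}") from exc

    modality = getattr(ds, "Modality", None)
    sop_class = str(getattr(ds, "SOPClassUID", ""))
    if modality != "RTPLAN" and "1.2.840.10008.5.1.4.1.1.481.5" not in sop_class:
        raise DicomImportError(
            f"not an RT Plan object (Modality={modality!r})"
        )
    if "BeamSequence" not in ds:
        raise DicomImportError("RT Plan has no BeamSequence")

    metersets = _metersets_by_beam(ds)
    fields = [_import_beam(beam, metersets) for beam in ds.BeamSequence]

    key = PlanKey(
        patient_id=str(getattr(ds, "PatientID", "")) or "unknown",
        course_id="C1",
        plan_id=str(getattr(ds, "RTPlanLabel", "")) or "imported",
    )
    plan = Plan(
        key=key,
        plan_status=PlanStatus.from_string(str(getattr(ds, "ApprovalStatus", ""))),
        patient_orientation=_dicom_orientation(ds),
        fields=fields,
    )
    return PlanDocument(plan=plan, source_system="dicom-import")


def _dicom_orientation(ds) -> str:
    try:
        setup = ds.PatientSetupSequence[0]
        return str(getattr(setup, "PatientPosition", "")) or "HFS"
    except (AttributeError, IndexError):
        return "HFS"


def _metersets_by_beam(ds) -> dict[int, float]:
    out: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            num = int(getattr(rb, "ReferencedBeamNumber", -1))
            mu = getattr(rb, "BeamMeterset", None)
            if num >= 0 and mu is not None:
                out[num] = float(mu)
    return out


def _import_beam(beam, metersets: dict[int, float]) -> TreatmentField:
    num = int(getattr(beam, "BeamNumber", 0))
    cps = list(getattr(beam, "ControlPointSequence", []))
    first = cps[0] if cps else None

    energy = ""
    gantry = collimator = couch = 0.0
    jaws: Optional[JawSetting] = None
    if first is not None:
        nominal = getattr(first, "NominalBeamEnergy", None)
        modality = str(getattr(beam, "RadiationType", "")).upper()
        if nominal is not None:
            suffix = "X" if modality == "PHOTON" else ("E" if modality == "ELECTRON" else "")
            energy = f"{fmt_num(float(nominal))}{suffix}"
        gantry = float(getattr(first, "GantryAngle", 0.0))
        collimator = float(getattr(first, "BeamLimitingDeviceAngle", 0.0))
        couch = float(getattr(first, "PatientSupportAngle", 0.0))
        jaws = _jaws_from_cp(first)

    mlc_cps: list[ControlPoint] = []
    for i, cp in enumerate(cps):
        leaves = _mlc_from_cp(cp)
        if leaves is None:
            continue
        bank_a, bank_b = leaves
        mw = getattr(cp, "CumulativeMetersetWeight", None)
        mlc_cps.append(
            ControlPoint(
                index=i,
                bank_a=bank_a,
                bank_b=bank_b,
                meterset_weight=None if mw is None else float(mw),
            )
        )

    return TreatmentField(
        field_id=str(num),
        field_name=str(getattr(beam, "BeamName", "")),
        machine_id=str(getattr(beam, "TreatmentMachineName", "")),
        field_type=str(getattr(beam, "BeamType", "")).title() or "Static",
        technique=str(getattr(beam, "BeamType", "")).title(),
        energy=energy,
        mode=str(getattr(beam, "RadiationType", "")).title(),
        monitor_units=metersets.get(num, 0.0),
        gantry_angle=gantry,
        collimator_rotation=collimator,
        couch_angle=couch,
        ssd=_first_ssd(cps),
        jaws=jaws,
        control_points=tuple(mlc_cps),
    )


def _first_ssd(cps) -> Optional[float]:
    for cp in cps:
        ssd_mm = getattr(cp, "SourceToSurfaceDistance", None)
        if ssd_mm is not None:
            return float(ssd_mm) / 10.0  # DICOM mm -> cm
    return None


def _jaws_from_cp(cp) -> Optional[JawSetting]:
    x = y = None
    for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        kind = str(getattr(bld, "RTBeamLimitingDeviceType", ""))
        pos = [float(v) / 10.0 for v in bld.LeafJawPositions]  # mm -> cm
        if kind in ("X", "ASYMX") and len(pos) == 2:
            x = pos
        elif kind in ("Y", "ASYMY") and len(pos) == 2:
            y = pos
    if x is None or y is None:
        return None
    return JawSetting(x1=min(x), x2=max(x), y1=min(y), y2=max(y))


def _mlc_from_cp(cp):
    for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        kind = str(getattr(bld, "RTBeamLimitingDeviceType", ""))
        if kind in ("MLCX", "MLCY"):
            pos = [float(v) / 10.0 for v in bld.LeafJawPositions]  # mm -> cm
            half = len(pos) // 2
            return tuple(pos[:half]), tuple(pos[half:])
    return None
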