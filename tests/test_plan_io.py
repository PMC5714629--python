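"""Canonical XML round trips and DICOM RT Plan import."""

import pytest
from pydicom.dataset import Dataset

from planverify.comparison import compare_plans
from planverify.fixtures import generate_plan
from planverify.plan_io import (
    DicomImportError,
    PlanDocument,
    PlanParseError,
    SchemaContentError,
    SchemaVersionError,
    import_dicom_rtplan,
    read_plan_xml,
    write_plan_xml,
)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(20))
    def test_write_read_write_fixpoint(self, seed):
        doc = PlanDocument(plan=generate_plan(seed, n_fields=seed % 6), source_system="ref")
        once = write_plan_xml(doc)
        again = write_plan_xml(read_plan_xml(once))
        assert once == again

    def test_roundtrip_introduces_no_phantom_differences(self, rules):
        for seed in range(10):
            plan = generate_plan(1000 + seed, n_fields=4)
            doc = PlanDocument(plan=plan, source_system="ref")
            back = read_plan_xml(write_plan_xml(doc))
            report = compare_plans(plan, back.plan, rules)
            assert report.verdict == "pass"
            assert report.differences == ()

    def test_large_imrt_field_roundtrips_bit_equal(self):
        from planverify.fixtures import MachineCatalogue, generate_field
        import random

        rng = random.Random(42)
        field = generate_field(
            rng, "BIG", "imrt", MachineCatalogue.default(),
            n_control_points=100, n_leaf_pairs=60,
        )
        plan = generate_plan(1, n_fields=0)
        plan.fields = [field]
        doc = PlanDocument(plan=plan, source_system="ref")
        once = write_plan_xml(doc)
        assert write_plan_xml(read_plan_xml(once)) == once

    def test_absent_couch_position_omits_the_element(self):
        plan = generate_plan(2, n_fields=1, technique_mix=("static",))
        plan.fields[0].couch_position = None
        xml = write_plan_xml(PlanDocument(plan=plan, source_system="ref"))
        assert "CouchPosition" not in xml
        assert read_plan_xml(xml).plan.fields[0].couch_position is None


class TestReadErrors:
    def test_unknown_schema_version(self):
        doc = PlanDocument(plan=generate_plan(1, 1), source_system="ref")
        xml = write_plan_xml(doc).replace('schema_version="1.0"', 'schema_version="99"')
        with pytest.raises(SchemaVersionError):
            read_plan_xml(xml)

    def test_truncated_document_is_a_parse_error(self):
        xml = write_plan_xml(PlanDocument(plan=generate_plan(1, 2), source_system="ref"))
        with pytest.raises(PlanParseError):
            read_plan_xml(xml[: len(xml) // 2])

    def test_missing_mandatory_element_names_the_path(self):
        xml = write_plan_xml(PlanDocument(plan=generate_plan(1, 1), source_system="ref"))
        import re

        broken = re.sub(r"<GantryAngle>[^<]*</GantryAngle>", "", xml)
        with pytest.raises(SchemaContentError, match="GantryAngle"):
            read_plan_xml(broken)

    def test_empty_source_system_rejected(self):
        xml = write_plan_xml(PlanDocument(plan=generate_plan(1, 1), source_system="x"))
        with pytest.raises(SchemaContentError, match="source_system"):
            read_plan_xml(xml.replace('source_system="x"', 'source_system=""'))


def _make_rtplan(n_beams=1, mlc_on_beam=(1,)):
    ds = Dataset()
    ds.Modality = "RTPLAN"
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.481.5"
    ds.PatientID = "PT001"
    ds.RTPlanLabel = "demo plan"
    beams = []
    for b in range(1, n_beams + 1):
        beam = Dataset()
        beam.BeamNumber = b
        beam.BeamName = f"Beam {b}"
        beam.TreatmentMachineName = "LINAC1"
        beam.BeamType = "STATIC"
        beam.RadiationType = "PHOTON"
        cp = Dataset()
        cp.NominalBeamEnergy = 6
        cp.GantryAngle = 250.0
        cp.BeamLimitingDeviceAngle = 10.0
        cp.PatientSupportAngle = 355.0
        cp.SourceToSurfaceDistance = 924.0  # mm
        bld_x = Dataset()
        bld_x.RTBeamLimitingDeviceType = "X"
        bld_x.LeafJawPositions = [-50.0, 50.0]  # mm
        bld_y = Dataset()
        bld_y.RTBeamLimitingDeviceType = "Y"
        bld_y.LeafJawPositions = [-40.0, 40.0]
        positions = [bld_x, bld_y]
        if b in mlc_on_beam:
            mlc = Dataset()
            mlc.RTBeamLimitingDeviceType = "MLCX"
            mlc.LeafJawPositions = [-10.0, -12.0, -8.0, 10.0, 12.0, 8.0]
            positions.append(mlc)
        cp.BeamLimitingDevicePositionSequence = positions
        beam.ControlPointSequence = [cp]
        beams.append(beam)
    ds.BeamSequence = beams
    fg = Dataset()
    rb = Dataset()
    rb.ReferencedBeamNumber = 1
    rb.BeamMeterset = 150.0
    fg.ReferencedBeamSequence = [rb]
    ds.FractionGroupSequence = [fg]
    return ds


class TestDicomImport:
    def test_single_beam_maps_field_parameters(self):
        doc = import_dicom_rtplan(_make_rtplan())
        assert len(doc.plan.fields) == 1
        f = doc.plan.fields[0]
        assert f.field_id == "1"
        assert f.gantry_angle == 250.0
        assert f.collimator_rotation == 10.0
        assert f.couch_angle == 355.0
        assert f.energy == "6X"
        assert f.mode == "Photon"
        assert f.monitor_units == 150.0
        assert f.ssd == pytest.approx(92.4)  # mm converted to cm
        assert f.jaws is not None and f.jaws.x1 == -5.0 and f.jaws.x2 == 5.0
        assert len(f.control_points) == 1
        assert f.control_points[0].bank_a == (-1.0, -1.2, -0.8)

    def test_beam_without_mlc_has_empty_control_points(self):
        doc = import_dicom_rtplan(_make_rtplan(n_beams=2, mlc_on_beam=(1,)))
        assert len(doc.plan.fields) == 2
        assert doc.plan.fields[0].control_points
        assert doc.plan.fields[1].control_points == ()

    def test_non_rtplan_rejected(self):
        ct = Dataset()
        ct.Modality = "CT"
        ct.SOPClassUID = "1.2.840.10008.5.1.4.1.1.2"
        with pytest.raises(DicomImportError):
            import_dicom_rtplan(ct)

    def test_rtplan_without_beams_rejected(self):
        ds = Dataset()
        ds.Modality = "RTPLAN"
        with pytest.raises(DicomImportError, match="BeamSequence"):
            import_dicom_rtplan(ds)
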