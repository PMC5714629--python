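"""The comparison engine: value rules, agreement, matching, plan diffing."""

import copy
import itertools
import random

import pytest

from planverify.comparison import (
    DiffKind,
    ExactNumeric,
    ExactString,
    NumericTolerance,
    ToleranceRules,
    _assignment_optimum,
    batch_compare,
    compare_fields,
    compare_plans,
    compare_value,
    field_agreement,
    match_fields,
    missing_plan_report,
)
from planverify.fixtures import (
    MutationKind,
    MutationSpec,
    apply_mutation,
    generate_plan,
)
from planverify.plan_io import PlanDocument
from planverify.plan_model import PlanKey
from planverify.plan_repository import InMemoryCorpus, PlanList

ANGLE_RULE = NumericTolerance(0.1, "degrees", circular=True)
LINEAR_RULE = NumericTolerance(0.1, "cm")


class TestCompareValue:
    @pytest.mark.parametrize(
        "ref, test, rule, differs",
        [
            (250.0, 0.0, ANGLE_RULE, True),       # zeroed-out angle
            (10.00, 10.10, ANGLE_RULE, False),    # boundary: exactly tol passes
            (359.95, 0.05, ANGLE_RULE, False),    # circular distance is 0.1
            (359.5, 0.0, ANGLE_RULE, True),       # circular distance is 0.5
            (400, 600, ExactNumeric(), True),
            (400.0, 400, ExactNumeric(), False),
            ("6X", "6X ", ExactString(), False),  # whitespace trimmed
            ("6X", "6x", ExactString(), True),    # case-sensitive
            (5.0, 5.05, LINEAR_RULE, False),
            (5.0, 5.2, LINEAR_RULE, True),
        ],
    )
    def test_rule_semantics(self, ref, test, rule, differs):
        d = compare_value("param", ref, test, rule)
        assert (d is not None) == differs

    def test_unparseable_numeric_is_structural_not_crash(self):
        d = compare_value("Monitor Unit", "abc", 100.0, NumericTolerance(0.1))
        assert d is not None and d.kind is DiffKind.STRUCTURAL_MISMATCH

    def test_absence_semantics(self):
        rule = NumericTolerance(0.1)
        assert compare_value("p", None, None, rule) is None
        d = compare_value("p", 1.0, None, rule)
        assert d is not None and d.kind is DiffKind.STRUCTURAL_MISMATCH


class TestFieldAgreement:
    def test_identical_fields_score_one(self, rules):
        plan = generate_plan(1, 2)
        assert field_agreement(plan.fields[0], plan.fields[0], rules) == 1.0

    def test_disjoint_fields_score_zero(self, rules):
        plan = generate_plan(2, 1, technique_mix=("static",))
        ref = plan.fields[0]
        test = copy.deepcopy(ref)
        test.field_id = ref.field_id + "zz"
        test.energy = "20E"
        test.mode = "Electron"
        test.field_type = "Dynamic"
        test.technique = "ARC"
        test.gantry_angle = (ref.gantry_angle + 90.0) % 360.0
        test.collimator_rotation = (ref.collimator_rotation + 90.0) % 360.0
        test.couch_angle = (ref.couch_angle + 90.0) % 360.0
        assert field_agreement(ref, test, rules) == 0.0

    def test_gantry_zeroed_scores_eight_ninths(self, rules):
        plan = generate_plan(3, 1, technique_mix=("static",))
        ref = plan.fields[0]
        ref.gantry_angle = 250.0
        test = copy.deepcopy(ref)
        test.gantry_angle = 0.0
        assert field_agreement(ref, test, rules) == pytest.approx(8.0 / 9.0)


def _brute_force_optimum(ref_plan, test_plan, rules):
    """Exhaustive-search maximum total agreement over all 1-1 assignments."""
    refs = sorted(ref_plan.fields, key=lambda f: f.field_id)
    tests = sorted(test_plan.fields, key=lambda f: f.field_id)
    if not refs or not tests:
        return 0.0
    k = min(len(refs), len(tests))
    best = 0.0
    for ref_subset in itertools.permutations(range(len(refs)), k):
        for test_subset in itertools.permutations(range(len(tests)), k):
            total = sum(
                field_agreement(refs[i], tests[j], rules)
                for i, j in zip(ref_subset, test_subset)
            )
            best = max(best, total)
    return best


class TestMatchFields:
    def test_identical_plans_fully_matched(self, rules):
        plan = generate_plan(6, 6)
        result = match_fields(plan, plan, rules)
        assert len(result.pairs) == 6
        assert all(score == 1.0 for _, _, score in result.pairs)
        assert result.unmatched_ref == () and result.unmatched_test == ()

    def test_missing_field_left_unmatched_on_reference_side(self, rules):
        ref = generate_plan(7, 4)
        test = copy.deepcopy(ref)
        dropped = test.fields.pop(2)
        result = match_fields(ref, test, rules)
        assert dropped.field_id in result.unmatched_ref
        assert result.unmatched_test == ()

    def test_heavily_modified_field_dissolves_below_threshold(self, rules):
        ref = generate_plan(8, 2, technique_mix=("static",))
        test = copy.deepcopy(ref)
        f = test.fields[0]
        f.field_id += "zz"
        f.energy, f.mode, f.field_type, f.technique = "20E", "Electron", "Dynamic", "ARC"
        f.gantry_angle = (f.gantry_angle + 45.0) % 360.0
        f.collimator_rotation = (f.collimator_rotation + 45.0) % 360.0
        f.couch_angle = (f.couch_angle + 45.0) % 360.0
        result = match_fields(ref, test, rules)
        assert ref.fields[0].field_id in result.unmatched_ref
        assert f.field_id in result.unmatched_test

    @pytest.mark.parametrize("trial", range(25))
    def test_assignment_total_equals_brute_force(self, trial, rules):
        rng = random.Random(1000 + trial)
        ref = generate_plan(rng.randrange(2**20), n_fields=rng.randint(1, 4))
        if rng.random() < 0.5:
            test = generate_plan(rng.randrange(2**20), n_fields=rng.randint(1, 4))
        else:
            test = copy.deepcopy(ref)
            rng.shuffle(test.fields)
        assert _assignment_optimum(ref, test, rules) == pytest.approx(
            _brute_force_optimum(ref, test, rules)
        )


class TestCompareFields:
    def test_field_against_itself_is_clean(self, rules, demo_plan):
        for f in demo_plan.fields:
            assert compare_fields(f, f, rules) == []

    def test_foreign_mlc_sequence_detected_in_control_points(self, rules, demo_plan):
        ref = demo_plan.field_by_id("1.1-5-RSO")
        test = copy.deepcopy(ref)
        test.control_points = copy.deepcopy(
            demo_plan.field_by_id("1.1-6-RAIO").control_points
        )
        diffs = compare_fields(ref, test, rules)
        assert diffs
        assert all(d.path.parameter.startswith("MLC Control Points") for d in diffs)

    def test_leaf_move_boundary(self, rules, demo_plan):
        ref = demo_plan.field_by_id("1.1-4-LAIO")

        def moved(delta):
            test = copy.deepcopy(ref)
            cps = list(test.control_points)
            cp = cps[2]
            bank_b = list(cp.bank_b)
            bank_b[7] = round(bank_b[7] + delta, 4)
            import dataclasses

            cps[2] = dataclasses.replace(cp, bank_b=tuple(bank_b))
            test.control_points = tuple(cps)
            return test

        assert compare_fields(ref, moved(0.05), rules) == []
        diffs = compare_fields(ref, moved(0.2), rules)
        assert len(diffs) == 1
        d = diffs[0]
        assert d.path.field_id == "1.1-4-LAIO"
        assert d.path.cp_index == 2 and d.path.leaf_index == 7

    def test_unequal_cp_counts_collapse_to_one_structural_diff(self, rules, demo_plan):
        ref = demo_plan.field_by_id("1.1-4-LAIO")
        test = copy.deepcopy(ref)
        test.control_points = test.control_points[:-2]
        diffs = compare_fields(ref, test, rules)
        assert len(diffs) == 1
        assert diffs[0].kind is DiffKind.STRUCTURAL_MISMATCH

    def test_sequence_present_on_one_side_is_structural(self, rules, demo_plan):
        ref = demo_plan.field_by_id("1.1-4-LAIO")
        test = copy.deepcopy(ref)
        test.control_points = ()
        diffs = compare_fields(ref, test, rules)
        assert len(diffs) == 1
        assert diffs[0].kind is DiffKind.STRUCTURAL_MISMATCH

    def test_accessory_sets_compared_per_element(self, rules, demo_plan):
        ref = copy.deepcopy(demo_plan.field_by_id("1.1-1-G250"))
        ref.slotted_accessories = frozenset({"W30"})
        test = copy.deepcopy(ref)
        test.slotted_accessories = frozenset({"W45"})
        diffs = compare_fields(ref, test, rules)
        assert {(d.ref_value, d.test_value) for d in diffs} == {
            ("W30", "(absent)"),
            ("(absent)", "W45"),
        }


class TestComparePlans:
    def test_plan_against_deep_copy_passes(self, rules, demo_plan):
        report = compare_plans(demo_plan, copy.deepcopy(demo_plan), rules)
        assert report.verdict == "pass"
        assert report.differences == ()

    def test_demo_mutant_localises_to_mutated_fields(self, rules, demo_plan, demo_mutant):
        report = compare_plans(demo_plan, demo_mutant, rules)
        assert report.verdict == "fail"
        touched = {d.path.field_id for d in report.differences}
        assert touched == {
            "1.1-1-G250", "1.1-2-G110", "1.1-4-LAIO", "1.1-5-RSO", "1.1-7-SUP",
        }
        by_field = {
            fid: {d.path.parameter for d in report.differences if d.path.field_id == fid}
            for fid in touched
        }
        assert {"Gantry Angle", "Collimator Rotation", "SSD"} <= by_field["1.1-1-G250"]
        assert "Couch Position" in by_field["1.1-2-G110"]
        assert any(p.startswith("MLC") for p in by_field["1.1-4-LAIO"])
        assert any(p.startswith("MLC") for p in by_field["1.1-5-RSO"])
        assert any(p.startswith("Primary Collimators") for p in by_field["1.1-7-SUP"])

    def test_status_differences_are_informational_only(self, rules, demo_plan):
        from planverify.plan_model import PlanStatus

        test = copy.deepcopy(demo_plan)
        test.plan_status = PlanStatus.COMPLETED
        report = compare_plans(demo_plan, test, rules)
        assert report.verdict == "pass"
        assert any(d.path.parameter == "Plan Status" for d in report.informational)

    def test_orientation_difference_fails_the_plan(self, rules, demo_plan):
        test = copy.deepcopy(demo_plan)
        test.patient_orientation = "FFP"
        report = compare_plans(demo_plan, test, rules)
        assert report.verdict == "fail"
        assert any(d.path.parameter == "Patient Orientation" for d in report.differences)

    def test_missing_plan_report(self):
        key = PlanKey("none", "C1", "1.1-1 C2 SBRT")
        report = missing_plan_report(key, "ref-db", "test-db")
        assert report.verdict == "fail"
        assert len(report.differences) == 1
        assert report.differences[0].kind is DiffKind.MISSING_PLAN

    def test_monotonicity_of_single_parameter_perturbation(self, rules, demo_plan):
        # once a gantry shift fails, larger shifts keep failing
        failed_already = False
        for delta in [0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 5.0, 20.0]:
            test = apply_mutation(
                demo_plan,
                MutationSpec(MutationKind.SHIFT_GANTRY, "1.1-1-G250", delta=delta),
            )
            verdict = compare_plans(demo_plan, test, rules).verdict
            if failed_already:
                assert verdict == "fail"
            failed_already = failed_already or verdict == "fail"
        assert failed_already


class TestBatchCompare:
    def _corpora(self, n=3):
        docs = [
            PlanDocument(
                plan=generate_plan(i, 2, key=PlanKey(f"P{i}", "C1", f"plan{i}")),
                source_system="ref-db",
            )
            for i in range(n)
        ]
        test_docs = [
            PlanDocument(plan=copy.deepcopy(d.plan), source_system="test-db")
            for d in docs
        ]
        return InMemoryCorpus(docs), InMemoryCorpus(test_docs)

    def test_identical_corpora_all_pass_with_accounting(self):
        ref, test = self._corpora(3)
        plan_list = PlanList(entries=ref.keys())
        summary = batch_compare(ref, test, plan_list)
        assert summary.completed == (3, 3)
        assert summary.all_passed
        assert summary.ref_source == "ref-db" and summary.test_source == "test-db"

    def test_presence_matrix_gives_distinct_verdicts(self):
        ref, test = self._corpora(2)
        only_ref = PlanKey("R", "C1", "ref-only")
        only_test = PlanKey("T", "C1", "test-only")
        nowhere = PlanKey("N", "C1", "nowhere")
        ref._docs[only_ref] = PlanDocument(
            plan=generate_plan(50, 1, key=only_ref), source_system="ref-db"
        )
        test._docs[only_test] = PlanDocument(
            plan=generate_plan(51, 1, key=only_test), source_system="test-db"
        )
        plan_list = PlanList(entries=[ref.keys()[0], only_ref, only_test, nowhere])
        summary = batch_compare(ref, test, plan_list)
        verdicts = {e.key: e.verdict for e in summary.entries}
        assert verdicts[only_ref] == "missing-in-test"
        assert verdicts[nowhere] == "missing-in-both"
        assert verdicts[only_test] == "load-error"
        assert verdicts[ref.keys()[0]] == "pass"
        # newly imported plans flagged
        assert only_ref in summary.reference_only_plans

    def test_processing_continues_past_failures(self):
        ref, test = self._corpora(4)
        missing = PlanKey("A", "C1", "absent")  # sorts first
        plan_list = PlanList(entries=[missing] + ref.keys())
        summary = batch_compare(ref, test, plan_list)
        assert summary.completed == (5, 5)
        assert [e.verdict for e in summary.entries] == [
            "missing-in-both" if e.key == missing else "pass" for e in summary.entries
        ]
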