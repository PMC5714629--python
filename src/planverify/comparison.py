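"""The comparison engine: match fields, then diff every parameter.

Two plans that are nominally "the same plan" in two TMS databases are
compared in three stages:

1. **Field matching.**  No assumption is made about which field in the
   reference plan corresponds to which field in the test plan.  Instead an
   agreement score in [0, 1] is computed for every (reference, test) field
   pair from identity, energy, mode, type, technique and the three machine
   angles, and an optimal one-to-one assignment maximising total agreement
   is found.  Pairs scoring below a threshold are dissolved: a field that
   was modified a great deal simply fails to match, which is itself a
   reportable (and detectable) outcome.

2. **Parameter diffing.**  Every matched pair is compared parameter by
   parameter under the tolerance rules; MLC sequences control point by
   control point, leaf by leaf.

3. **Verdict.**  A plan passes iff zero non-informational differences were
   found.  Status fields are compared but reported as informational only.

The comparison is directional: the reference plan is ground truth.  Missing
and extra fields are both reported, so the difference set is informationally
symmetric even though the verdict is not.
"""

from __future__ import annotations

import enum
import time
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import yaml
from scipy.optimize import linear_sum_assignment

from .plan_io import fmt_num
from .plan_model import Plan, PlanKey, TreatmentField

__all__ = [
    "ExactString",
    "ExactNumeric",
    "NumericTolerance",
    "ToleranceRules",
    "DiffKind",
    "DiffPath",
    "Difference",
    "MatchResult",
    "ComparisonReport",
    "SummaryEntry",
    "SummaryReport",
    "compare_value",
    "field_agreement",
    "match_fields",
    "compare_fields",
    "compare_plans",
    "missing_plan_report",
    "batch_compare",
    "DEFAULT_MATCH_THRESHOLD",
]

DEFAULT_MATCH_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# tolerance rules


@dataclass(frozen=True)
class ExactString:
    """Strings must match exactly after whitespace trimming (case-sensitive)."""


@dataclass(frozen=True)
class ExactNumeric:
    """Numbers must be exactly equal after parsing."""


@dataclass(frozen=True)
class NumericTolerance:
    """Numbers may differ by at most ``tol`` (inclusive boundary).

    ``circular`` marks angle parameters compared by minimal distance on the
    360-degree circle, so 359.95 vs 0.05 is a 0.1-degree discrepancy.
    """

    tol: float
    unit: str = ""
    circular: bool = False


Rule = Union[ExactString, ExactNumeric, NumericTolerance]

# Default rule table: one row per compared parameter with its comparison
# mode and tolerance (degrees / cm / MU / minutes are unit-native).
_DEFAULT_RULES: dict[str, Rule] = {
    "Field Name": ExactString(),
    "Field ID": ExactString(),
    "Machine ID": ExactString(),
    "Field Type": ExactString(),
    "Monitor Unit": NumericTolerance(0.1, "MU"),
    "Gantry Angle": NumericTolerance(0.1, "degrees", circular=True),
    "Treatment Time": NumericTolerance(0.1, "minutes"),
    "Field Technique": ExactString(),
    "Field Energy": ExactString(),
    "Field Mode": ExactString(),
    "Dose Rate": ExactNumeric(),
    "Tolerance Table": ExactString(),
    "SSD": NumericTolerance(0.1, "cm"),
    "Collimator Rotation": NumericTolerance(0.1, "degrees", circular=True),
    "Couch Angle": NumericTolerance(0.1, "degrees", circular=True),
    "MLC Control Points": NumericTolerance(0.1, "cm"),
    "Primary Collimators": NumericTolerance(0.1, "cm"),
    "Slotted Field Accessories": ExactString(),
    "Other Accessories": ExactString(),
    # Parameters compared but without a published tolerance row; couch
    # position gets the same 0.1 cm as every other linear tolerance.
    "Couch Position": NumericTolerance(0.1, "cm"),
    "Patient Orientation": ExactString(),
    "Meterset Weight": ExactNumeric(),
}


@dataclass
class ToleranceRules:
    """Parameter name -> comparison rule; the engine's configuration."""

    rules: dict[str, Rule] = dc_field(default_factory=lambda: dict(_DEFAULT_RULES))

    def __getitem__(self, param: str) -> Rule:
        return self.rules[param]

    def __contains__(self, param: str) -> bool:
        return param in self.rules

    @classmethod
    def default(cls) -> "ToleranceRules":
        return cls()

    @classmethod
    def load(cls, path) -> "ToleranceRules":
        """Load rules from a YAML config file (see docs/methods.md)."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"rules file {path} is not a mapping")
        rules: dict[str, Rule] = {}
        for name, spec in raw.items():
            rules[name] = _rule_from_spec(name, spec)
        return cls(rules=rules)

    def save(self, path) -> None:
        out: dict[str, dict] = {}
        for name, rule in self.rules.items():
            if isinstance(rule, ExactString):
                out[name] = {"mode": "exact_string"}
            elif isinstance(rule, ExactNumeric):
                out[name] = {"mode": "exact_numeric"}
            else:
                out[name] = {
                    "mode": "tolerance",
                    "tol": rule.tol,
                    "unit": rule.unit,
                    "circular": rule.circular,
                }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)


def _rule_from_spec(name: str, spec) -> Rule:
    if not isinstance(spec, dict) or "mode" not in spec:
        raise ValueError(f"rule for {name!r} must be a mapping with a 'mode'")
    mode = spec["mode"]
    if mode == "exact_string":
        return ExactString()
    if mode == "exact_numeric":
        return ExactNumeric()
    if mode == "tolerance":
        tol = float(spec["tol"])
        if tol <= 0:
            raise ValueError(f"rule for {name!r}: tol must be > 0")
        return NumericTolerance(tol, str(spec.get("unit", "")), bool(spec.get("circular", False)))
    raise ValueError(f"rule for {name!r}: unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# differences


class DiffKind(enum.Enum):
    VALUE_MISMATCH = "ValueMismatch"
    MISSING_FIELD = "MissingField"
    EXTRA_FIELD = "ExtraField"
    MISSING_PLAN = "MissingPlan"
    STRUCTURAL_MISMATCH = "StructuralMismatch"


@dataclass(frozen=True)
class DiffPath:
    """Structured locator: plan-level, field, or control-point/leaf level."""

    parameter: str
    field_id: Optional[str] = None
    cp_index: Optional[int] = None
    leaf_index: Optional[int] = None

    def render(self) -> str:
        parts = []
        if self.field_id is not None:
            parts.append(f"field[{self.field_id}]")
        if self.cp_index is not None:
            parts.append(f"cp[{self.cp_index}]")
        if self.leaf_index is not None:
            parts.append(f"leaf[{self.leaf_index}]")
        parts.append(self.parameter)
        return "/".join(parts)

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class Difference:
    """One detected discrepancy between reference and test."""

    path: DiffPath
    kind: DiffKind
    ref_value: str
    test_value: str

    def __str__(self) -> str:
        return f"{self.path}: {self.kind.value} ref={self.ref_value!r} test={self.test_value!r}"


_ABSENT = "(absent)"


def _render(value) -> str:
    if value is None:
        return _ABSENT
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, float)):
        return fmt_num(value)
    return str(value)


# ---------------------------------------------------------------------------
# compare_value


def circular_distance(a: float, b: float) -> float:
    """Minimal angular distance between two angles in degrees."""
    d = abs(float(a) - float(b)) % 360.0
    return min(d, 360.0 - d)


def compare_value(
    param: str,
    ref,
    test,
    rule: Rule,
    *,
    field_id: Optional[str] = None,
    cp_index: Optional[int] = None,
    leaf_index: Optional[int] = None,
) -> Optional[Difference]:
    """Compare one parameter value pair under *rule*.

    Returns ``None`` when the values agree, otherwise a :class:`Difference`.
    Absence on both sides agrees; absence on exactly one side is a
    structural mismatch.  A value that cannot be parsed as a number under a
    numeric rule is likewise a structural mismatch, never a crash.
    """
    path = DiffPath(param, field_id=field_id, cp_index=cp_index, leaf_index=leaf_index)

    if ref is None and test is None:
        return None
    if ref is None or test is None:
        return Difference(path, DiffKind.STRUCTURAL_MISMATCH, _render(ref), _render(test))

    if isinstance(rule, ExactString):
        r, t = str(ref).strip(), str(test).strip()
        if r != t:
            return Difference(path, DiffKind.VALUE_MISMATCH, r, t)
        return None

    # numeric rules: parse first
    try:
        rv, tv = float(ref), float(test)
    except (TypeError, ValueError):
        return Difference(path, DiffKind.STRUCTURAL_MISMATCH, _render(ref), _render(test))

    if isinstance(rule, ExactNumeric):
        if rv != tv:
            return Difference(path, DiffKind.VALUE_MISMATCH, _render(rv), _render(tv))
        return None

    delta = circular_distance(rv, tv) if rule.circular else abs(rv - tv)
    # closed boundary: a discrepancy of exactly tol passes; the 1e-9 guard
    # keeps "exactly at tolerance" robust to float representation noise
    # (values carry >= 0.001 granularity, far above the guard)
    if delta - rule.tol > 1e-9:
        return Difference(path, DiffKind.VALUE_MISMATCH, _render(rv), _render(tv))
    return None


# ---------------------------------------------------------------------------
# field matching


@dataclass(frozen=True)
class MatchResult:
    """Outcome of field matching between two plans."""

    pairs: tuple[tuple[str, str, float], ...]  # (ref field_id, test field_id, score)
    unmatched_ref: tuple[str, ...]
    unmatched_test: tuple[str, ...]


# agreement components: (label, weight); field identity counts double
_AGREEMENT_EXACT = (
    ("field_id", 2.0),
    ("energy", 1.0),
    ("mode", 1.0),
    ("field_type", 1.0),
    ("technique", 1.0),
)
_AGREEMENT_ANGLES = (
    ("gantry_angle", "Gantry Angle"),
    ("collimator_rotation", "Collimator Rotation"),
    ("couch_angle", "Couch Angle"),
)


def field_agreement(
    ref: TreatmentField,
    test: TreatmentField,
    rules: Optional[ToleranceRules] = None,
) -> float:
    """Agreement score in [0, 1] between two fields.

    Weighted fraction of matching components: field_id (weight 2, exact),
    energy / mode / field_type / technique (weight 1 each, exact), and the
    gantry, collimator and couch angles (weight 1 each, within their
    tolerance rule).  Identical fields score 1.0; fields sharing nothing
    score 0.0.
    """
    rules = rules or ToleranceRules.default()
    total = 0.0
    matched = 0.0
    for attr, weight in _AGREEMENT_EXACT:
        total += weight
        if str(getattr(ref, attr)).strip() == str(getattr(test, attr)).strip():
            matched += weight
    for attr, param in _AGREEMENT_ANGLES:
        total += 1.0
        rule = rules[param] if param in rules else NumericTolerance(0.1, "degrees", True)
        if compare_value(param, getattr(ref, attr), getattr(test, attr), rule) is None:
            matched += 1.0
    return matched / total


def match_fields(
    ref: Plan,
    test: Plan,
    rules: Optional[ToleranceRules] = None,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> MatchResult:
    """One-to-one field assignment maximising total agreement score.

    The assignment is globally optimal (bipartite matching), not greedy.
    Pairs scoring below *match_threshold* are dissolved into unmatched on
    both sides.  Field order is canonicalised by field_id so the result is
    deterministic regardless of input order.
    """
    rules = rules or ToleranceRules.default()
    ref_fields = sorted(ref.fields, key=lambda f: f.field_id)
    test_fields = sorted(test.fields, key=lambda f: f.field_id)
    if not ref_fields or not test_fields:
        return MatchResult(
            pairs=(),
            unmatched_ref=tuple(f.field_id for f in ref_fields),
            unmatched_test=tuple(f.field_id for f in test_fields),
        )

    scores = [
        [field_agreement(rf, tf, rules) for tf in test_fields] for rf in ref_fields
    ]
    cost = [[-s for s in row] for row in scores]
    row_ind, col_ind = linear_sum_assignment(cost)

    pairs: list[tuple[str, str, float]] = []
    matched_ref: set[int] = set()
    matched_test: set[int] = set()
    for i, j in zip(row_ind, col_ind):
        score = scores[i][j]
        if score < match_threshold:
            continue  # dissolved: too dissimilar to be "the same field"
        pairs.append((ref_fields[i].field_id, test_fields[j].field_id, score))
        matched_ref.add(i)
        matched_test.add(j)

    pairs.sort(key=lambda p: (p[0], p[1]))
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_ref=tuple(
            f.field_id for i, f in enumerate(ref_fields) if i not in matched_ref
        ),
        unmatched_test=tuple(
            f.field_id for j, f in enumerate(test_fields) if j not in matched_test
        ),
    )


def _assignment_optimum(ref: Plan, test: Plan, rules: Optional[ToleranceRules] = None) -> float:
    """Total agreement of the optimal assignment (before threshold dissolution)."""
    rules = rules or ToleranceRules.default()
    ref_fields = sorted(ref.fields, key=lambda f: f.field_id)
    test_fields = sorted(test.fields, key=lambda f: f.field_id)
    if not ref_fields or not test_fields:
        return 0.0
    scores = [
        [field_agreement(rf, tf, rules) for tf in test_fields] for rf in ref_fields
    ]
    cost = [[-s for s in row] for row in scores]
    row_ind, col_ind = linear_sum_assignment(cost)
    return float(sum(scores[i][j] for i, j in zip(row_ind, col_ind)))


# ---------------------------------------------------------------------------
# field diffing

# (attribute, Table-1 parameter name) for the scalar field parameters
_SCALAR_PARAMS = (
    ("field_id", "Field ID"),
    ("field_name", "Field Name"),
    ("machine_id", "Machine ID"),
    ("field_type", "Field Type"),
    ("technique", "Field Technique"),
    ("energy", "Field Energy"),
    ("mode", "Field Mode"),
    ("dose_rate", "Dose Rate"),
    ("monitor_units", "Monitor Unit"),
    ("treatment_time", "Treatment Time"),
    ("gantry_angle", "Gantry Angle"),
    ("collimator_rotation", "Collimator Rotation"),
    ("couch_angle", "Couch Angle"),
    ("ssd", "SSD"),
    ("tolerance_table", "Tolerance Table"),
)


def compare_fields(
    ref: TreatmentField,
    test: TreatmentField,
    rules: Optional[ToleranceRules] = None,
) -> list[Difference]:
    """Diff every parameter of a matched field pair under the rules."""
    rules = rules or ToleranceRules.default()
    fid = ref.field_id
    out: list[Difference] = []

    for attr, param in _SCALAR_PARAMS:
        d = compare_value(param, getattr(ref, attr), getattr(test, attr), rules[param], field_id=fid)
        if d is not None:
            out.append(d)

    out.extend(_compare_couch_position(ref, test, rules, fid))
    out.extend(_compare_jaws(ref, test, rules, fid))
    for attr, param in (
        ("slotted_accessories", "Slotted Field Accessories"),
        ("other_accessories", "Other Accessories"),
    ):
        out.extend(
            _compare_accessory_sets(param, getattr(ref, attr), getattr(test, attr), fid)
        )
    out.extend(_compare_control_points(ref, test, rules, fid))
    return out


def _compare_couch_position(ref, test, rules, fid) -> list[Difference]:
    param = "Couch Position"
    if ref.couch_position is None and test.couch_position is None:
        return []
    if ref.couch_position is None or test.couch_position is None:
        return [
            Difference(
                DiffPath(param, field_id=fid),
                DiffKind.STRUCTURAL_MISMATCH,
                _render(ref.couch_position and "present"),
                _render(test.couch_position and "present"),
            )
        ]
    out = []
    rule = rules[param]
    for axis, rv, tv in zip("xyz", ref.couch_position, test.couch_position):
        d = compare_value(f"{param} ({axis})", rv, tv, rule, field_id=fid)
        if d is not None:
            out.append(d)
    return out


def _compare_jaws(ref, test, rules, fid) -> list[Difference]:
    param = "Primary Collimators"
    if ref.jaws is None and test.jaws is None:
        return []
    if ref.jaws is None or test.jaws is None:
        return [
            Difference(
                DiffPath(param, field_id=fid),
                DiffKind.STRUCTURAL_MISMATCH,
                _render(ref.jaws and "present"),
                _render(test.jaws and "present"),
            )
        ]
    out = []
    rule = rules[param]
    for edge in ("x1", "x2", "y1", "y2"):
        d = compare_value(
            f"{param} ({edge})", getattr(ref.jaws, edge), getattr(test.jaws, edge), rule, field_id=fid
        )
        if d is not None:
            out.append(d)
    return out


def _compare_accessory_sets(
    param: str, ref: frozenset[str], test: frozenset[str], fid: str
) -> list[Difference]:
    # set equality, reported per element so each discrepancy is localised
    out = []
    for item in sorted(ref - test):
        out.append(
            Difference(DiffPath(param, field_id=fid), DiffKind.VALUE_MISMATCH, item, _ABSENT)
        )
    for item in sorted(test - ref):
        out.append(
            Difference(DiffPath(param, field_id=fid), DiffKind.VALUE_MISMATCH, _ABSENT, item)
        )
    return out


def _compare_control_points(ref, test, rules, fid) -> list[Difference]:
    param = "MLC Control Points"
    path = DiffPath(param, field_id=fid)
    r_cps, t_cps = ref.control_points, test.control_points
    if not r_cps and not t_cps:
        return []
    if bool(r_cps) != bool(t_cps):
        return [
            Difference(
                path,
                DiffKind.STRUCTURAL_MISMATCH,
                f"{len(r_cps)} control points",
                f"{len(t_cps)} control points",
            )
        ]
    if len(r_cps) != len(t_cps):
        return [
            Difference(
                path,
                DiffKind.STRUCTURAL_MISMATCH,
                f"{len(r_cps)} control points",
                f"{len(t_cps)} control points",
            )
        ]
    r_leaves = {len(cp.bank_a) for cp in r_cps} | {len(cp.bank_b) for cp in r_cps}
    t_leaves = {len(cp.bank_a) for cp in t_cps} | {len(cp.bank_b) for cp in t_cps}
    if len(r_leaves) != 1 or len(t_leaves) != 1 or r_leaves != t_leaves:
        return [
            Difference(
                path,
                DiffKind.STRUCTURAL_MISMATCH,
                f"leaf counts {sorted(r_leaves)}",
                f"leaf counts {sorted(t_leaves)}",
            )
        ]

    rule = rules[param]
    mw_rule = rules["Meterset Weight"] if "Meterset Weight" in rules else ExactNumeric()
    out: list[Difference] = []
    for rcp, tcp in zip(r_cps, t_cps):
        if rcp.index != tcp.index:
            out.append(
                Difference(
                    DiffPath(param, field_id=fid, cp_index=rcp.index),
                    DiffKind.STRUCTURAL_MISMATCH,
                    f"index {rcp.index}",
                    f"index {tcp.index}",
                )
            )
            continue
        for bank_name, rbank, tbank in (
            ("A", rcp.bank_a, tcp.bank_a),
            ("B", rcp.bank_b, tcp.bank_b),
        ):
            for leaf, (rv, tv) in enumerate(zip(rbank, tbank)):
                d = compare_value(
                    f"{param} (bank {bank_name})",
                    rv,
                    tv,
                    rule,
                    field_id=fid,
                    cp_index=rcp.index,
                    leaf_index=leaf,
                )
                if d is not None:
                    out.append(d)
        d = compare_value(
            "Meterset Weight",
            rcp.meterset_weight,
            tcp.meterset_weight,
            mw_rule,
            field_id=fid,
            cp_index=rcp.index,
        )
        if d is not None:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# plan comparison and reports


@dataclass
class ComparisonReport:
    """Per-plan verdict plus the differences behind it.

    ``differences`` drive the verdict; ``informational`` entries (status
    changes) are reported prominently but do not fail the plan.
    """

    key: PlanKey
    verdict: str  # "pass" | "fail"
    differences: tuple[Difference, ...]
    informational: tuple[Difference, ...] = ()
    ref_source: str = ""
    test_source: str = ""
    timestamp: str = ""
    match: Optional[MatchResult] = None

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def compare_plans(
    ref: Plan,
    test: Plan,
    rules: Optional[ToleranceRules] = None,
    *,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    ref_source: str = "",
    test_source: str = "",
) -> ComparisonReport:
    """Compare two plans field by field, control point by control point.

    Plan-level parameters are compared first (patient orientation is a
    failing difference; plan and course status are informational), then
    fields are matched and each matched pair fully diffed.  Unmatched
    reference fields become ``MissingField`` differences and unmatched test
    fields ``ExtraField``.  Verdict is pass iff no failing difference.
    """
    rules = rules or ToleranceRules.default()
    differences: list[Difference] = []
    informational: list[Difference] = []

    d = compare_value(
        "Patient Orientation", ref.patient_orientation, test.patient_orientation,
        rules["Patient Orientation"],
    )
    if d is not None:
        differences.append(d)

    for param, rv, tv in (
        ("Plan Status", ref.plan_status.value, test.plan_status.value),
        ("Course Status", ref.course_status.value, test.course_status.value),
    ):
        if rv != tv:
            informational.append(
                Difference(DiffPath(param), DiffKind.VALUE_MISMATCH, rv, tv)
            )

    match = match_fields(ref, test, rules, match_threshold)
    for ref_id, test_id, _score in match.pairs:
        differences.extend(
            compare_fields(ref.field_by_id(ref_id), test.field_by_id(test_id), rules)
        )
    for fid in match.unmatched_ref:
        differences.append(
            Difference(
                DiffPath("Field", field_id=fid),
                DiffKind.MISSING_FIELD,
                "present",
                "no corresponding field found",
            )
        )
    for fid in match.unmatched_test:
        differences.append(
            Difference(
                DiffPath("Field", field_id=fid),
                DiffKind.EXTRA_FIELD,
                "no corresponding field found",
                "present",
            )
        )

    return ComparisonReport(
        key=ref.key,
        verdict="pass" if not differences else "fail",
        differences=tuple(differences),
        informational=tuple(informational),
        ref_source=ref_source,
        test_source=test_source,
        timestamp=_now(),
        match=match,
    )


def missing_plan_report(
    key: PlanKey, ref_source: str = "", test_source: str = ""
) -> ComparisonReport:
    """Failing report for a plan absent from the test corpus."""
    return ComparisonReport(
        key=key,
        verdict="fail",
        differences=(
            Difference(
                DiffPath("Plan"), DiffKind.MISSING_PLAN, key.render(), _ABSENT
            ),
        ),
        ref_source=ref_source,
        test_source=test_source,
        timestamp=_now(),
    )


# ---------------------------------------------------------------------------
# batch comparison


@dataclass(frozen=True)
class SummaryEntry:
    """One row of the batch summary."""

    key: PlanKey
    verdict: str  # pass | fail | missing-in-test | missing-in-both | load-error
    annotation: str = ""
    report: Optional[ComparisonReport] = None


@dataclass
class SummaryReport:
    """Aggregated verdicts over a whole plan list."""

    entries: tuple[SummaryEntry, ...]
    completed: tuple[int, int]  # (k, n)
    ref_source: str
    test_source: str
    user_list_banner: bool = False
    reference_only_plans: tuple[PlanKey, ...] = ()
    timestamp: str = ""
    elapsed_seconds: float = 0.0

    @property
    def all_passed(self) -> bool:
        return all(e.verdict == "pass" for e in self.entries)


def batch_compare(
    ref_corpus,
    test_corpus,
    plan_list,
    rules: Optional[ToleranceRules] = None,
    *,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    progress=None,
) -> SummaryReport:
    """Compare every plan named in *plan_list* between the two corpora.

    Processing continues past every failure: a load failure becomes a
    failed ``load-error`` entry, a plan absent from the test corpus a
    ``missing-in-test`` entry, a plan absent from both corpora a distinct
    ``missing-in-both`` entry.  The summary records both corpus identities
    (so the operator can confirm the right two databases were compared) and
    flags plans that exist only in the reference corpus — newly imported
    plans that could not have migrated yet.

    *progress*, if given, is called as ``progress(k, n, entry)`` after each
    plan.
    """
    rules = rules or ToleranceRules.default()
    ref_source = ref_corpus.source_system
    test_source = test_corpus.source_system
    started = time.monotonic()

    ref_keys = set(ref_corpus.keys())
    test_keys = set(test_corpus.keys())

    entries: list[SummaryEntry] = []
    n = len(plan_list.entries)
    for k, key in enumerate(plan_list.entries, start=1):
        entry = _compare_one(
            key, ref_corpus, test_corpus, ref_keys, test_keys, rules,
            match_threshold, ref_source, test_source,
        )
        entries.append(entry)
        if progress is not None:
            progress(k, n, entry)

    return SummaryReport(
        entries=tuple(entries),
        completed=(len(entries), n),
        ref_source=ref_source,
        test_source=test_source,
        user_list_banner=plan_list.user_supplied,
        reference_only_plans=tuple(sorted(ref_keys - test_keys)),
        timestamp=_now(),
        elapsed_seconds=time.monotonic() - started,
    )


def _compare_one(
    key, ref_corpus, test_corpus, ref_keys, test_keys, rules,
    match_threshold, ref_source, test_source,
) -> SummaryEntry:
    in_ref, in_test = key in ref_keys, key in test_keys
    if not in_ref and not in_test:
        return SummaryEntry(
            key, "missing-in-both", annotation="plan absent from both corpora"
        )
    if in_ref and not in_test:
        return SummaryEntry(
            key,
            "missing-in-test",
            annotation="plan missing from the test corpus",
            report=missing_plan_report(key, ref_source, test_source),
        )
    if not in_ref:
        return SummaryEntry(
            key,
            "load-error",
            annotation="plan exists only in the test corpus; no reference to compare against",
        )
    try:
        ref_doc = ref_corpus.load(key)
    except Exception as exc:
        return SummaryEntry(key, "load-error", annotation=f"reference load failed: {exc}")
    try:
        test_doc = test_corpus.load(key)
    except Exception as exc:
        return SummaryEntry(key, "load-error", annotation=f"test load failed: {exc}")
    report = compare_plans(
        ref_doc.plan,
        test_doc.plan,
        rules,
        match_threshold=match_threshold,
        ref_source=ref_source,
        test_source=test_source,
    )
    return SummaryEntry(key, report.verdict, report=report)
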