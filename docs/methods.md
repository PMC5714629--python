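# Methods

## The verification model

`planverify` treats migration QA as a document-comparison problem. Both
databases' plans are projected into one canonical XML schema (below); the
reference document is ground truth and the test document must agree with it
parameter for parameter under a tolerance table. The engine never assumes
field correspondence, because migration faults include re-ordered, dropped,
duplicated and heavily rewritten fields: correspondence is *recovered* by
optimal assignment, and failure to recover it is itself a finding.

A plan-level verdict is `pass` iff zero failing differences were found.
Plan and course status differences are reported as informational only:
nothing in the delivery geometry depends on them, and flagging them both
ways (prominently reported, never silently failing) is safer than either
silent choice.

### Field agreement and matching

For fields `r` (reference) and `t` (test) the agreement score is

    s(r, t) = [2·1(id) + 1(energy) + 1(mode) + 1(type) + 1(technique)
               + 1(gantry≈) + 1(collimator≈) + 1(couch≈)] / 9

where `1(·)` are exact string matches after whitespace trimming and `≈`
means within the angle tolerance on the circle. The field identifier is
double-weighted: it is the one component intended to be unique. The
matching maximises `Σ s` over one-to-one assignments (solved exactly with
`scipy.optimize.linear_sum_assignment`, so a brute-force oracle can verify
optimality). Pairs with `s < 0.5` (default `match_threshold`) are
dissolved: below half agreement the pair is more plausibly two unrelated
fields than one corrupted field, and reporting "no corresponding field
found" reads better than a page of mismatches. The threshold and the
weights are engine parameters, not clinical constants.

### Tolerance rules

The shipped default table (also at `src/planverify/data/tolerance_rules.yaml`):

| parameter | mode | tolerance |
|---|---|---|
| Field Name / Field ID / Machine ID / Field Type / Field Technique / Field Energy / Field Mode / Tolerance Table / Slotted Field Accessories / Other Accessories / Patient Orientation | exact string | — |
| Dose Rate / Meterset Weight | exact numeric | — |
| Monitor Unit | numeric | 0.1 MU |
| Treatment Time | numeric | 0.1 min |
| Gantry Angle / Collimator Rotation / Couch Angle | numeric, circular | 0.1° |
| SSD / MLC Control Points / Primary Collimators / Couch Position | numeric | 0.1 cm |

Decisions behind the table:

* **Closed boundary.** A discrepancy of exactly the tolerance passes;
  `delta > tol` fails. "Within tolerance" conventionally includes the
  limit. A guard of 1e-9 absorbs float representation noise at the
  boundary; all serialised values carry ≥ 0.001 granularity, so the guard
  can never mask a real discrepancy.
* **Angles on the circle.** Gantry, collimator and couch angles are
  compared by minimal angular distance: 359.95° vs 0.05° is physically a
  0.1° difference. Angles are normalised to [0, 360) on ingest.
* **Couch position** has no published tolerance row but is mutated in the
  reference damage suite, so it must be compared; it gets 0.1 cm, the same
  linear tolerance as every other length.
* **Meterset weight** (the cumulative meterset fraction per control point)
  is compared exactly when present on both sides — serialisation is
  lossless so exactness is well defined — ignored when absent on both, and
  a structural mismatch when present on exactly one side. The same
  both/one/neither rule applies to every optional parameter (couch
  position, SSD, treatment time, dose rate, jaws, MLC sequence).
* **MLC tolerance is 0.1 cm (1 mm) per leaf.** Note the consequence: a
  genuinely sub-millimetre leaf change (e.g. 0.5 mm) *passes* under this
  table. Sites wanting sub-millimetre sensitivity should tighten the
  `MLC Control Points` row in a custom rules file; the engine takes any
  per-parameter override.

### Difference taxonomy

`ValueMismatch` (both values present, rule violated), `StructuralMismatch`
(value or substructure present on one side only, unparseable numerics,
changed control-point/leaf counts — per-point diffing is suppressed once
the sequences are structurally incomparable), `MissingField` /
`ExtraField` (unmatched after assignment), `MissingPlan` (listed plan
absent from the test corpus). Every difference carries a structured path
(field → control point → leaf → parameter) plus both rendered values.

## Canonical XML schema

One plan per document (`PlanDocument` root): `schema_version` and
`source_system` attributes (the latter feeds the wrong-database hazard
echo), a `Key` (patient / course / plan identifiers), plan and course
status (with the raw source string retained for reporting), patient
orientation, and an ordered `Fields` sequence. Each `Field` holds the
scalar parameters as elements, jaws and couch position as attribute
groups, accessory sets as sorted element lists, and the MLC sequence as
`ControlPoint` elements with space-separated bank A/B leaf positions in
cm. Optional values are omitted elements, never zero-filled: "couch
position deleted" and "couch at origin" are different defects.

Numbers are serialised as shortest round-trip decimals (no trailing
`.0`, locale-independent), so write→read→write is a byte-level fixpoint
and I/O introduces no phantom differences. Unknown `schema_version`,
missing mandatory elements and malformed XML raise typed errors naming
the path or line; a partial plan is never returned.

The MLC sign convention is: for leaf pair *i*, `bank_a[i] ≤ bank_b[i]`,
with equality a closed pair. Source systems with other conventions must be
normalised on import.

DICOM RT Plan import is a best-effort, deliberately lossy on-ramp (beam →
field, mm → cm, meterset from the referenced fraction group); the
canonical XML is the contract format.

## Corpora and the active-plan list

A corpus is a directory laid out `<patient>/<course>/<plan>.xml`
(components percent-encoded), with status metadata inside each document —
the queryable semantics of a TMS database without any database. *Active*
plans are those in an active course with status Unapproved, Planning
Approved or Treatment Approved; the list is generated before migration so
the QA targets are known in advance. User-supplied lists (which may add
e.g. Completed plans) carry a flag that surfaces as a banner in the
summary: "Plan list provided by user! Some active plans may be missing!".
Unreadable documents become recorded load failures, never silent gaps, and
in batch mode every per-plan error becomes a failed entry while processing
continues.

## The synthetic generator and mutation suite

`fixtures.generate_plan(seed, …)` draws fields over realistic ranges:
energies/wedges/cones from a configurable machine catalogue (default: a
typical dual-photon-energy linac, 6X/16X with four wedges, five electron
energies with five cones), angles uniform on [0, 360), monitor units
50–300 MU, SSD 80–110 cm, jaws up to ±10 cm, couch position present with
probability 0.8, and IMRT fields with 4–12 control points × 40 or 60 leaf
pairs with valid leaf geometry and monotone meterset weights. Values are
rounded to the 0.1 (leaves 0.01) granularity real TMS exports show.
Generation is reproducible from the seed, and every unmutated plan
validates cleanly.

What the generator does **not** emulate: clinically realistic joint
distributions (beam arrangements, fraction schemes, site-specific
catalogues), dose or deliverability. Passing tests therefore demonstrate
the *comparison machinery* — faithful round trips, correct tolerance
semantics, detection and localisation of planted damage — not clinical
realism of the inputs.

The mutation suite implements the migration failure modes used to validate
the engine: changed energy/mode, shifted or deleted couch position and
angle, deleted MLC sequence, foreign MLC sequence attached, single-leaf
perturbation in one control point, changed monitor units, modified jaws,
zeroed gantry+collimator, rounded SSD, flipped patient orientation, and
gantry/collimator shifts. Each mutation deep-copies the plan and touches
only the target field's subtree (patient orientation, a plan-level value,
is the documented exception), which the locality tests verify by XML diff.
The seven-field demonstration plan (`make_demo_plan`) carries the
canonical combination — five fields damaged, two negative controls — and
the acceptance checks assert exact localisation with the controls clean.

Probe magnitudes: supra-tolerance mutations default to 0.2 native units
(0.5 cm for jaws), sub-tolerance probes to 0.05; with the 0.1 tolerances
these sit safely either side of the boundary.

## Problem sizes and numerical choices

The acceptance checks run 1,000 seeded plans (1–5 fields each) for the
identity/round-trip sweep, 200 random pairs of ≤ 6 fields against the
exhaustive matching oracle, 100 random corpora for the active-list
predicate, a 30-point 0.01–0.30 grid for each tolerance-boundary sweep,
and a 358-plan batch (≤ 3 fields per plan) for the accounting check —
sizes chosen so the whole suite exercises every path at meaningful scale
while remaining a desk-side run. Matching ties are broken deterministically
(fields canonicalised by identifier before assignment; pair lists sorted);
only the total assignment score is asserted against the oracle, since
tied optima are legitimately interchangeable.

## Known limitations

* Geometry only: no dose recomputation, reference-point dose tracking,
  image/structure/DRR verification, or brachytherapy content.
* The 1 mm MLC tolerance hides sub-millimetre leaf corruption (see above).
* DICOM import covers common single-MLC beam layouts; exotic beam-limiting
  device configurations may import incompletely (import is for
  convenience; the XML schema is the contract).
* Completed plans are checked only when a user-supplied list includes
  them; corruption in plans outside the list is out of reach by design.
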