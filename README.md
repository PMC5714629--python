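# planverify

Tolerance-based verification that radiotherapy treatment plans survive a
treatment-management-system (TMS) database migration unchanged.

## The problem

When a record-and-verify system (e.g. a clinical oncology information
system) is upgraded, all plan data is migrated from the old database schema
to the new one. A migrated plan drives actual treatment delivery, so every
one of its thousands of parameters — monitor units, gantry/collimator/couch
angles, jaw positions, every MLC leaf in every control point of every IMRT
field — must be verified against the pre-migration original. Doing this by
hand is infeasible and repeating pretreatment QA measurements is costly and
may still miss corrupted control data.

`planverify` automates the check for physicists and medical-physics QA
teams. It compares a *reference* corpus (the pre-migration database
content, considered ground truth) against a *test* corpus (the migrated
content), plan by plan, **field by field, control point by control point,
parameter by parameter**, and renders pass/fail reports for human review
plus a machine-readable XML verdict for pipeline gating.

## The method

Each plan is normalised into a canonical XML document, so two database
schema generations become directly comparable. For a plan pair the engine:

1. **Matches fields without assuming correspondence.** For every
   (reference, test) field pair an agreement score in [0, 1] is computed as
   the weighted fraction of matching components — field ID (weight 2),
   energy, mode, field type, technique (weight 1 each, exact), and the
   gantry, collimator and couch angles (weight 1 each, within tolerance).
   An optimal one-to-one bipartite assignment maximising total agreement is
   found (Hungarian algorithm); pairs scoring below 0.5 dissolve into
   "no corresponding field found". Either outcome — a reported difference
   or a failed match — detects a modified field.
2. **Diffs every parameter under a tolerance table.** String parameters
   (energy, mode, machine, accessories, …) must match exactly; dose rate
   must be numerically exact; linear and angular parameters may differ by
   at most 0.1 in native units (MU, degrees, minutes, cm), with angles
   compared on the 360° circle (359.95° vs 0.05° is a 0.1° discrepancy,
   which passes). A discrepancy of exactly the tolerance passes; anything
   larger fails. MLC sequences are compared leaf by leaf per control point;
   structural damage (deleted sequence, changed control-point or leaf
   count) is reported as a single structural mismatch.
3. **Aggregates a batch.** The active-plan list (plans in an active course
   with status Unapproved / Planning Approved / Treatment Approved) is
   generated from the reference corpus before migration; the batch run then
   compares every listed plan, continues past every failure, reports both
   database identities (a wrong-database hazard mitigation), flags plans
   that exist only in the reference corpus, and keeps a `Completed: k/n`
   counter.

No external dataset is needed: the `fixtures` module generates realistic
synthetic corpora (including "one of everything" plans covering every
energy/wedge/cone/accessory combination) and applies a mutation suite that
emulates migration damage.

## Worked example

Command line — generate a 6-plan synthetic corpus, mutate half of the test
copies, list active plans and compare:

```
$ planverify fixtures --seed 7 --n-plans 6 --mutate --mutation-rate 0.5 --out fx
6 plan(s) written to fx/reference
6 plan(s) written to fx/test (4 mutated; manifest in fx/mutations.txt)
$ planverify list-active fx/reference active.xml
corpus: reference-db (fx/reference)
4 active plan(s) written to active.xml
$ planverify compare fx/reference fx/test --out run
planverify 0.1.0 (rules builtin)
reference database: reference-db (/tmp/demo/fx/reference)
test database:      test-db (/tmp/demo/fx/test)
[1/4] PT0000 / C1 / 0.1 Plan: fail
[2/4] PT0001 / C2 / 1.1 Plan: fail
[3/4] PT0003 / C1 / 3.1 Plan: fail
[4/4] PT0004 / C2 / 4.1 Plan: fail
Completed: 4/4 in 0.0 s; reports in run
```

The exit code is 1 because differences were found; `run/summary.html` lists
each plan with a link to its per-plan report, and `fx/mutations.txt` shows
the damage that was planted (e.g. `ZeroGantryAndCollimator @ 1-G280`).

Library — compare the built-in seven-field demonstration plan against its
canonical mutant (gantry/collimator zeroed and SSD rounded on field 1,
couch position deleted on field 2, MLC sequence deleted on field 4, a
foreign MLC sequence attached to field 5, jaws modified on field 7; fields
3 and 6 untouched):

```python
>>> from planverify import compare_plans
>>> from planverify.fixtures import make_demo_plan, make_demo_mutant
>>> ref = make_demo_plan()
>>> report = compare_plans(ref, make_demo_mutant(ref))
>>> report.verdict, len(report.differences)
('fail', 1191)
>>> for d in report.differences[:5]: print(d)
field[1.1-1-G250]/Gantry Angle: ValueMismatch ref='250' test='0'
field[1.1-1-G250]/Collimator Rotation: ValueMismatch ref='10' test='0'
field[1.1-1-G250]/SSD: ValueMismatch ref='92.4' test='92'
field[1.1-2-G110]/Couch Position: StructuralMismatch ref='present' test='(absent)'
field[1.1-4-LAIO]/MLC Control Points: StructuralMismatch ref='10 control points' test='0 control points'
```

Every difference is localised to the mutated field; the untouched fields
produce none (the foreign-sequence swap on field 5 accounts for most of the
1191 entries — one per differing leaf).

## Scope

External-beam plan geometry only: brachytherapy content, images,
structures, DRRs and reference-point dose tracking are out of scope and
must be verified by other means. See `docs/methods.md` for the model,
parameter and design details.
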