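# Default comparison rule table: one row per compared plan parameter.
# modes: exact_string | exact_numeric | tolerance (tol in the stated unit,
# closed boundary — a discrepancy of exactly tol passes; circular marks
# angles compared by minimal distance on the 360-degree circle).
Field Name: {mode: exact_string}
Field ID: {mode: exact_string}
Machine ID: {mode: exact_string}
Field Type: {mode: exact_string}
Monitor Unit: {mode: tolerance, tol: 0.1, unit: MU}
Gantry Angle: {mode: tolerance, tol: 0.1, unit: degrees, circular: true}
Treatment Time: {mode: tolerance, tol: 0.1, unit: minutes}
Field Technique: {mode: exact_string}
Field Energy: {mode: exact_string}
Field Mode: {mode: exact_string}
Dose Rate: {mode: exact_numeric}
Tolerance Table: {mode: exact_string}
SSD: {mode: tolerance, tol: 0.1, unit: cm}
Collimator Rotation: {mode: tolerance, tol: 0.1, unit: degrees, circular: true}
Couch Angle: {mode: tolerance, tol: 0.1, unit: degrees, circular: true}
MLC Control Points: {mode: tolerance, tol: 0.1, unit: cm}
Primary Collimators: {mode: tolerance, tol: 0.1, unit: cm}
Slotted Field Accessories: {mode: exact_string}
Other Accessories: {mode: exact_string}
Couch Position: {mode: tolerance, tol: 0.1, unit: cm}
Patient Orientation: {mode: exact_string}
Meterset Weight: {mode: exact_numeric}
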