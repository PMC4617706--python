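"""Pull-down evidence filtering: replication, controls, peptide support.

Applies the two classic AP-MS evidence rules to a small evidence table:
keep proteins detected in at least 3 of 4 bait runs and in no control
run, and accept identifications supported by at least two unique
peptides per run.
"""

import pandas as pd

import epasis as ep

evidence = pd.DataFrame(
    [
        # accession, run, run_class, unique_peptides
        ("REAL_1", "bait1", "bait", 8), ("REAL_1", "bait2", "bait", 6),
        ("REAL_1", "bait3", "bait", 7), ("REAL_1", "bait4", "bait", 5),
        ("SPORADIC", "bait1", "bait", 4), ("SPORADIC", "bait2", "bait", 3),
        ("STICKY", "bait1", "bait", 9), ("STICKY", "bait2", "bait", 9),
        ("STICKY", "bait3", "bait", 8), ("STICKY", "ctrl1", "control", 7),
        ("ONE_HIT", "bait1", "bait", 1), ("ONE_HIT", "bait2", "bait", 1),
        ("ONE_HIT", "bait3", "bait", 1),
    ],
    columns=["accession", "run", "run_class", "unique_peptides"],
)
# controls without detections still define the control runs
for run in ("ctrl1", "ctrl2", "ctrl3"):
    evidence.loc[len(evidence)] = ("REAL_1", run, "control", 0)

kept = ep.pulldown_filter(evidence, min_bait_runs=3, max_control_runs=0)
print("retained after replication + control rule:", kept)

per_run = ep.two_peptide_rule(evidence, min_peptides=2)
print("accepted in bait1 (>= 2 unique peptides):", per_run["bait1"])

# REAL_1 survives (4/4 bait runs, absent from controls).  SPORADIC fails
# replication (2/4), STICKY appears in a control (background binder),
# and ONE_HIT never reaches two unique peptides in any run.
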