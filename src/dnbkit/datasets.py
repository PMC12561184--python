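"""Worked-example inputs reconstructed from the published trial's summary tables.

The dose-escalation study treated 11 patients with advanced gastric
cancer (lenvatinib 4/8/12/16 mg plus paclitaxel, modified 3+3 with a
single accelerated enrolment at 4 mg).  The functions here rebuild
patient-level inputs consistent with the printed summary statistics —
response composition (no CR, one PR per dose group, 8 disease-controlled),
the adverse-event table, the DLT tally, and the external validation
cohort's response split (21 patients: 14 score-low with 5 PR, 7
score-high with none).  Lesion sums, visit times and the per-patient
adverse-event assignment are synthetic reconstructions: they are chosen
to reproduce the printed summary cells exactly, not taken from
patient-level source data (which is not public).
"""

from __future__ import annotations

import pandas as pd

from .clinical import Assessment, ResponseRecord

DOSE_LEVELS_MG = (4.0, 8.0, 12.0, 16.0)


def trial_response_records() -> list[ResponseRecord]:
    """Eleven patients reproducing the published best-response composition.

    One PR per dose group (4 PR), 4 SD (durations straddling the 4-month
    good-responder threshold) and 3 PD; no CR.  Lesion sums are synthetic
    (PR: -36% from baseline; SD: -8%; PD: +30%).
    """

    def rec(pid, dose, kind, sd_duration=None):
        sums = {"PR": [32.0, 30.0], "SD": [46.0, 47.0], "PD": [65.0]}[kind]
        return ResponseRecord(
            patient_id=pid, dose_mg=dose, baseline_sum=50.0,
            assessments=[Assessment(float(2 * (i + 1)), s) for i, s in enumerate(sums)],
            sd_duration_months=sd_duration,
        )

    return [
        rec("4mg-1", 4.0, "PR"),
        rec("8mg-1", 8.0, "PR"),
        rec("8mg-2", 8.0, "SD", sd_duration=5.0),
        rec("8mg-3", 8.0, "PD"),
        rec("12mg-1", 12.0, "PR"),
        rec("12mg-2", 12.0, "SD", sd_duration=4.5),
        rec("12mg-3", 12.0, "PD"),
        rec("16mg-1", 16.0, "PR"),
        rec("16mg-2", 16.0, "SD", sd_duration=3.0),
        rec("16mg-3", 16.0, "SD", sd_duration=2.0),
        rec("16mg-4", 16.0, "PD"),
    ]


def trial_teae_listing() -> pd.DataFrame:
    """Adverse-event listing (patient, term, grade) reproducing the
    published per-term table: 9 of 11 patients with any event (7 with a
    worst-grade-1 term, 3 with grade 2, 2 with grade 3/4)."""
    rows = [
        ("p03", "White blood cell count decreased", 1),
        ("p04", "White blood cell count decreased", 1),
        ("p06", "White blood cell count decreased", 1),
        ("p09", "White blood cell count decreased", 1),
        ("p05", "White blood cell count decreased", 2),
        ("p03", "Neutrophil count decreased", 1),
        ("p04", "Neutrophil count decreased", 1),
        ("p07", "Neutrophil count decreased", 2),
        ("p04", "Platelet count decreased", 1),
        ("p09", "Platelet count decreased", 1),
        ("p06", "Platelet count decreased", 2),
        ("p08", "Hypertension", 1),
        ("p01", "Hypertension", 3),
        ("p08", "Blood bilirubin increased", 1),
        ("p02", "Blood bilirubin increased", 3),
        ("p01", "AST/ALT increased", 1),
        ("p02", "AST/ALT increased", 1),
        ("p03", "Peripheral sensory neuropathy", 1),
        ("p09", "Peripheral sensory neuropathy", 1),
        ("p09", "Anemia", 1),
        ("p07", "Hypoalbuminemia", 2),
        ("p08", "Hyperkalemia", 1),
        ("p05", "Urinary tract infection", 2),
        ("p01", "Biliary tract infection", 3),
    ]
    return pd.DataFrame(rows, columns=["patient", "term", "grade"])


def trial_dlt_outcomes() -> dict:
    """Completed DLT evaluations per dose: no DLT at any level."""
    return {4.0: (1, 0), 8.0: (3, 0), 12.0: (3, 0), 16.0: (4, 0)}


def validation_response_split() -> tuple[pd.Series, pd.Series]:
    """Score groups and response labels of the 21-patient validation cohort
    (14 score-low, 5 of them PR; 7 score-high, none PR)."""
    ids = [f"v{i:02d}" for i in range(21)]
    groups = pd.Series(["low"] * 14 + ["high"] * 7, index=ids, name="group")
    labels = pd.Series(
        ["PR"] * 5 + ["non-PR"] * 9 + ["non-PR"] * 7, index=ids, name="response"
    )
    return groups, labels
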