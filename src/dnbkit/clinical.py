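"""RECIST 1.1 response calling, trial efficacy/safety tables, and 3+3 bookkeeping.

Target-lesion response follows RECIST 1.1: complete response (CR) is
disappearance of all target lesions; partial response (PR) is a >= 30%
decrease of the lesion-diameter sum from baseline; progressive disease
(PD) is a >= 20% increase from the nadir (the smallest prior sum,
baseline included) or the appearance of a new lesion; stable disease (SD)
is everything between.  Best overall response is the best call (CR > PR >
SD > PD) among assessments up to and including the first progression.

Efficacy summaries: ORR is the fraction of patients with best response CR
or PR, DCR additionally counts SD.  Good responders (GoR) are CR, PR, or
SD lasting >= 4 months; poor responders (PoR) are SD < 4 months or PD.

Adverse-event tables count each patient once per term at their worst
grade; the "Any" row counts, per grade column, patients with at least one
term whose worst grade falls in that column.  Percentages are printed to
one decimal, half-up.

Dose escalation follows a modified 3+3 with a single-patient accelerated
start at the lowest level: 0/3 DLT escalates, 1/3 expands the level to 6,
>= 2 DLTs at a level exceed the MTD (the previous level becomes MTD), and
a cleared top level is declared MTD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_ORDER = {"CR": 0, "PR": 1, "SD": 2, "PD": 3, "NE": 4}


def round1(x: float) -> float:
    """Round to one decimal, half-up (matching printed trial tables)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def round_pct(k: int, n: int) -> float:
    """k/n as a percentage, one decimal, half-up."""
    if n == 0:
        raise ValueError("empty denominator")
    return round1(100.0 * k / n)


@dataclass
class Assessment:
    time: float               # months from baseline
    lesion_sum: float         # mm
    new_lesion: bool = False


@dataclass
class ResponseRecord:
    """Per-patient target-lesion course and derived outcomes."""

    patient_id: str
    dose_mg: float
    baseline_sum: float       # mm, > 0 for evaluable patients
    assessments: list[Assessment] = field(default_factory=list)
    sd_duration_months: float | None = None
    pfs_months: float | None = None
    pfs_event: int | None = None
    os_months: float | None = None
    os_event: int | None = None


def classify_response(
    baseline_sum: float,
    assessment_sum: float,
    nadir_sum: float,
    new_lesion: bool = False,
) -> str:
    """Classify a single assessment against baseline and nadir.

    PD if a new lesion appeared or the sum grew >= 20% from the nadir;
    otherwise CR if the sum is 0, PR if the sum fell >= 30% from
    baseline, else SD.  A zero nadir with a non-zero sum (regrowth after
    complete disappearance) is flagged NE.
    """
    if baseline_sum <= 0:
        raise ValueError("baseline target-lesion sum must be > 0")
    if min(assessment_sum, nadir_sum) < 0:
        raise ValueError("lesion sums must be >= 0")
    if new_lesion:
        return "PD"
    if assessment_sum == 0:
        return "CR"
    if nadir_sum == 0:
        return "NE"
    if (assessment_sum - nadir_sum) / nadir_sum >= 0.20:
        return "PD"
    if (baseline_sum - assessment_sum) / baseline_sum >= 0.30:
        return "PR"
    return "SD"


def best_overall_response(record: ResponseRecord) -> str:
    """Best response (CR > PR > SD > PD) over assessments up to first PD."""
    if not record.assessments:
        return "NE"
    nadir = record.baseline_sum
    calls = []
    for a in sorted(record.assessments, key=lambda a: a.time):
        call = classify_response(record.baseline_sum, a.lesion_sum, nadir, a.new_lesion)
        calls.append(call)
        if call == "PD":
            break
        nadir = min(nadir, a.lesion_sum)
    non_ne = [c for c in calls if c != "NE"]
    if not non_ne:
        return "NE"
    return min(non_ne, key=lambda c: RESPONSE_ORDER[c])


def efficacy_table(records: Sequence[ResponseRecord]) -> dict:
    """ORR and DCR with per-category counts.

    ORR = (CR + PR) / n, DCR = (CR + PR + SD) / n, percentages to one
    decimal half-up.
    """
    if not records:
        raise ValueError("no response records")
    best = [best_overall_response(r) for r in records]
    n = len(best)
    counts = {c: best.count(c) for c in ("CR", "PR", "SD", "PD", "NE")}
    orr_n = counts["CR"] + counts["PR"]
    dcr_n = orr_n + counts["SD"]
    return {
        "n": n,
        **{f"n_{c.lower()}": counts[c] for c in ("CR", "PR", "SD", "PD", "NE")},
        "orr_pct": round_pct(orr_n, n),
        "dcr_pct": round_pct(dcr_n, n),
    }


def best_percent_change(record: ResponseRecord) -> float:
    """Best (most negative) percent change of the lesion sum from baseline."""
    if not record.assessments:
        raise ValueError(f"{record.patient_id}: no assessments")
    best = min(a.lesion_sum for a in record.assessments)
    return 100.0 * (best - record.baseline_sum) / record.baseline_sum


def stratify_gor_por(
    records: Sequence[ResponseRecord], sd_duration_threshold: float = 4.0
) -> pd.Series:
    """Good-vs-poor responder labels.

    CR/PR -> GoR; SD with duration >= threshold (months, inclusive) ->
    GoR; SD below threshold or PD -> PoR.  SD without a recorded duration
    stays unlabeled with a warning.
    """
    labels = {}
    for r in records:
        best = best_overall_response(r)
        if best in ("CR", "PR"):
            labels[r.patient_id] = "GoR"
        elif best == "PD":
            labels[r.patient_id] = "PoR"
        elif best == "SD":
            if r.sd_duration_months is None:
                logger.warning(
                    "stratify_gor_por: %s is SD without duration; unlabeled",
                    r.patient_id,
                )
                labels[r.patient_id] = "unknown"
            elif r.sd_duration_months >= sd_duration_threshold:
                labels[r.patient_id] = "GoR"
            else:
                labels[r.patient_id] = "PoR"
        else:
            labels[r.patient_id] = "unknown"
    return pd.Series(labels, name="group")


def teae_summary(listings: pd.DataFrame, n_patients: int) -> pd.DataFrame:
    """Adverse-event summary table in worst-grade-per-patient form.

    ``listings`` has columns ``patient, term, grade`` (grades 1-5; one
    row per event, duplicates merged to the worst grade).  Returns one
    row per term plus a leading ``Any`` row, with columns
    ``all_n, all_pct, g1_n, g1_pct, g2_n, g2_pct, g3_4_n, g3_4_pct``.
    Per term, each patient counts once at their worst grade for that
    term; the Any row counts, per grade column, patients having at least
    one term at that worst grade (so grade columns can overlap), and in
    the All column patients with any event.
    """
    required = {"patient", "term", "grade"}
    missing = required - set(listings.columns)
    if missing:
        raise ValueError(f"listings missing column(s) {sorted(missing)}")
    if not listings.empty and not listings["grade"].isin([1, 2, 3, 4, 5]).all():
        bad = listings.loc[~listings["grade"].isin([1, 2, 3, 4, 5])].iloc[0]
        raise ValueError(f"invalid grade {bad['grade']!r} for patient {bad['patient']!r}")

    def grade_bucket(g: int) -> str:
        return {1: "g1", 2: "g2"}.get(int(g), "g3_4")

    dup = listings.duplicated(subset=["patient", "term"], keep=False)
    if dup.any():
        logger.info(
            "teae_summary: merged %d duplicate (patient, term) row(s) to worst grade",
            int(dup.sum()),
        )
    worst = listings.groupby(["patient", "term"], sort=False)["grade"].max().reset_index()

    rows = []
    # "Any" row: per grade column, patients with >= 1 term at that worst grade
    if worst.empty:
        any_counts = {"all": 0, "g1": 0, "g2": 0, "g3_4": 0}
    else:
        worst["bucket"] = worst["grade"].map(grade_bucket)
        any_counts = {
            "all": worst["patient"].nunique(),
            **{
                b: worst.loc[worst["bucket"] == b, "patient"].nunique()
                for b in ("g1", "g2", "g3_4")
            },
        }
    rows.append(("Any", any_counts))
    for term, grp in worst.groupby("term", sort=False):
        counts = {"all": len(grp)}
        for b in ("g1", "g2", "g3_4"):
            counts[b] = int((grp["bucket"] == b).sum())
        rows.append((term, counts))

    out = []
    for term, counts in rows:
        row = {"term": term}
        for b, key in (("all", "all"), ("g1", "g1"), ("g2", "g2"), ("g3_4", "g3_4")):
            row[f"{key}_n"] = counts[b]
            row[f"{key}_pct"] = round_pct(counts[b], n_patients)
        out.append(row)
    return pd.DataFrame(out).set_index("term")


@dataclass
class EscalationDecision:
    action: str               # enroll-1-accelerated | expand-to-3 | expand-to-6 |
                              # escalate | de-escalate/stop | declare-MTD
    dose: float | None        # the dose the action applies to
    mtd: float | None = None


def escalation_state(
    dose_levels: Sequence[float],
    outcomes: dict,
    accelerated_start: bool = True,
) -> EscalationDecision:
    """Next action of a modified 3+3 escalation with accelerated start.

    ``dose_levels`` are in escalation order; ``outcomes`` maps dose ->
    (n_enrolled, n_dlt) for completed DLT evaluations.  Transitions:
    single-patient accelerated enrolment at the lowest level (0 DLT
    escalates, 1 DLT expands the level to 3); then standard 3+3 — 0/3
    escalates, 1/3 expands to 6, <= 1/6 escalates, >= 2 DLTs at a level
    exceed the MTD (previous level is declared MTD, or the trial stops
    if there is none), and a cleared top level is the MTD.
    """
    for dose in outcomes:
        if dose not in dose_levels:
            raise ValueError(f"outcomes reported for unenrolled dose {dose!r}")
    prev = None
    for i, dose in enumerate(dose_levels):
        top = i == len(dose_levels) - 1
        n, dlt = outcomes.get(dose, (0, 0))
        if dlt > n:
            raise ValueError(f"dose {dose!r}: more DLTs than patients")
        if n == 0:
            if i == 0 and accelerated_start:
                return EscalationDecision("enroll-1-accelerated", dose)
            # previous level cleared; begin enrolment here
            return EscalationDecision("escalate", dose)
        if i == 0 and accelerated_start and n == 1:
            if dlt == 0:
                if top:
                    return EscalationDecision("declare-MTD", dose, mtd=dose)
                prev = dose
                continue
            return EscalationDecision("expand-to-3", dose)
        if n < 3:
            return EscalationDecision("expand-to-3", dose)
        if dlt >= 2:
            return EscalationDecision("de-escalate/stop", dose, mtd=prev)
        if n < 6:
            if dlt == 1:
                return EscalationDecision("expand-to-6", dose)
            # 0/3 clears the level
        else:
            if dlt > 1:
                return EscalationDecision("de-escalate/stop", dose, mtd=prev)
        if top:
            return EscalationDecision("declare-MTD", dose, mtd=dose)
        prev = dose
    raise AssertionError("unreachable")
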