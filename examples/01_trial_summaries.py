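"""Trial efficacy, safety and dose-escalation summaries.

Builds the 11-patient worked example (lesion-sum courses, adverse-event
listing, DLT tally) and derives best overall response per RECIST 1.1,
the ORR/DCR table, the per-term adverse-event table and the 3+3
escalation decision.
"""

from dnbkit import best_overall_response, efficacy_table, escalation_state, teae_summary
from dnbkit.datasets import (
    DOSE_LEVELS_MG,
    trial_dlt_outcomes,
    trial_response_records,
    trial_teae_listing,
)

records = trial_response_records()
print("Best overall response per patient:")
for rec in records:
    print(f"  {rec.patient_id:8s} ({rec.dose_mg:g} mg): {best_overall_response(rec)}")

eff = efficacy_table(records)
print(
    f"\nORR {eff['orr_pct']}% ({eff['n_cr'] + eff['n_pr']}/{eff['n']}), "
    f"DCR {eff['dcr_pct']}% ({eff['n_cr'] + eff['n_pr'] + eff['n_sd']}/{eff['n']})"
)
print("(ORR counts CR+PR; DCR additionally counts SD.)")

print("\nAdverse events (worst grade per patient, % of n=11):")
print(teae_summary(trial_teae_listing(), n_patients=11).to_string())

decision = escalation_state(list(DOSE_LEVELS_MG), trial_dlt_outcomes())
print(
    f"\n3+3 escalation: action={decision.action}, MTD={decision.mtd:g} mg "
    "(all four dose levels cleared without DLT)"
)
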