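"""Building and testing the Cox-weighted prognostic score (DNBscore).

Simulates a tumor/normal survival cohort with three genes carrying both a
tumor-vs-normal shift and a hazard effect, filters the panel through
differential expression and univariate Cox, scores every tumor subject,
splits at the median and compares survival.
"""

from dnbkit import (
    SurvivalSimConfig,
    build_score_model,
    cox_multivariate,
    generate_survival_cohort,
    km_logrank,
    median_stratify,
    score_subjects,
)

cohort, truth = generate_survival_cohort(SurvivalSimConfig(n_subjects=400, seed=2))
print(
    f"Cohort: {len(cohort.tumor_subjects)} tumor + {len(cohort.normal_subjects)} "
    f"normal samples, {cohort.expression.shape[0]} genes, "
    f"{int(cohort.survival['event'].sum())} deaths"
)

model = build_score_model(cohort, list(cohort.expression.index))
print("\nScore model (DE-significant AND Cox-significant genes):")
for g in model.genes:
    print(f"  {g}: beta = {model.betas[g]:+.3f} (true {truth['betas'][g]:+.1f})")

scores = score_subjects(model, cohort.expression[cohort.tumor_subjects])
groups = median_stratify(scores)
print(f"\nMedian split: {(groups == 'low').sum()} low / {(groups == 'high').sum()} high")

_, chi2, p = km_logrank(
    cohort.survival["time"], cohort.survival["event"], groups.loc[cohort.survival.index]
)
print(f"Log-rank: chi2 = {chi2:.1f}, p = {p:.2e} "
      "(high-score patients die faster, as the betas dictate)")

table = cox_multivariate(cohort, groups)
print("\nMultivariate Cox (score group adjusted for age and stage):")
print(table.round(3).to_string(index=False))
print("(HR > 1 with a tight CI for score_high and ~1 for age/stage shows "
      "the score is an independent prognostic factor here.)")
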