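# dnbkit

Dynamic network biomarker (DNB) discovery from longitudinal plasma
proteomics, with a Cox-weighted prognostic score and clinical trial
summaries.

## Who this is for

Translational researchers running early-phase oncology trials who collect
serial blood proteomics (e.g. Olink NPX panels) during treatment and want
to (a) find an efficacy-related protein module from the time course,
(b) turn that module into a per-patient prognostic score on an external
survival cohort, and (c) tabulate the trial itself (RECIST responses,
adverse events, 3+3 dose escalation). Every pipeline input can be
simulated, so the whole analysis builds and tests without any external
download.

## The model

A **dynamic network biomarker** is a group of molecules that acts as an
early-warning signal of a critical state transition: approaching the
tipping point, the group's cross-subject variance inflates, its internal
correlation tightens, and its correlation with the rest of the network
weakens. With baseline D0 as reference and post-baseline sampling points
D5/DT/LT, candidate modules are ranked by the criticality index

```
CI = SDavg · PPCi / PPCo
```

where SDavg is the mean member standard deviation at post-baseline time
points, PPCi the mean |Pearson r| among members, and PPCo the mean
|Pearson r| between members and all other proteins. Identification is a
four-step procedure: (1) keep proteins whose SD at every post-baseline
time point is ≥ 2× their baseline SD; (2) z-score each candidate's mean
time profile; (3) cluster profiles by fuzzy c-means; (4) pick the cluster
meeting the DNB criteria with the highest CI. The **DNB panel** is the
intersection of the winning cluster with a PLS-DA selection (proteins
with VIP ≥ 1 separating good from poor responders), where

```
VIP_j = sqrt( p · Σ_a SS_a w_aj² / Σ_a SS_a ),   Σ_j VIP_j² = p.
```

The **DNBscore** of a subject is the panel's Cox-weighted expression sum
`score = Σ_g β_g · x_g`, with β_g the univariate Cox log-hazard ratios of
the panel genes that pass both a tumor-vs-normal Wilcoxon/BH filter and
a Cox significance filter. Subjects split at the within-cohort median
("high" strictly above) are compared by Kaplan–Meier/log-rank, adjusted
for age and stage by multivariate Cox, and the response-associated score
cutoff in a validation cohort is found by ROC/Youden's J after a
reference-anchored location-scale batch adjustment.

## Worked example

`examples/` contains one narrative script per capability. The trial
summaries (`python examples/01_trial_summaries.py`) print:

```
ORR 36.4% (4/11), DCR 72.7% (8/11)
...
Any                                   9     81.8     7    63.6     3    27.3       2      18.2
White blood cell count decreased      5     45.5     4    36.4     1     9.1       0       0.0
...
3+3 escalation: action=declare-MTD, MTD=16 mg (all four dose levels cleared without DLT)
```

i.e. 4 of 11 patients achieve an objective response (CR or PR), 8 are
disease-controlled, white-blood-cell decrease is the most common adverse
event (45.5% of patients), and the top 16 mg dose level clears without a
dose-limiting toxicity and becomes the maximum tolerated dose. DNB
discovery on a simulated cohort (`python examples/02_dnb_discovery.py`)
prints:

```
SD filter (2x, every post-baseline time point): 11 candidates
  cluster cl1: 11 members, SDavg=2.79, PPCi=0.64, PPCo=0.15, CI=12.1, ...
Winning cluster cl1: recovers 11/12 planted proteins, 0 background
```

— the detector recovers the planted 12-protein module (one member is
lost to the strict conjunctive SD filter) with no background
contamination. `03_prognostic_score.py` and `04_validation_and_tme.py`
continue the chain: the score model recovers the prognostic genes, the
median split separates survival (log-rank p ≈ 2×10⁻²⁴ at n = 400), and
the validation ROC finds the responder-enriched low-score group.

A thin CLI wraps the same library:

```bash
dnbkit --seed 1 --out run1 all        # full simulated pipeline + manifest
dnbkit --out sim simulate             # write synthetic CSV inputs
dnbkit --out out dnb sim/npx_long.csv # DNB detection on a long-format NPX file
```

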