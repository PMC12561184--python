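# Methods

## Scope

dnbkit implements an exploratory biomarker workflow for longitudinal
plasma proteomics collected during treatment: supervised response
contrasts (PLS-DA/VIP), dynamic network biomarker (DNB) detection,
construction and validation of a Cox-weighted prognostic score, and
clinical trial summaries (RECIST 1.1 response calling, efficacy and
adverse-event tables, modified 3+3 bookkeeping). Cell-infiltration
deconvolution, pathway enrichment and assay-level QC are out of scope;
the package consumes fraction tables and normalized NPX-scale values as
given.

## DNB detection

**Model.** Near a critical transition, the molecules of the driving
module show (i) inflated cross-subject variance, (ii) tightened mutual
correlation, and (iii) weakened correlation with the rest of the
network. With the baseline time point (D0) as reference and
post-baseline points D5/DT/LT, the module search proceeds in four steps:

1. *SD filter* — keep proteins whose cross-patient SD at **every**
   post-baseline time point is at least `fold` (default 2) times their
   baseline SD. The conjunctive reading is the stricter of the two
   possible readings of "each time point"; a disjunctive mode (any one
   time point suffices) sits behind a flag. A zero baseline SD passes a
   time point iff the SD there is positive (the limit of the ratio);
   both zero fails. Proteins with fewer than 3 observations at any time
   point are dropped from candidacy with a logged reason.
2. *Profile normalisation* — each candidate's per-time-point mean
   profile is z-scored across time points, so clustering sees shape,
   not level or amplitude.
3. *Fuzzy c-means clustering* of the normalised profiles (fuzzifier
   m = 1.25 on 4-point profiles; both configurable). When the cluster
   count is not fixed, c ∈ [2, 8] is scanned and the count maximising
   the minimum pairwise centroid distance is chosen. Because a fuzzy
   partition always produces at least two clusters even when the
   filter survivors form a single coherent module, a merge step
   follows: clusters whose member-averaged, per-time-point z-scored
   trajectories correlate at |r| ≥ 0.5 across the pooled
   patient × time-point observations are merged transitively. The
   merge statistic deliberately uses the patient-level data rather
   than the two short centroid profiles — the Pearson correlation of
   two 4-point vectors is nearly uniform under the null, whereas the
   patient-level correlation has a standard error of about
   1/√(n_patients × n_timepoints) and cleanly separates "one split
   module" (expected r ≈ 0.9 for an exchangeable ρ = 0.7 module) from
   "two independent modules" (r ≈ 0).
4. *Index-based selection* — per cluster: SDavg (mean member SD over
   post-baseline time points), PPCi (mean |Pearson r| among members),
   PPCo (mean |Pearson r| of members vs all non-members), and
   CI = SDavg · PPCi / max(PPCo, ε) with ε = 10⁻⁶. Among clusters
   passing the three DNB criteria the highest-CI cluster wins; ties
   break by larger membership then lexicographic ID. If no cluster
   passes, the max-CI cluster is returned with a prominent warning.

Correlations are computed per time point across patients on
pairwise-complete patient-matched values and averaged over post-baseline
time points; absolute values are used throughout, since network
tightness concerns correlation magnitude, and per-time-point computation
avoids the mean-trajectory confound that pooling raw observations across
time points would introduce. Time points with fewer than 3 matched
observations are excluded from the averages and flagged in the report.

**Criteria and significance.** The three criteria are evaluated against
the baseline reference: fluctuation (mean SD ratio ≥ `fold`), PPCi
changed significantly, PPCo decreased significantly. "Significantly"
uses a seeded permutation test (default 1000 draws, α = 0.05) that
independently permutes each member protein's patient order within every
post-baseline time point, destroying cross-protein correlation while
preserving marginals. Note that in the default synthetic design the
PPCo-decrease criterion is typically *not* met — baseline correlations
are null by construction, so the member-to-background correlation rises
slightly rather than falls — and selection then proceeds through the
documented max-CI fallback. Real cohorts with correlated baselines can
satisfy all three criteria.

## PLS-DA and VIP

Two-class PLS-DA is fitted by the classical NIPALS PLS1 sequence on
autoscaled (centered, unit-variance) proteins with the binary label
coded 0/1 and centered; for a single response the NIPALS inner loop is
exact in one step, so the fit is deterministic. Variable importance in
projection is VIP_j = √(p Σ_a SS_a w_aj² / Σ_a SS_a) with SS_a the
response sum of squares explained by component a; Σ_j VIP_j² = p holds
identically and VIP ≥ 1 (inclusive) defines the selection. Defaults:
2 components (typical for two-class NPX-scale data; configurable),
per-protein mean imputation of missing cells (logged). Two contrasts are
run: baseline-only samples and all samples, each sample weighted equally
with its patient's good/poor-responder label. The DNB panel is the exact
intersection of the winning DNB cluster with the PLS-DA selection.

## Prognostic score

Panel genes are filtered by (1) tumor-vs-normal two-sided Wilcoxon
rank-sum with Benjamini–Hochberg adjustment (q < 0.05; a Welch t-test
mode exists) and (2) univariate Cox proportional hazards (Wald
p < 0.05); survivors contribute their Cox β to the score
`score_i = Σ_g β_g x_gi`, evaluated on the same expression scale the β
was fitted on — cross-cohort transfer therefore goes through batch
adjustment first. Cox models are fitted with lifelines, which handles
ties by Efron's method; the toy oracles in the test suite have untied
event times, where Efron, Breslow and the exact likelihood coincide.
Very small fits (< 10 subjects or < 5 events) warn rather than fail so
that hand-checkable toys run; estimates with |β| > 20 are flagged as
possible complete separation, and non-convergent genes are excluded with
a flag.

Stratification uses the cohort's own median, "high" strictly above it
(a subject exactly at the median is low). Group survival is compared by
Kaplan–Meier and the two-group log-rank test; independence from age and
stage by a joint Cox fit (exactly collinear covariates raise). The
response-associated cutoff maximises Youden's J over a threshold sweep
whose direction is chosen by the oriented AUC (responders are expected
at low scores for a hazard-weighted sum); ties resolve to the lowest
cutoff. Score-vs-infiltration associations are Spearman correlations,
BH-adjusted across cell types, on ≥ 5 overlapping subjects.

**Batch adjustment.** Cross-cohort transfer uses a reference-anchored
location-scale adjustment: per gene, each non-reference batch is
standardised by its own moments and mapped to the reference batch's mean
and SD; the reference batch is untouched, zero-variance genes fall back
to a mean shift with a warning, and the operation is idempotent. This is
a deliberate, simpler stand-in for empirical-Bayes batch correction: the
downstream statistic (a weighted sum compared to its within-cohort
median) is invariant to the difference for the designs tested here.

## Clinical summaries

RECIST 1.1 target-lesion rules: CR = disappearance (sum 0), PR = ≥ 30%
decrease from baseline, PD = ≥ 20% increase from the nadir (smallest
prior sum, baseline included) or a new lesion, SD otherwise; a zero
nadir with regrowth is flagged NE. Best overall response is the best
call (CR > PR > SD > PD) up to and including the first progression;
response confirmation by repeat imaging is not modeled. ORR counts
CR+PR, DCR additionally SD; percentages print to one decimal, half-up.
Good responders are CR, PR, or SD lasting ≥ 4 months (inclusive); poor
responders SD < 4 months or PD; SD without a recorded duration stays
unlabeled with a warning. Adverse-event tables count each patient once
per term at the worst grade; the "Any" row counts, per grade column,
patients with at least one term at that worst grade, so grade columns
may overlap across terms. Dose escalation follows a modified 3+3 with a
single-patient accelerated start at the lowest level: 0/3 escalates,
1/3 expands to 6, ≤ 1/6 escalates, ≥ 2 DLTs exceed the MTD (previous
level declared), a cleared top level is the MTD.

## Synthetic cohorts

The generators produce every input the pipeline needs, with the
statistical structure the analysis assumes; equal seeds give
bit-identical outputs.

*Longitudinal NPX* — values are Gaussian on the NPX scale (NPX is
already log2-like; no count model). Baseline values are i.i.d. per
protein around protein-specific means (mean ~ N(5, 2), SD ~ U(0.8,
1.2)). At post-baseline time points the planted module has SD amplified
by `sd_amplification` (default 3), exchangeable correlation `rho_in`
(default 0.7) through a shared per-patient latent factor
(x = √ρ·z_common + √(1−ρ)·z_own, giving exact exchangeable
correlation), a background loading chosen so that planted-to-background
correlation equals `rho_out` (default 0.1), and a shared rising mean
trajectory of amplitude `trajectory_amplitude` (default 2 NPX) — the
coherent treatment-course fluctuation that profile clustering groups
on. Poor responders' planted proteins are shifted by `effect_shift`
(default 1 NPX, a free choice: the magnitude of baseline group
separation is not externally constrained) at baseline only. An optional
per-time-point dropout mask emulates uneven real-world sampling
(default off). What this does **not** emulate: assay noise mechanisms
(hook effects, detection limits), heavy-tailed or skewed NPX
distributions, patient-level confounders correlated with group, or
drifting background correlation — so passing tests demonstrate
correctness of the machinery under the stated model, not robustness to
those real-data features.

*Survival* — event times are exponential with hazard
h₀·exp(Σ β_g x_g) (default h₀ = 0.03/month, three non-zero β of
0.7/0.5/−0.6), censoring an independent exponential, tumor expression
shifted by `de_shift` on a designated subset (default: the non-zero-β
genes) relative to normals, age ~ N(63, 10) truncated to [35, 80] and
stage ordinal 1–4 uniform, independent of expression. Proportional
hazards holds by construction.

*Validation* — expression for the score-model genes plus noise genes,
shifted wholesale by `batch_shift`; response is Bernoulli with
logit p = logit(0.24) − strength · z(score), so the objective-response
probability decreases monotonically in the true score.

## Numerical choices and degenerate inputs

- PPCo floor ε = 10⁻⁶ in the CI ratio; singleton clusters and
  clusters equal to the full protein set are errors.
- Constant candidate profiles are dropped before clustering; constant
  Cox covariates return β = 0, p = 1.
- FCM: seeded centroid initialisation from distinct data rows,
  convergence at max membership change < 10⁻⁹ or 300 iterations;
  membership rows sum to 1 by construction.
- Median-split tie rule: "high" is strictly above the median; all-equal
  scores are an error (no stratification possible).
- ROC ties: lowest threshold attaining the maximal Youden J.
- Rounding of printed percentages: one decimal, half-up.
- Readers reject malformed tables naming the offending row/column;
  writers emit floats at 9 significant digits, enough to round-trip.

## Problem sizes used in tests

The default test and acceptance designs are 40 patients × 120 proteins ×
4 time points with a 12-protein planted module (20 seeded replicates),
survival cohorts of 100–1000 subjects, 200 null simulations for type-I
calibration, and 200-subject validation cohorts — sizes representative
of the exploratory setting (a trial-scale proteomics arm against a
TCGA-scale survival cohort) while keeping a full run in the order of
seconds to a minute.

## Known limitations

- The PPCo-decrease criterion rarely triggers under the default
  generator (see above); the selection fallback covers it, but criteria
  flags on synthetic runs should be read with that in mind.
- The permutation null for PPCi/PPCo destroys all cross-protein
  correlation, which is conservative when the background itself is
  weakly correlated.
- Univariate Cox β estimates are marginal; with several prognostic
  genes the score weights are attenuated relative to the generating
  coefficients (non-collapsibility), which affects calibration of the
  score scale but not ranking or stratification.
- The location-scale batch adjustment assumes batch effects are
  per-gene affine; it cannot remove interaction-type batch effects.
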