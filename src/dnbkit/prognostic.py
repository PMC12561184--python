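"""Cox-weighted prognostic score (DNBscore) construction and validation.

From a survival cohort and a candidate gene panel, the score is built in
three steps: (1) a tumor-vs-normal differential-expression filter
(Wilcoxon rank-sum, Benjamini-Hochberg adjusted); (2) a univariate Cox
proportional-hazards fit per surviving gene, keeping genes with Wald
p < alpha; (3) the score itself,

    score_i = sum_g beta_g * x_gi,

the beta-weighted sum of the retained genes' expression.  Subjects are
stratified at the within-cohort median (strictly above the median is
"high"), survival between strata is compared by Kaplan-Meier / log-rank,
independence from age and stage is assessed by multivariate Cox, a
response-associated cutoff is found by ROC / Youden's J, and score vs
cell-infiltration associations use Spearman correlation with BH
adjustment.

Cox models are fitted with lifelines (Efron tie handling); Kaplan-Meier
and log-rank likewise.  Expression enters the score on the scale it was
fitted on — no re-scaling — so cross-cohort transfer must go through
batch adjustment first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass
class ScoreModel:
    """Per-gene Cox beta weights; maps an expression profile to a scalar score."""

    genes: list
    betas: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in self.genes if g not in self.betas]
        if missing:
            raise ValueError(f"genes without a beta coefficient: {missing}")

    def score(self, expr: pd.DataFrame) -> pd.Series:
        return score_subjects(self, expr)

    def to_files(self, csv_path: str | Path, provenance_path: str | Path | None = None) -> None:
        pd.DataFrame(
            {"gene": self.genes, "beta": [self.betas[g] for g in self.genes]}
        ).to_csv(csv_path, index=False, float_format="%.12g")
        if provenance_path is not None:
            Path(provenance_path).write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_files(cls, csv_path: str | Path, provenance_path: str | Path | None = None) -> "ScoreModel":
        df = pd.read_csv(csv_path)
        prov = {}
        if provenance_path is not None and Path(provenance_path).exists():
            prov = json.loads(Path(provenance_path).read_text())
        return cls(
            genes=list(df["gene"]),
            betas=dict(zip(df["gene"], df["beta"])),
            provenance=prov,
        )


def de_filter(
    cohort: SurvivalCohort,
    genes: Sequence[str] | None = None,
    alpha_fdr: float = 0.05,
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Tumor-vs-normal differential expression filter.

    Per gene, a two-sided Wilcoxon rank-sum (Mann-Whitney U) test of
    tumor against normal samples (``method="ttest"`` switches to Welch's
    t), Benjamini-Hochberg adjusted across genes.  Returns a DataFrame
    (gene, stat, p, q, selected) where ``selected`` marks adjusted
    p < ``alpha_fdr``.
    """
    tumor = cohort.expression[cohort.tumor_subjects]
    normal = cohort.expression[cohort.normal_subjects]
    if tumor.shape[1] < 3 or normal.shape[1] < 3:
        raise ValueError("need >= 3 tumor and >= 3 normal samples")
    if genes is None:
        genes = list(cohort.expression.index)
    rows = []
    for gene in genes:
        a = tumor.loc[gene].dropna().to_numpy()
        b = normal.loc[gene].dropna().to_numpy()
        if method == "wilcoxon":
            if np.array_equal(np.sort(a), np.sort(b)) or (a.std() == 0 and b.std() == 0 and a[0] == b[0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        elif method == "ttest":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append((gene, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "stat", "p"]).set_index("gene")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["selected"] = out["q"] < alpha_fdr
    logger.info(
        "de_filter(%s): %d of %d genes at FDR < %g", method,
        int(out["selected"].sum()), len(out), alpha_fdr,
    )
    return out


@dataclass
class CoxResult:
    beta: float
    hr: float
    p: float
    se: float
    converged: bool = True
    flag: str = ""


def _cox_frame(cohort: SurvivalCohort, columns: Mapping[str, pd.Series]) -> pd.DataFrame:
    df = cohort.survival[["time", "event"]].copy()
    for name, series in columns.items():
        df[name] = series.reindex(df.index)
    return df


def cox_univariate(cohort: SurvivalCohort, gene: str) -> CoxResult:
    """Univariate Cox proportional-hazards fit for one gene.

    Returns beta (log hazard ratio), HR = exp(beta), Wald p and SE.  A
    constant covariate carries no information and returns beta 0 with
    p 1; non-convergence (e.g. complete separation) is flagged rather
    than raised so callers can exclude the gene.
    """
    if gene not in cohort.expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    x = cohort.expression.loc[gene, cohort.survival.index]
    if float(x.std(ddof=1)) == 0.0:
        return CoxResult(beta=0.0, hr=1.0, p=1.0, se=np.inf, flag="constant covariate")
    n_events = int(cohort.survival["event"].sum())
    if n_events < 2:
        raise ValueError("Cox fit needs at least two observed events")
    if n_events < 5 or len(cohort.survival) < 10:
        logger.warning(
            "cox_univariate(%s): small sample (%d subjects, %d events); "
            "estimate will be unstable", gene, len(cohort.survival), n_events,
        )
    df = _cox_frame(cohort, {"x": x})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult(beta=np.nan, hr=np.nan, p=np.nan, se=np.nan,
                         converged=False, flag="non-convergence")
    s = cph.summary.loc["x"]
    flag = ""
    if abs(s["coef"]) > 20:
        flag = "possible complete separation"
    return CoxResult(beta=float(s["coef"]), hr=float(np.exp(s["coef"])),
                     p=float(s["p"]), se=float(s["se(coef)"]), flag=flag)


def build_score_model(
    cohort: SurvivalCohort,
    panel_genes: Sequence[str],
    alpha_cox: float = 0.05,
    alpha_fdr: float = 0.05,
    de_method: str = "wilcoxon",
) -> ScoreModel:
    """Build the prognostic score model from a survival cohort and a panel.

    Panel genes must pass both the DE filter (tumor vs normal, BH-adjusted
    p < ``alpha_fdr``) and the univariate Cox filter (Wald p <
    ``alpha_cox``); survivors are retained with their Cox beta.  Raises
    if no gene survives.
    """
    panel_genes = [g for g in panel_genes if g in cohort.expression.index]
    if not panel_genes:
        raise ValueError("panel is empty or disjoint from the expression matrix")
    de = de_filter(cohort, genes=panel_genes, alpha_fdr=alpha_fdr, method=de_method)
    de_pass = list(de.index[de["selected"]])
    cox_rows = {}
    for gene in de_pass:
        res = cox_univariate(cohort, gene)
        if res.converged and not np.isnan(res.beta):
            cox_rows[gene] = res
    retained = [g for g, r in cox_rows.items() if r.p < alpha_cox]
    if not retained:
        raise ValueError("no gene passes both the DE and Cox filters")
    betas = {g: cox_rows[g].beta for g in retained}
    provenance = {
        "panel": list(panel_genes),
        "alpha_fdr": alpha_fdr,
        "alpha_cox": alpha_cox,
        "de_method": de_method,
        "de_q": {g: float(de.loc[g, "q"]) for g in panel_genes},
        "cox_p": {g: float(r.p) for g, r in cox_rows.items()},
    }
    logger.info(
        "build_score_model: %d panel -> %d DE -> %d scored genes",
        len(panel_genes), len(de_pass), len(retained),
    )
    return ScoreModel(genes=retained, betas=betas, provenance=provenance)


def score_subjects(model: ScoreModel, expr: pd.DataFrame) -> pd.Series:
    """Per-subject score: sum over model genes of beta_g * expression_gi.

    Raises if any model gene is absent from the matrix — never a silent
    zero.
    """
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"expression matrix lacks model gene(s): {missing}")
    beta = np.array([model.betas[g] for g in model.genes])
    vals = expr.loc[model.genes].to_numpy(dtype=float)
    return pd.Series(beta @ vals, index=expr.columns, name="score")


def median_stratify(scores: pd.Series) -> pd.Series:
    """Median split: strictly above the median is "high", at or below is "low"."""
    if len(scores) < 2:
        raise ValueError("need >= 2 subjects to stratify")
    med = float(scores.median())
    if (scores == scores.iloc[0]).all():
        raise ValueError("all scores identical: no stratification possible")
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="group")


def km_logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> tuple[dict, float, float]:
    """Kaplan-Meier tables per group plus the two-group log-rank test.

    Returns ({group: table(time, at_risk, events, survival)}, chi2, p).
    """
    times, events, groups = (pd.Series(v) for v in (times, events, groups))
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {labels}")
    tables = {}
    for label in labels:
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"group {label!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(label))
        table = kmf.event_table.copy()
        tables[label] = pd.DataFrame(
            {
                "time": table.index,
                "at_risk": table["at_risk"].to_numpy(),
                "events": table["observed"].to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        ).reset_index(drop=True)
    a, b = (groups == labels[0]), (groups == labels[1])
    res = logrank_test(times[a], times[b], events[a], events[b])
    return tables, float(res.test_statistic), float(res.p_value)


def cox_multivariate(
    cohort: SurvivalCohort,
    score_groups: pd.Series,
    covariates: Sequence[str] = ("age", "stage"),
) -> pd.DataFrame:
    """Multivariate Cox fit of score group plus clinical covariates.

    Returns a forest-plot-ready table (term, HR, ci_low, ci_high, p).
    The score group enters as an indicator (high = 1).  Exactly collinear
    covariate pairs raise.
    """
    cols = {"score_high": (score_groups == "high").astype(float)}
    for cov in covariates:
        if cov not in cohort.survival.columns:
            raise KeyError(f"covariate {cov!r} missing from cohort")
        cols[cov] = cohort.survival[cov].astype(float)
    df = _cox_frame(cohort, cols)
    x = df.drop(columns=["time", "event"])
    corr = x.corr().abs()
    np.fill_diagonal(corr.to_numpy(), 0.0)
    if (corr > 0.9999).any().any():
        pair = corr.stack().idxmax()
        raise ValueError(f"collinear covariates: {pair[0]} and {pair[1]}")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary
    return pd.DataFrame(
        {
            "term": s.index,
            "HR": np.exp(s["coef"]).to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"]).to_numpy(),
            "ci_high": np.exp(s["coef upper 95%"]).to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def response_cutoff(
    scores: pd.Series, labels: pd.Series, positive: str = "PR"
) -> dict:
    """ROC-based score cutoff for objective response.

    The ROC is built by sweeping every observed score as a threshold.
    The sweep orients itself: if responders sit at *low* scores (AUC of
    "higher score predicts response" below 0.5, the expected direction
    for a hazard-weighted score), prediction is "score <= threshold is a
    responder"; otherwise "score >= threshold".  The reported AUC is the
    oriented one, so a perfectly separating score gives AUC 1 in either
    direction.  The cutoff maximises Youden's J = sensitivity +
    specificity - 1, ties resolved to the lowest cutoff; subjects are
    then labeled low (score <= cutoff) / high (score > cutoff).

    Returns dict(roc=DataFrame(threshold, tpr, fpr), auc, cutoff,
    direction, groups).
    """
    labels = pd.Series(labels)
    y = (labels == positive).astype(int)
    if y.nunique() < 2:
        raise ValueError("both response classes must be present")

    def sweep(sign: float) -> pd.DataFrame:
        s = sign * scores.to_numpy()
        order = np.argsort(-s, kind="mergesort")
        s_sorted, y_sorted = s[order], y.to_numpy()[order]
        pos, neg = y_sorted.sum(), (1 - y_sorted).sum()
        thresholds, tprs, fprs = [], [], []
        tp = fp = 0
        i, n = 0, len(y_sorted)
        while i < n:
            thr = s_sorted[i]
            while i < n and s_sorted[i] == thr:
                tp += y_sorted[i]
                fp += 1 - y_sorted[i]
                i += 1
            thresholds.append(sign * thr)
            tprs.append(tp / pos)
            fprs.append(fp / neg)
        roc = pd.DataFrame({"threshold": thresholds, "tpr": tprs, "fpr": fprs})
        roc.attrs["auc"] = float(
            np.trapezoid(np.r_[0.0, roc["tpr"]], np.r_[0.0, roc["fpr"]])
        )
        return roc

    roc_high = sweep(1.0)
    if roc_high.attrs["auc"] >= 0.5:
        roc, direction = roc_high, "high"
    else:
        roc, direction = sweep(-1.0), "low"
    auc = roc.attrs["auc"]
    j = roc["tpr"] - roc["fpr"]
    best = j.max()
    cutoff = float(roc.loc[j == best, "threshold"].min())  # ties -> lowest cutoff
    groups = pd.Series(
        np.where(scores > cutoff, "high", "low"), index=scores.index, name="group"
    )
    return {"roc": roc, "auc": auc, "cutoff": cutoff, "direction": direction,
            "groups": groups}


def response_table(groups: pd.Series, labels: pd.Series, positive: str = "PR") -> pd.DataFrame:
    """Per-group and overall objective-response tabulation.

    Returns rows (group, n, n_pr, pr_rate_pct) for each group plus an
    ``overall`` row; percentages are rounded half-up to one decimal.
    """
    from .clinical import round_pct  # shared printed-precision rule

    groups, labels = pd.Series(groups), pd.Series(labels)
    rows = []
    for label in sorted(groups.unique()):
        mask = groups == label
        n = int(mask.sum())
        n_pr = int((labels[mask] == positive).sum())
        rows.append((label, n, n_pr, round_pct(n_pr, n)))
    n_all = len(groups)
    n_pr_all = int((labels == positive).sum())
    rows.append(("overall", n_all, n_pr_all, round_pct(n_pr_all, n_all)))
    return pd.DataFrame(rows, columns=["group", "n", "n_pr", "pr_rate_pct"])


def fraction_correlation(
    scores: pd.Series, fractions: pd.DataFrame, min_overlap: int = 5
) -> pd.DataFrame:
    """Spearman correlation of a score with cell-infiltration fractions.

    Per cell type (row of ``fractions``), Spearman rho with two-sided p
    on the overlapping subjects, BH-adjusted across cell types.
    """
    overlap = fractions.columns.intersection(scores.index)
    if len(overlap) < min_overlap:
        raise ValueError(
            f"only {len(overlap)} overlapping subjects (< {min_overlap})"
        )
    rows = []
    for cell_type in fractions.index:
        rho, p = stats.spearmanr(
            scores[overlap].to_numpy(), fractions.loc[cell_type, overlap].to_numpy()
        )
        rows.append((cell_type, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["cell_type", "rho", "p"]).set_index("cell_type")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
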