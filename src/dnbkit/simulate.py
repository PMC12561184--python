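"""Synthetic cohort generators with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs:

* :func:`generate_longitudinal_npx` — a multi-time-point NPX-scale protein
  matrix with a planted DNB cluster: amplified cross-patient variance,
  exchangeable intra-cluster correlation and a shared mean trajectory at
  post-baseline time points, plus a baseline (D0) group shift separating
  poor from good responders.
* :func:`generate_survival_cohort` — a tumor/normal expression matrix with
  proportional-hazards survival driven by a known coefficient vector, plus
  age and stage covariates.
* :func:`generate_validation_cohort` — a batch-shifted expression matrix
  whose objective-response labels are logistically linked to the true
  prognostic score.

Baseline values are Gaussian on the NPX scale (NPX is already log2-like,
so no count model is used).  Correlated planted values are produced via a
shared latent factor, x = sqrt(rho) * z_common + sqrt(1 - rho) * z_own,
which gives exact exchangeable correlation.  Equal seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NpxMatrix, SurvivalCohort


@dataclass
class LongitudinalSimConfig:
    """Configuration of the longitudinal NPX generator.

    Parameters
    ----------
    n_patients, n_proteins, n_planted
        Cohort and panel sizes; ``n_planted`` is the size of the true DNB
        cluster and must be smaller than ``n_proteins``.
    timepoints
        Ordered sampling labels; the first is the baseline reference.
    sd_amplification
        Ratio a of post-baseline to baseline cross-patient SD for planted
        proteins.  Recovery by the 2x SD filter needs a > 2 (documented,
        not enforced).
    rho_in, rho_out
        Pairwise correlation among planted proteins, and between planted
        and background proteins, at post-baseline time points.  Require
        0 <= rho_out <= rho_in < 1.
    frac_gor
        Fraction of patients labeled GoR (good responder).
    effect_shift
        Mean NPX shift of planted proteins in PoR patients at baseline —
        the group-separable signal PLS-DA is meant to find.
    trajectory_amplitude
        Amplitude (NPX units) of the deterministic mean trajectory shared
        by planted proteins at post-baseline time points; this is the
        coherent "wide fluctuation during treatment" that profile
        clustering groups on.
    dropout
        Optional per-time-point probability of a patient's sample being
        missing (emulates uneven real-world sampling); default no dropout.
    """

    n_patients: int = 40
    n_proteins: int = 120
    n_planted: int = 12
    timepoints: Sequence[str] = ("D0", "D5", "DT", "LT")
    sd_amplification: float = 3.0
    rho_in: float = 0.7
    rho_out: float = 0.1
    frac_gor: float = 0.5
    effect_shift: float = 1.0
    trajectory_amplitude: float = 2.0
    dropout: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_proteins, self.n_planted) <= 0:
            raise ValueError("counts must be positive")
        if self.n_planted >= self.n_proteins:
            raise ValueError("n_planted must be < n_proteins")
        if not (0.0 <= self.rho_out <= self.rho_in < 1.0):
            raise ValueError("require 0 <= rho_out <= rho_in < 1")
        if not (0.0 <= self.frac_gor <= 1.0):
            raise ValueError("frac_gor must be in [0, 1]")
        if self.sd_amplification <= 0:
            raise ValueError("sd_amplification must be positive")
        if len(self.timepoints) < 2:
            raise ValueError("need a baseline plus at least one later time point")


def generate_longitudinal_npx(config: LongitudinalSimConfig) -> tuple[NpxMatrix, dict]:
    """Generate a longitudinal NPX matrix with a planted DNB cluster.

    Returns the matrix and a truth record with keys ``planted`` (protein
    IDs of the true cluster) and ``groups`` (patient -> GoR/PoR).

    Baseline (D0) values are i.i.d. per protein around protein-specific
    means.  At post-baseline time points, planted proteins have SD equal
    to ``sd_amplification`` times their baseline SD, pairwise correlation
    ``rho_in`` (via a shared per-patient-per-time latent factor) and a
    shared rising mean trajectory; background proteins keep their baseline
    SD and carry a weak loading on the same factor so that their
    correlation with planted proteins is ``rho_out``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    P, G, K = config.n_patients, config.n_proteins, config.n_planted
    tps = list(config.timepoints)
    a = config.sd_amplification

    proteins = [f"P{j:04d}" for j in range(G)]
    patients = [f"pt{i:03d}" for i in range(P)]
    planted = proteins[:K]

    n_gor = int(round(config.frac_gor * P))
    groups = np.array(["GoR"] * n_gor + ["PoR"] * (P - n_gor))
    rng.shuffle(groups)

    mu = rng.normal(5.0, 2.0, size=G)          # protein baseline means (NPX)
    sigma = rng.uniform(0.8, 1.2, size=G)      # protein baseline SDs

    # background loading b on the common factor gives corr(planted, bg)
    # = sqrt(rho_in * b) = rho_out  =>  b = rho_out^2 / rho_in
    b = config.rho_out**2 / config.rho_in if config.rho_in > 0 else 0.0

    # planted mean trajectory: 0 at baseline, rising afterwards
    n_post = len(tps) - 1
    shape = np.linspace(1.0, 2.0, n_post) if n_post > 1 else np.array([1.0])
    traj = config.trajectory_amplitude * shape / shape[-1]

    por = groups == "PoR"
    blocks = {}
    for k, tp in enumerate(tps):
        x = np.empty((G, P))
        if k == 0:
            z = rng.normal(size=(G, P))
            x = mu[:, None] + sigma[:, None] * z
            x[:K, por] += config.effect_shift
        else:
            z_common = rng.normal(size=P)                 # shared factor per patient
            z_own = rng.normal(size=(G, P))
            load = np.full(G, np.sqrt(b))
            load[:K] = np.sqrt(config.rho_in)
            amp = sigma.copy()
            amp[:K] = a * sigma[:K]
            x = (
                mu[:, None]
                + amp[:, None] * (load[:, None] * z_common[None, :]
                                  + np.sqrt(1.0 - load[:, None] ** 2) * z_own)
            )
            x[:K] += traj[k - 1]
        blocks[tp] = x

    records = []
    sample_ids, meta_rows = [], []
    for k, tp in enumerate(tps):
        drop_p = (config.dropout or {}).get(tp, 0.0)
        keep = rng.random(P) >= drop_p
        if k == 0:
            keep[:] = True  # every patient has a baseline sample
        for i, patient in enumerate(patients):
            if not keep[i]:
                continue
            sid = f"{patient}_{tp}"
            sample_ids.append(sid)
            meta_rows.append((patient, tp, k))
            records.append(blocks[tp][:, i])

    values = pd.DataFrame(
        np.column_stack(records), index=pd.Index(proteins, name="protein_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    sample_meta = pd.DataFrame(
        meta_rows, index=values.columns,
        columns=["patient_id", "timepoint", "collection_order"],
    )
    patient_meta = pd.DataFrame(
        {"group": groups}, index=pd.Index(patients, name="patient_id")
    )
    m = NpxMatrix(values=values, sample_meta=sample_meta, patient_meta=patient_meta)
    truth = {
        "planted": list(planted),
        "groups": dict(zip(patients, groups)),
    }
    return m, truth


@dataclass
class SurvivalSimConfig:
    """Configuration of the proportional-hazards survival generator.

    Event times are exponential with hazard
    ``baseline_hazard * exp(sum_g beta_g x_g)``; censoring is an
    independent exponential with rate ``censor_rate``.  Tumor samples
    carry ``de_shift`` on the designated DE subset relative to normal
    samples; by default that subset is the set of genes with non-zero
    ``true_betas``.  Age is Normal(63, 10) truncated to [35, 80] and
    stage is ordinal 1-4 uniform, both independent of expression.
    """

    n_subjects: int = 400
    n_genes: int = 20
    true_betas: Sequence[float] | None = None
    baseline_hazard: float = 0.03
    censor_rate: float = 0.01
    n_normal: int = 50
    de_shift: float = 2.0
    de_genes: Sequence[int] | None = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.n_genes) <= 0 or self.n_normal < 0:
            raise ValueError("counts must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive (all-zero hazard)")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")

    def betas(self) -> np.ndarray:
        if self.true_betas is None:
            # default: first three genes prognostic, rest null
            beta = np.zeros(self.n_genes)
            beta[: min(3, self.n_genes)] = [0.7, 0.5, -0.6][: min(3, self.n_genes)]
            return beta
        beta = np.asarray(self.true_betas, dtype=float)
        if beta.shape != (self.n_genes,):
            raise ValueError("true_betas must have length n_genes")
        return beta


def generate_survival_cohort(config: SurvivalSimConfig) -> tuple[SurvivalCohort, dict]:
    """Generate a tumor/normal cohort with proportional-hazards survival.

    Returns the cohort and a truth record with ``betas`` (per-gene) and
    ``de_genes`` (IDs of the shifted subset).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_subjects, config.n_genes
    beta = config.betas()
    genes = [f"G{j:03d}" for j in range(g)]
    tumor_ids = [f"T{i:04d}" for i in range(n)]
    normal_ids = [f"N{i:04d}" for i in range(config.n_normal)]

    de_idx = (
        np.flatnonzero(beta != 0)
        if config.de_genes is None
        else np.asarray(config.de_genes, dtype=int)
    )

    x_tumor = rng.normal(size=(g, n))
    x_tumor[de_idx, :] += config.de_shift
    x_normal = rng.normal(size=(g, config.n_normal))

    linpred = beta @ x_tumor
    hazard = config.baseline_hazard * np.exp(linpred)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # strictly positive

    age = np.clip(rng.normal(63.0, 10.0, size=n), 35.0, 80.0)
    stage = rng.integers(1, 5, size=n)

    survival = pd.DataFrame(
        {"time": time, "event": event, "age": age, "stage": stage},
        index=pd.Index(tumor_ids, name="subject_id"),
    )
    expression = pd.DataFrame(
        np.hstack([x_tumor, x_normal]),
        index=pd.Index(genes, name="gene_id"),
        columns=tumor_ids + normal_ids,
    )
    tissue = pd.Series(
        ["tumor"] * n + ["normal"] * config.n_normal, index=expression.columns
    )
    cohort = SurvivalCohort(
        survival=survival, expression=expression, tissue=tissue, time_unit="months"
    )
    truth = {
        "betas": dict(zip(genes, beta)),
        "de_genes": [genes[j] for j in de_idx],
    }
    return cohort, truth


def generate_validation_cohort(
    score_model,
    n_subjects: int = 200,
    batch_shift: float = 2.0,
    response_link_strength: float = 2.0,
    base_response_rate: float = 0.24,
    n_extra_genes: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Generate a batch-shifted validation expression matrix with response labels.

    Expression for the model's genes (plus ``n_extra_genes`` noise genes)
    is drawn on the same scale as the survival cohort, then every gene in
    this cohort is shifted by ``batch_shift`` (a pure batch effect).  The
    probability of objective response follows a logistic link that
    decreases with the true (pre-shift) score:
    ``logit p = logit(base_response_rate) - strength * zscore(score)``.

    Returns (expression, response labels in {PR, non-PR}, batch labels).
    """
    if not getattr(score_model, "genes", None):
        raise ValueError("empty score model")
    rng = np.random.default_rng(seed)
    genes = list(score_model.genes) + [f"X{j:03d}" for j in range(n_extra_genes)]
    subjects = [f"V{i:04d}" for i in range(n_subjects)]
    x = rng.normal(size=(len(genes), n_subjects))
    expr_clean = pd.DataFrame(x, index=pd.Index(genes, name="gene_id"), columns=subjects)

    score = score_model.score(expr_clean)
    sd = score.std(ddof=1)
    z = (score - score.mean()) / (sd if sd > 0 else 1.0)
    intercept = np.log(base_response_rate / (1.0 - base_response_rate))
    logit = intercept - response_link_strength * z
    p = 1.0 / (1.0 + np.exp(-logit))
    responded = rng.random(n_subjects) < p
    labels = pd.Series(np.where(responded, "PR", "non-PR"), index=subjects)

    expr = expr_clean + batch_shift
    batches = pd.Series("validation", index=expr.columns)
    return expr, labels, batches
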