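import numpy as np
import pandas as pd
import pytest

from dnbkit import (
    LongitudinalSimConfig,
    SurvivalSimConfig,
    generate_longitudinal_npx,
    generate_survival_cohort,
)
from dnbkit.io import NpxMatrix, SurvivalCohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic longitudinal cohort with a planted DNB cluster."""
    return generate_longitudinal_npx(LongitudinalSimConfig(seed=11))


@pytest.fixture(scope="session")
def survival_cohort():
    """Default synthetic survival cohort (3 prognostic+DE genes of 20)."""
    return generate_survival_cohort(SurvivalSimConfig(seed=11))


@pytest.fixture()
def tiny_npx():
    """2 patients x 2 time points x 3 proteins, complete, hand-sized."""
    proteins = ["A", "B", "C"]
    samples = ["p1_D0", "p1_D5", "p2_D0", "p2_D5"]
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4), index=proteins, columns=samples
    )
    sample_meta = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p2"],
            "timepoint": ["D0", "D5", "D0", "D5"],
            "collection_order": [0, 1, 0, 1],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    patient_meta = pd.DataFrame(
        {"group": ["GoR", "PoR"]}, index=pd.Index(["p1", "p2"], name="patient_id")
    )
    return NpxMatrix(values=values, sample_meta=sample_meta, patient_meta=patient_meta)


@pytest.fixture()
def toy_cox_cohort():
    """Six untied death times with an interleaved binary covariate.

    The covariate marks the deaths at times 1, 3 and 5, which keeps the
    partial likelihood strictly concave with a finite maximiser (a
    covariate marking only the earliest deaths would be completely
    separated and push beta to infinity).
    """
    surv = pd.DataFrame(
        {
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 1, 1, 1, 1],
            "age": [60.0] * 6,
            "stage": [2] * 6,
        },
        index=pd.Index([f"s{i}" for i in range(6)], name="subject_id"),
    )
    expr = pd.DataFrame(
        {f"s{i}": [1.0 if i % 2 == 0 else 0.0] for i in range(6)},
        index=pd.Index(["gX"], name="gene_id"),
    )
    tissue = pd.Series("tumor", index=expr.columns)
    return SurvivalCohort(survival=surv, expression=expr, tissue=tissue)
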