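"""Readers, writers and containers for the tables the pipeline touches.

The central container is :class:`NpxMatrix`, a protein x sample matrix of
NPX-scale (log2-like) relative abundances with per-sample patient and
time-point annotations and per-patient response-group labels.  Survival
cohorts (expression + time/event/covariates + tumor/normal tissue labels)
live in :class:`SurvivalCohort`.  Cell-infiltration fraction tables are
plain cell-type x subject DataFrames.

All file formats are comma-separated UTF-8 CSV with a header row.  Readers
validate rather than coerce: malformed tables raise with the offending
row/column named.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised time-point labels. LT ("last time of sampling") is a derived
#: role assigned by :func:`assign_lt`, but may also appear directly in files
#: (e.g. simulated cohorts with no dropout).
TIMEPOINTS = ("D0", "D5", "DT", "PD", "LT")

GROUPS = ("GoR", "PoR", "unknown")


class TableFormatError(ValueError):
    """A table failed validation; the message names the offending entry."""


@dataclass
class NpxMatrix:
    """Protein x sample NPX matrix with sample and patient annotations.

    Parameters
    ----------
    values
        DataFrame indexed by protein_id with one column per sample_id.
        Missing measurements are NaN.
    sample_meta
        DataFrame indexed by sample_id with columns ``patient_id``,
        ``timepoint`` (one of D0/D5/DT/PD/LT), ``collection_order`` (int,
        chronological within patient) and, after :func:`assign_lt`, a
        boolean ``is_lt`` column marking each patient's last-time sample.
    patient_meta
        DataFrame indexed by patient_id with a ``group`` column
        (GoR / PoR / unknown).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    patient_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableFormatError(f"duplicate protein_id {dup!r}")
        if self.sample_meta.index.duplicated().any():
            dup = self.sample_meta.index[self.sample_meta.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample_id {dup!r}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise TableFormatError(f"samples without metadata: {sorted(missing)[:5]}")
        bad_tp = set(self.sample_meta["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise TableFormatError(
                f"unknown time-point label(s) {sorted(bad_tp)}; expected one of {TIMEPOINTS}"
            )
        # at most one sample per (patient, timepoint)
        pt = self.sample_meta[["patient_id", "timepoint"]]
        dup_mask = pt.duplicated()
        if dup_mask.any():
            row = pt[dup_mask].iloc[0]
            raise TableFormatError(
                f"patient {row['patient_id']!r} has more than one {row['timepoint']} sample"
            )

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> pd.Index:
        return self.patient_meta.index

    def samples_at(self, timepoint: str) -> pd.Index:
        """Sample IDs carrying the given time-point role.

        ``LT`` matches both samples labeled LT outright and samples tagged
        with the derived LT role by :func:`assign_lt` (a sample may carry
        both its original label and the LT role).
        """
        meta = self.sample_meta
        mask = meta["timepoint"] == timepoint
        if timepoint == "LT" and "is_lt" in meta.columns:
            mask = mask | meta["is_lt"].fillna(False).astype(bool)
        return meta.index[mask]

    def values_at(self, timepoint: str) -> pd.DataFrame:
        """Protein x sample sub-matrix for one time-point role, with columns
        relabeled by patient ID (patients are the replication unit)."""
        samples = self.samples_at(timepoint)
        sub = self.values[samples]
        sub.columns = self.sample_meta.loc[samples, "patient_id"].to_numpy()
        return sub

    def timepoints_present(self) -> list[str]:
        """Time-point roles present, in canonical order."""
        present = set(self.sample_meta["timepoint"])
        if "is_lt" in self.sample_meta.columns and self.sample_meta["is_lt"].any():
            present.add("LT")
        return [t for t in TIMEPOINTS if t in present]


def read_npx_long(path: str | Path) -> NpxMatrix:
    """Read a long-format NPX CSV into an :class:`NpxMatrix`.

    Expected columns: ``sample_id, patient_id, timepoint, protein_id, npx``
    and optionally ``collection_order`` and ``group``.  Duplicate
    (sample, protein) rows are rejected; missing cells stay missing.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise TableFormatError(f"{path}: empty NPX table")
    required = {"sample_id", "patient_id", "timepoint", "protein_id", "npx"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df.duplicated(subset=["sample_id", "protein_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise TableFormatError(
            f"{path}: duplicated measurement for sample "
            f"{row['sample_id']!r}, protein {row['protein_id']!r}"
        )
    values = df.pivot(index="protein_id", columns="sample_id", values="npx")
    meta_cols = ["patient_id", "timepoint"]
    if "collection_order" in df.columns:
        meta_cols.append("collection_order")
    sample_meta = df.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
    if "collection_order" not in sample_meta.columns:
        order = {t: i for i, t in enumerate(TIMEPOINTS)}
        sample_meta["collection_order"] = sample_meta["timepoint"].map(order)
    if "group" in df.columns:
        patient_meta = (
            df.drop_duplicates("patient_id").set_index("patient_id")[["group"]]
        )
    else:
        patient_meta = pd.DataFrame(
            {"group": "unknown"}, index=pd.Index(sample_meta["patient_id"].unique(), name="patient_id")
        )
    values = values[sample_meta.index]
    m = NpxMatrix(values=values, sample_meta=sample_meta, patient_meta=patient_meta)
    logger.info(
        "read_npx_long: %d proteins x %d samples from %s", *values.shape, path
    )
    return m


def write_npx_long(m: NpxMatrix, path: str | Path) -> None:
    """Write an :class:`NpxMatrix` back to long-format CSV (round-trips
    through :func:`read_npx_long`)."""
    long = (
        m.values.reset_index()
        .melt(id_vars="protein_id", var_name="sample_id", value_name="npx")
        .dropna(subset=["npx"])
    )
    long = long.merge(
        m.sample_meta[["patient_id", "timepoint", "collection_order"]],
        left_on="sample_id",
        right_index=True,
    )
    long = long.merge(m.patient_meta["group"], left_on="patient_id", right_index=True)
    cols = ["sample_id", "patient_id", "timepoint", "collection_order", "group", "protein_id", "npx"]
    long[cols].to_csv(path, index=False)


def assign_lt(m: NpxMatrix) -> NpxMatrix:
    """Tag each patient's last-time sample with the LT role.

    For each patient the PD (progression) sample, if present, otherwise the
    chronologically last sample by ``collection_order``, receives the LT
    role.  The sample keeps its original time-point label; the role is an
    additional boolean ``is_lt`` column, so both baseline-vs-last contrasts
    and full four-point trajectories remain constructible.
    """
    meta = m.sample_meta.copy()
    meta["is_lt"] = False
    for patient, grp in meta.groupby("patient_id"):
        if grp.empty:
            raise TableFormatError(f"patient {patient!r} has zero samples")
        pd_samples = grp.index[grp["timepoint"] == "PD"]
        if len(pd_samples):
            lt_sample = pd_samples[0]
        else:
            lt_sample = grp["collection_order"].idxmax()
        meta.loc[lt_sample, "is_lt"] = True
    return NpxMatrix(values=m.values, sample_meta=meta, patient_meta=m.patient_meta)


def adjust_batches(
    expr: pd.DataFrame,
    batches: Mapping[str, str] | pd.Series,
    reference_batch: str,
) -> pd.DataFrame:
    """Reference-anchored location-scale batch adjustment.

    Per gene, each non-reference batch is standardised (subtract its own
    batch mean, divide by its own batch SD) and mapped onto the reference
    batch's mean and SD; the reference batch passes through unchanged.  A
    gene with zero variance inside a non-reference batch falls back to a
    mean shift only (with a warning).  The operation is idempotent.

    Parameters
    ----------
    expr
        gene x sample expression matrix covering all batches.
    batches
        sample -> batch label.
    reference_batch
        The batch whose per-gene moments anchor the others.
    """
    batches = pd.Series(batches)
    batches = batches.loc[expr.columns]
    labels = batches.unique()
    if len(labels) < 2:
        raise ValueError("adjust_batches needs at least two batches")
    if reference_batch not in labels:
        raise ValueError(f"reference batch {reference_batch!r} not among {list(labels)}")
    ref_cols = batches.index[batches == reference_batch]
    ref = expr[ref_cols]
    ref_mean = ref.mean(axis=1)
    ref_sd = ref.std(axis=1, ddof=1)
    if (ref_sd == 0).any():
        bad = ref_sd.index[ref_sd == 0][0]
        raise ValueError(f"gene {bad!r} has zero variance in the reference batch")
    out = expr.copy()
    for label in labels:
        if label == reference_batch:
            continue
        cols = batches.index[batches == label]
        block = expr[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "adjust_batches: %d gene(s) with zero variance in batch %r; "
                "mean-shift only for those",
                int(zero.sum()),
                label,
            )
        scale = ref_sd / sd.where(~zero, other=np.inf)
        scale = scale.where(~zero, other=1.0)  # mean-shift fallback
        out[cols] = block.sub(mean, axis=0).mul(scale, axis=0).add(ref_mean, axis=0)
    return out


@dataclass
class SurvivalCohort:
    """Survival cohort: expression, outcomes, covariates, tissue labels.

    ``survival`` is indexed by subject with columns ``time`` (> 0, in
    ``time_unit``), ``event`` (1 death observed / 0 censored) and any
    covariates (``age`` in years, ``stage`` ordinal 1-4).  ``expression``
    is gene x subject and must cover every subject with a survival row;
    ``tissue`` maps each expression column to ``tumor`` or ``normal`` (the
    normal samples exist for differential-expression testing only and
    carry no survival row).
    """

    survival: pd.DataFrame
    expression: pd.DataFrame
    tissue: pd.Series
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if (self.survival["time"] <= 0).any():
            bad = self.survival.index[self.survival["time"] <= 0][0]
            raise TableFormatError(f"subject {bad!r}: survival time must be > 0")
        if not self.survival["event"].isin([0, 1]).all():
            bad = self.survival.index[~self.survival["event"].isin([0, 1])][0]
            raise TableFormatError(f"subject {bad!r}: event flag must be 0 or 1")
        missing = set(self.survival.index) - set(self.expression.columns)
        if missing:
            raise TableFormatError(
                f"subjects with survival but no expression: {sorted(missing)[:5]}"
            )

    @property
    def tumor_subjects(self) -> pd.Index:
        return self.tissue.index[self.tissue == "tumor"]

    @property
    def normal_subjects(self) -> pd.Index:
        return self.tissue.index[self.tissue == "normal"]


def read_survival(path: str | Path, expression_path: str | Path) -> SurvivalCohort:
    """Read survival/covariate and expression CSVs into a cohort.

    The survival CSV needs columns ``subject_id, time, event`` plus any
    covariates and an optional constant ``time_unit`` metadata column.
    The expression CSV is gene x subject with the gene ID in the first
    column; per-sample tumor/normal labels are carried as a ``__tissue__``
    pseudo-gene row (the first row after the header), which is stripped on
    read.
    """
    surv = pd.read_csv(path)
    required = {"subject_id", "time", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    time_unit = "months"
    if "time_unit" in surv.columns:
        units = surv["time_unit"].unique()
        if len(units) != 1:
            raise TableFormatError(f"{path}: inconsistent time_unit values {units}")
        time_unit = str(units[0])
        surv = surv.drop(columns="time_unit")
    surv = surv.set_index("subject_id")
    expr = pd.read_csv(expression_path, index_col=0)
    if "__tissue__" not in expr.index:
        raise TableFormatError(f"{expression_path}: missing __tissue__ label row")
    tissue = expr.loc["__tissue__"].astype(str)
    expr = expr.drop(index="__tissue__").astype(float)
    return SurvivalCohort(survival=surv, expression=expr, tissue=tissue, time_unit=time_unit)


def write_survival(cohort: SurvivalCohort, path: str | Path, expression_path: str | Path) -> None:
    surv = cohort.survival.reset_index(names="subject_id").copy()
    surv["time_unit"] = cohort.time_unit
    surv.to_csv(path, index=False)
    expr = cohort.expression.copy()
    expr.loc["__tissue__"] = cohort.tissue
    expr = expr.loc[["__tissue__"] + [g for g in expr.index if g != "__tissue__"]]
    expr.to_csv(expression_path)


def read_fractions(path: str | Path, subjects: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a cell-type x subject infiltration-fraction CSV.

    If ``subjects`` is given, the table is intersected with it (with a
    warning when some subjects are absent on either side).
    """
    frac = pd.read_csv(path, index_col=0)
    if not np.isfinite(frac.to_numpy(dtype=float)).all():
        raise TableFormatError(f"{path}: non-finite fraction values")
    if subjects is not None:
        subjects = pd.Index(subjects)
        overlap = frac.columns.intersection(subjects)
        if len(overlap) < len(subjects) or len(overlap) < frac.shape[1]:
            logger.warning(
                "read_fractions: subject mismatch (%d in table, %d requested, "
                "%d overlap); using the intersection",
                frac.shape[1],
                len(subjects),
                len(overlap),
            )
        frac = frac[overlap]
    return frac


def write_report(tables: Mapping[str, pd.DataFrame], outdir: str | Path, precision: int = 9) -> None:
    """Write a dict of DataFrames as CSVs plus a sidecar row-count log.

    Numeric fields are written with enough digits to round-trip
    bit-identically at the declared precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, table in tables.items():
        dest = outdir / f"{name}.csv"
        table.to_csv(dest, float_format=f"%.{precision}g")
        lines.append(f"{name}: {len(table)} rows x {table.shape[1]} cols")
    (outdir / "report.log").write_text("\n".join(lines) + "\n")
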