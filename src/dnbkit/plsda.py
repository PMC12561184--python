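"""Two-class PLS-DA with VIP scoring for response-discriminant protein selection.

Partial least squares discriminant analysis projects the autoscaled
protein matrix onto a few latent components chosen to covary maximally
with the binary class label (good vs poor responder).  Each protein's
contribution is summarised by its variable importance in projection,

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ),

where w_a are the unit-norm component weight vectors and SS_a the class
variance explained by component a.  The identity sum_j VIP_j^2 = p holds
exactly, so VIP >= 1 marks proteins contributing more than average; that
threshold defines the selection.

The fit is the classical NIPALS PLS1 sequence (for a single binary
response the inner NIPALS loop converges in one step, so the fit is exact
and deterministic): w_a = X'y / |X'y|, t_a = X w_a, deflation of X and y
by the component's regression loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NpxMatrix

logger = logging.getLogger(__name__)


@dataclass
class PlsModel:
    """Fitted PLS-DA model.

    Attributes
    ----------
    weights : DataFrame, protein x component
        Unit-norm NIPALS weight vectors w_a.
    scores : DataFrame, sample x component
        Latent sample scores t_a.
    explained_y_ss : ndarray, per component
        Class-response sum of squares explained by each component.
    vip : Series, per protein
        Variable importance in projection.
    """

    weights: pd.DataFrame
    scores: pd.DataFrame
    explained_y_ss: np.ndarray
    vip: pd.Series
    n_components: int

    @property
    def protein_ids(self) -> pd.Index:
        return self.weights.index


def _autoscale(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center and unit-variance scale; returns (scaled, keep mask)."""
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    xs = (x[:, keep] - mean[keep]) / sd[keep]
    return xs, keep


def fit_plsda(
    x: pd.DataFrame,
    y,
    n_components: int = 2,
) -> PlsModel:
    """Fit a two-class PLS-DA model on a protein x sample matrix.

    Missing cells are mean-imputed per protein (PLS needs complete
    columns; the imputation count is logged), proteins are autoscaled
    (centered, unit variance) across samples, and the binary label is
    coded 0/1 and centered.  Zero-variance proteins are dropped before
    the fit and assigned VIP 0.

    Parameters
    ----------
    x : protein x sample DataFrame.
    y : per-sample binary labels (two distinct values, >= 2 samples each).
    n_components : number of latent components A.
    """
    y = pd.Series(np.asarray(y), index=x.columns)
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {list(classes)}")
    counts = y.value_counts()
    if counts.min() < 2:
        raise ValueError("each class needs at least two samples")

    xm = x.to_numpy(dtype=float).T  # samples x proteins
    n_missing = int(np.isnan(xm).sum())
    if n_missing:
        col_mean = np.nanmean(xm, axis=0)
        idx = np.where(np.isnan(xm))
        xm[idx] = np.take(col_mean, idx[1])
        logger.info("fit_plsda: mean-imputed %d missing cell(s)", n_missing)

    xs, keep = _autoscale(xm)
    p_kept = xs.shape[1]
    if p_kept == 0:
        raise ValueError("no proteins left after zero-variance filtering")
    a_max = min(n_components, xs.shape[0] - 1, p_kept)

    yv = (y == classes[1]).to_numpy(dtype=float)
    yv = yv - yv.mean()

    n, p = xs.shape
    W = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    ss = np.zeros(a_max)
    Xd, yd = xs.copy(), yv.copy()
    for a in range(a_max):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            a_max = a
            W, T, ss = W[:, :a], T[:, :a], ss[:a]
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q = yd @ t / tt
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q * t
        W[:, a], T[:, a] = w, t
        ss[a] = q**2 * tt  # y sum of squares explained by component a

    # VIP over the kept proteins; dropped (constant) proteins get VIP 0
    total = ss.sum()
    if total <= 0:
        vip_kept = np.zeros(p)
    else:
        vip_kept = np.sqrt(p_kept * (W**2 @ ss) / total)
    vip = pd.Series(0.0, index=x.index, name="vip")
    vip.iloc[np.flatnonzero(keep)] = vip_kept

    weights = pd.DataFrame(0.0, index=x.index, columns=[f"c{a+1}" for a in range(a_max)])
    weights.iloc[np.flatnonzero(keep), :] = W
    scores = pd.DataFrame(T, index=x.columns, columns=weights.columns)
    return PlsModel(
        weights=weights, scores=scores, explained_y_ss=ss, vip=vip, n_components=a_max
    )


def select_vip(model: PlsModel, threshold: float = 1.0) -> pd.Series:
    """Proteins with VIP >= threshold (inclusive), with their VIP values.

    Returns a Series (protein -> VIP) sorted by decreasing VIP; the index
    is the selected protein ID set.
    """
    if model.vip.empty:
        raise ValueError("empty model")
    sel = model.vip[model.vip >= threshold]
    return sel.sort_values(ascending=False)


def run_group_contrasts(
    m: NpxMatrix,
    n_components: int = 2,
    threshold: float = 1.0,
) -> dict:
    """Run the two response-group PLS-DA contrasts: baseline-only and all samples.

    Uses samples whose patient carries a GoR/PoR label.  Returns a dict
    with keys ``"D0"`` and ``"all"``, each holding ``model`` (PlsModel)
    and ``selection`` (VIP-selected protein Series).
    """
    groups = m.sample_meta["patient_id"].map(m.patient_meta["group"])
    labeled = groups.isin(["GoR", "PoR"])
    out = {}
    for name, mask in {
        "D0": labeled & (m.sample_meta["timepoint"] == "D0"),
        "all": labeled,
    }.items():
        samples = m.sample_meta.index[mask]
        y = groups.loc[samples]
        if y.value_counts().min() < 2:
            raise ValueError(f"contrast {name!r}: a class has fewer than 2 samples")
        model = fit_plsda(m.values[samples], y, n_components=n_components)
        out[name] = {"model": model, "selection": select_vip(model, threshold)}
        logger.info(
            "run_group_contrasts[%s]: %d samples, %d proteins selected (VIP >= %g)",
            name, len(samples), len(out[name]["selection"]), threshold,
        )
    return out
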