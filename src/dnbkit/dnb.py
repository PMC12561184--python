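"""Dynamic network biomarker (DNB) detection from longitudinal NPX trajectories.

A DNB is a group of molecules that behaves as an early-warning signal of a
critical transition: as the system approaches the tipping point their
cross-subject variance inflates, their mutual correlation tightens, and
their correlation with the rest of the network weakens.  Detection here
follows a four-step procedure with the baseline (D0) time point as
reference:

1. **SD filter** — keep proteins whose cross-patient standard deviation at
   post-baseline time points is at least ``fold`` (default 2) times their
   baseline SD.
2. **Profile normalisation** — z-score each candidate's per-time-point
   mean profile across time points.
3. **Fuzzy c-means clustering** of the normalised profiles into candidate
   modules.
4. **Index-based selection** — for each module compute the four DNB
   indices (SDavg, PPCi, PPCo, and the criticality index
   CI = SDavg * PPCi / PPCo) and pick the module that satisfies the DNB
   criteria with the highest CI.

The DNB panel is the intersection of the winning module with the PLS-DA
selection.

Notes on conventions (all configurable): the SD filter is conjunctive
(every post-baseline time point must pass) with a disjunctive mode behind
a flag; correlations are mean absolute Pearson values computed per time
point across patients and averaged over post-baseline time points;
"significantly changed / decreased" criteria use a seeded within-time-point
permutation test; PPCo is floored at ``eps`` in the CI ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NpxMatrix

logger = logging.getLogger(__name__)

POST_BASELINE = ("D5", "DT", "LT")


@dataclass
class SdProfile:
    """Per-protein cross-patient SDs per time point, with post/baseline ratios."""

    sd: pd.DataFrame        # protein x timepoint
    ratio: pd.DataFrame     # protein x post-baseline timepoint, SD_t / SD_D0
    dropped: list = field(default_factory=list)  # (protein, reason)


@dataclass
class DnbReport:
    """Four DNB indices and criteria flags for one candidate cluster."""

    cluster_id: str
    members: list
    sd_avg: float
    sd_ratio_avg: float
    ppc_in: float
    ppc_out: float
    ppc_in_ref: float
    ppc_out_ref: float
    ci: float
    fluctuation: bool
    ppci_changed: bool
    ppco_decreased: bool
    p_ppci: float
    p_ppco: float
    low_n_flags: list = field(default_factory=list)

    @property
    def passes_criteria(self) -> tuple[bool, bool, bool]:
        return (self.fluctuation, self.ppci_changed, self.ppco_decreased)

    @property
    def passes_all(self) -> bool:
        return all(self.passes_criteria)


@dataclass
class DnbPanel:
    """Proteins in the overlap of the winning DNB cluster and the PLS-DA selection."""

    proteins: list
    dnb_cluster: str
    contrast: str


def _post_timepoints(m: NpxMatrix) -> list[str]:
    present = m.timepoints_present()
    return [t for t in POST_BASELINE if t in present]


def sd_filter(
    m: NpxMatrix,
    fold: float = 2.0,
    mode: str = "conjunctive",
    min_patients: int = 3,
) -> tuple[list, SdProfile]:
    """Select proteins whose post-baseline SD exceeds ``fold`` x baseline SD.

    In the default conjunctive mode every post-baseline time point must
    pass; in disjunctive mode one suffices.  A protein with baseline SD 0
    passes a time point iff its SD there is positive (the ratio's limit);
    proteins with fewer than ``min_patients`` observations at any time
    point are dropped from candidacy (logged).
    """
    if mode not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown mode {mode!r}")
    post = _post_timepoints(m)
    if not post:
        raise ValueError("no post-baseline time points present")
    tps = ["D0"] + post
    sds, counts = {}, {}
    for tp in tps:
        vals = m.values_at(tp)
        sds[tp] = vals.std(axis=1, ddof=1)
        counts[tp] = vals.notna().sum(axis=1)
    sd = pd.DataFrame(sds)
    nobs = pd.DataFrame(counts)

    dropped = []
    enough = (nobs >= min_patients).all(axis=1)
    for prot in sd.index[~enough]:
        dropped.append((prot, "fewer than %d observations at some time point" % min_patients))
    if dropped:
        logger.info("sd_filter: dropped %d protein(s) for low n", len(dropped))

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sd[post].div(sd["D0"], axis=0)
    # SD_D0 == 0: pass iff SD_t > 0 (ratio -> +inf); both zero fails
    zero_base = sd["D0"] == 0
    for tp in post:
        ratio.loc[zero_base, tp] = np.where(sd.loc[zero_base, tp] > 0, np.inf, np.nan)

    passes_tp = ratio >= fold
    if mode == "conjunctive":
        passes = passes_tp.all(axis=1)
    else:
        passes = passes_tp.any(axis=1)
    passes &= enough
    candidates = list(sd.index[passes])
    logger.info(
        "sd_filter(fold=%g, %s): %d of %d proteins pass", fold, mode,
        len(candidates), len(sd),
    )
    return candidates, SdProfile(sd=sd, ratio=ratio, dropped=dropped)


def normalize_trajectories(candidates, m: NpxMatrix) -> pd.DataFrame:
    """Z-score each candidate's per-time-point mean profile across time points.

    Returns candidate x time-point DataFrame of standardized profiles
    (row mean 0, row SD 1).  Constant profiles are dropped with a log
    message.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate proteins")
    tps = ["D0"] + _post_timepoints(m)
    prof = pd.DataFrame(
        {tp: m.values_at(tp).loc[candidates].mean(axis=1) for tp in tps}
    )
    sd = prof.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info(
            "normalize_trajectories: dropped %d constant profile(s)", int(constant.sum())
        )
    prof = prof[~constant]
    sd = sd[~constant]
    return prof.sub(prof.mean(axis=1), axis=0).div(sd, axis=0)


def _fuzzy_cmeans(
    data: np.ndarray,
    c: int,
    m_fuzz: float = 1.25,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means on row vectors; returns (membership n x c, centroids c x d).

    Standard Bezdek alternating optimisation: memberships
    u_ik = 1 / sum_l (d_ik / d_il)^(2/(m-1)), centroids as u^m-weighted
    means.  Initialised from c distinct rows chosen by the seeded RNG.
    """
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    centroids = data[rng.choice(n, size=c, replace=False)].astype(float)
    expo = 2.0 / (m_fuzz - 1.0)
    u = np.full((n, c), 1.0 / c)
    for _ in range(max_iter):
        d2 = ((data[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-expo / 2.0)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        um = u_new**m_fuzz
        centroids = (um.T @ data) / um.sum(axis=0)[:, None]
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return u, centroids


@dataclass
class ClusterResult:
    membership: pd.DataFrame   # protein x cluster, rows sum to 1
    assignment: pd.Series      # protein -> cluster label
    centroids: pd.DataFrame    # cluster x timepoint
    c: int


def cluster_candidates(
    profiles: pd.DataFrame,
    c: int | None = None,
    m_fuzz: float = 1.25,
    seed: int = 0,
    c_range: tuple[int, int] = (2, 8),
    merge_threshold: float | None = None,
) -> ClusterResult:
    """Fuzzy c-means clustering of normalised time profiles.

    If ``c`` is None, candidate counts from ``c_range`` (capped at
    n_candidates - 1) are scanned and the count maximising the minimum
    pairwise centroid distance (Dmin) is chosen.  Optionally, clusters
    whose centroid profiles correlate at least ``merge_threshold`` are
    merged afterwards (their membership columns summed); the pipeline's
    default merge step instead operates on patient-level correlations
    (see :func:`merge_correlated_clusters`), which is far better powered
    than correlating two short centroid profiles.
    """
    data = profiles.to_numpy(dtype=float)
    n = data.shape[0]
    if n < 3:
        # too few candidates to partition: one cluster containing all
        logger.warning("cluster_candidates: %d candidate(s) only; single cluster", n)
        membership = pd.DataFrame({"cl1": np.ones(n)}, index=profiles.index)
        assignment = pd.Series("cl1", index=profiles.index)
        centroids = pd.DataFrame([data.mean(axis=0)], index=["cl1"], columns=profiles.columns)
        return ClusterResult(membership, assignment, centroids, 1)

    if c is not None and not (2 <= c < n):
        raise ValueError(f"c={c} out of range [2, {n - 1}]")
    if c is None:
        best_c, best_dmin = None, -np.inf
        for cc in range(max(2, c_range[0]), min(c_range[1], n - 1) + 1):
            _, cent = _fuzzy_cmeans(data, cc, m_fuzz=m_fuzz, seed=seed)
            dist = np.sqrt(((cent[:, None] - cent[None, :]) ** 2).sum(axis=2))
            dmin = dist[np.triu_indices(cc, k=1)].min()
            if dmin > best_dmin:
                best_c, best_dmin = cc, dmin
        c = best_c
    u, cent = _fuzzy_cmeans(data, c, m_fuzz=m_fuzz, seed=seed)

    # merge near-duplicate centroids (transitive closure on profile correlation)
    groups = list(range(c))
    if c > 1 and merge_threshold is not None:
        cent_sd = cent.std(axis=1, ddof=1)
        parent = list(range(c))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(c):
            for j in range(i + 1, c):
                if cent_sd[i] > 0 and cent_sd[j] > 0:
                    r = np.corrcoef(cent[i], cent[j])[0, 1]
                    if r >= merge_threshold:
                        parent[find(j)] = find(i)
        groups = [find(i) for i in range(c)]

    labels_map = {}
    for g in sorted(set(groups)):
        labels_map[g] = f"cl{len(labels_map) + 1}"
    cols = sorted(set(groups))
    merged_u = np.column_stack([u[:, [i for i in range(c) if groups[i] == g]].sum(axis=1) for g in cols])
    membership = pd.DataFrame(
        merged_u, index=profiles.index, columns=[labels_map[g] for g in cols]
    )
    assignment = membership.idxmax(axis=1)
    um = u**m_fuzz
    merged_cent = []
    for g in cols:
        idx = [i for i in range(c) if groups[i] == g]
        w = um[:, idx].sum(axis=1)
        merged_cent.append((w @ data) / w.sum())
    centroids = pd.DataFrame(
        merged_cent, index=[labels_map[g] for g in cols], columns=profiles.columns
    )
    if len(cols) < c:
        logger.info(
            "cluster_candidates: merged %d fuzzy clusters into %d (centroid r >= %g)",
            c, len(cols), merge_threshold,
        )
    return ClusterResult(membership, assignment, centroids, len(cols))


def merge_correlated_clusters(
    clusters: ClusterResult,
    m: NpxMatrix,
    r_threshold: float = 0.5,
) -> ClusterResult:
    """Merge clusters that are facets of one correlated protein module.

    The fuzzy partition always yields at least two clusters, even when
    the SD-filter survivors form a single tight module, so a merge
    decision is needed.  Rather than comparing two short centroid
    profiles (whose Pearson correlation on a handful of time points is
    nearly uniform under the null), this uses the patient-level signal
    the profiles discard: for each cluster, member values are z-scored
    per post-baseline time point across patients and averaged into one
    module trajectory per patient; two clusters are merged (transitively)
    when these module averages have absolute Pearson correlation at
    least ``r_threshold`` over the pooled patient x time-point
    observations.  For a split of an exchangeable rho = 0.7 module the
    expected correlation is ~0.9; for independent modules it is ~0 with
    a standard error of about 1/sqrt(n_patients x n_timepoints).
    """
    labels = list(clusters.membership.columns)
    if len(labels) < 2:
        return clusters
    post = _post_timepoints(m)
    averages = {}
    for cid in labels:
        members = list(clusters.assignment.index[clusters.assignment == cid])
        chunks = []
        for tp in post:
            vals = m.values_at(tp).loc[members].T  # patients x members
            z = _standardize_cols(vals)
            if z is not None:
                chunks.append(np.nanmean(z, axis=1))
        averages[cid] = np.concatenate(chunks) if chunks else np.array([])

    parent = {cid: cid for cid in labels}

    def find(cid):
        while parent[cid] != cid:
            parent[cid] = parent[parent[cid]]
            cid = parent[cid]
        return cid

    for i, ci in enumerate(labels):
        for cj in labels[i + 1 :]:
            a, b = averages[ci], averages[cj]
            n = min(len(a), len(b))
            if n < 3:
                continue
            r = np.corrcoef(a[:n], b[:n])[0, 1]
            if abs(r) >= r_threshold:
                parent[find(cj)] = find(ci)

    groups = {}
    for cid in labels:
        groups.setdefault(find(cid), []).append(cid)
    if len(groups) == len(labels):
        return clusters
    logger.info(
        "merge_correlated_clusters: %d clusters -> %d (|r| >= %g on patient-level averages)",
        len(labels), len(groups), r_threshold,
    )
    new_membership = pd.DataFrame(index=clusters.membership.index)
    new_centroids = []
    new_labels = []
    for k, (root, members) in enumerate(sorted(groups.items()), start=1):
        label = f"cl{k}"
        new_labels.append(label)
        new_membership[label] = clusters.membership[members].sum(axis=1)
        sizes = np.array([
            (clusters.assignment == cid).sum() for cid in members
        ], dtype=float)
        cent = (
            clusters.centroids.loc[members].to_numpy() * sizes[:, None]
        ).sum(axis=0) / max(sizes.sum(), 1.0)
        new_centroids.append(cent)
    assignment = new_membership.idxmax(axis=1)
    centroids = pd.DataFrame(
        new_centroids, index=new_labels, columns=clusters.centroids.columns
    )
    return ClusterResult(new_membership, assignment, centroids, len(new_labels))


def _mean_abs_corr_blocks(
    z_members: np.ndarray, z_others: np.ndarray | None
) -> tuple[float, float]:
    """Mean |Pearson r| among member columns, and members vs other columns.

    Inputs are column-standardised observation matrices (rows = patients).
    Returns (ppc_in, ppc_out); NaN where undefined.
    """
    n = z_members.shape[0]
    k = z_members.shape[1]
    ppc_in = np.nan
    if k >= 2:
        r = z_members.T @ z_members / (n - 1)
        iu = np.triu_indices(k, 1)
        ppc_in = float(np.nanmean(np.abs(r[iu])))
    ppc_out = np.nan
    if z_others is not None and z_others.shape[1] >= 1:
        r = z_members.T @ z_others / (n - 1)
        ppc_out = float(np.nanmean(np.abs(r)))
    return ppc_in, ppc_out


def _standardize_cols(x: pd.DataFrame) -> np.ndarray | None:
    """Drop rows with missing values, column-standardise; None if < 3 rows."""
    arr = x.to_numpy(dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 3:
        return None
    sd = arr.std(axis=0, ddof=1)
    sd[sd == 0] = np.nan
    return (arr - arr.mean(axis=0)) / sd


def dnb_indices(
    members,
    m: NpxMatrix,
    reference: str = "D0",
    cluster_id: str = "cl1",
    fold: float = 2.0,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    eps: float = 1e-6,
    seed: int = 0,
) -> DnbReport:
    """Compute the four DNB indices and criteria flags for one cluster.

    SDavg is the mean member SD over post-baseline time points; PPCi /
    PPCo are mean absolute Pearson correlations (within members / members
    vs non-members) computed per time point across patients on
    pairwise-complete patient-matched values, averaged over post-baseline
    time points; CI = SDavg * PPCi / max(PPCo, eps).

    Criteria against the baseline reference: (1) fluctuation — mean SD
    ratio >= ``fold``; (2) PPCi changed significantly; (3) PPCo decreased
    significantly.  Significance is a seeded permutation test
    (``n_permutations`` draws) that independently permutes each member
    protein's patient order within every post-baseline time point,
    destroying cross-protein correlation while keeping margins; the
    observed |PPCi - PPCi_ref| (resp. PPCo_ref - PPCo) must exceed the
    1 - alpha quantile of the permuted statistic.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("singleton cluster: DNB indices need >= 2 members")
    others = [p for p in m.protein_ids if p not in set(members)]
    if not others:
        raise ValueError("cluster equals the complete protein set: PPCo undefined")
    post = _post_timepoints(m)
    if not post:
        raise ValueError("no post-baseline time points present")
    rng = np.random.default_rng(seed)

    low_n_flags = []

    def tp_corrs(tp: str) -> tuple[float, float, np.ndarray | None, np.ndarray | None]:
        vals = m.values_at(tp).T  # patients x proteins
        zm = _standardize_cols(vals[members])
        zo = _standardize_cols(vals[others]) if others else None
        if zm is None:
            low_n_flags.append((tp, "fewer than 3 patient-matched observations"))
            return np.nan, np.nan, None, None
        if zo is not None and zo.shape[0] != zm.shape[0]:
            # pairwise-complete across blocks: recompute on common rows
            both = vals[members + others].dropna()
            if len(both) < 3:
                low_n_flags.append((tp, "fewer than 3 complete member/non-member rows"))
                zo = None
            else:
                zm2 = _standardize_cols(both[members])
                zo = _standardize_cols(both[others])
                ppc_i, _ = _mean_abs_corr_blocks(zm, None)
                _, ppc_o = _mean_abs_corr_blocks(zm2, zo)
                return ppc_i, ppc_o, zm, zo
        ppc_i, ppc_o = _mean_abs_corr_blocks(zm, zo)
        return ppc_i, ppc_o, zm, zo

    # post-baseline indices (averaged over time points)
    ppc_in_list, ppc_out_list, blocks = [], [], []
    for tp in post:
        ppc_i, ppc_o, zm, zo = tp_corrs(tp)
        if not np.isnan(ppc_i):
            ppc_in_list.append(ppc_i)
        if not np.isnan(ppc_o):
            ppc_out_list.append(ppc_o)
        if zm is not None:
            blocks.append((zm, zo))
    ppc_in = float(np.mean(ppc_in_list)) if ppc_in_list else np.nan
    ppc_out = float(np.mean(ppc_out_list)) if ppc_out_list else np.nan

    ref_i, ref_o, _, _ = tp_corrs(reference)

    # SD indices
    sd_tp = {tp: m.values_at(tp).loc[members].std(axis=1, ddof=1) for tp in [reference] + post}
    sd_avg = float(np.mean([sd_tp[tp].mean() for tp in post]))
    base = sd_tp[reference]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = [
            np.where(base > 0, sd_tp[tp] / base, np.where(sd_tp[tp] > 0, np.inf, np.nan))
            for tp in post
        ]
    sd_ratio_avg = float(np.nanmean([np.nanmean(r) for r in ratios]))

    # permutation null: shuffle each member column independently per time point
    obs_di = abs(ppc_in - ref_i)
    obs_do = ref_o - ppc_out
    null_di = np.empty(n_permutations)
    null_do = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_in, perm_out = [], []
        for zm, zo in blocks:
            zp = np.empty_like(zm)
            for j in range(zm.shape[1]):
                zp[:, j] = zm[rng.permutation(zm.shape[0]), j]
            pi, po = _mean_abs_corr_blocks(zp, zo)
            if not np.isnan(pi):
                perm_in.append(pi)
            if not np.isnan(po):
                perm_out.append(po)
        pin = np.mean(perm_in) if perm_in else np.nan
        pout = np.mean(perm_out) if perm_out else np.nan
        null_di[b] = abs(pin - ref_i)
        null_do[b] = ref_o - pout
    p_ppci = float((1 + np.sum(null_di >= obs_di)) / (1 + n_permutations))
    p_ppco = float((1 + np.sum(null_do >= obs_do)) / (1 + n_permutations))

    fluctuation = bool(sd_ratio_avg >= fold)
    ppci_changed = bool(p_ppci < alpha)
    ppco_decreased = bool((ppc_out < ref_o) and (p_ppco < alpha))

    ci = float(sd_avg * ppc_in / max(ppc_out, eps))
    return DnbReport(
        cluster_id=cluster_id,
        members=members,
        sd_avg=sd_avg,
        sd_ratio_avg=sd_ratio_avg,
        ppc_in=ppc_in,
        ppc_out=ppc_out,
        ppc_in_ref=float(ref_i),
        ppc_out_ref=float(ref_o),
        ci=ci,
        fluctuation=fluctuation,
        ppci_changed=ppci_changed,
        ppco_decreased=ppco_decreased,
        p_ppci=p_ppci,
        p_ppco=p_ppco,
        low_n_flags=low_n_flags,
    )


def select_dnb(reports: list[DnbReport]) -> DnbReport:
    """Pick the winning DNB cluster.

    Among clusters passing all three criteria, the one with maximal CI;
    ties broken by larger membership, then lexicographic cluster ID.  If
    no cluster passes, the max-CI cluster is returned with a prominent
    warning.
    """
    if not reports:
        raise ValueError("empty report list")
    passing = [r for r in reports if r.passes_all]
    pool = passing if passing else reports
    if not passing:
        warnings.warn(
            "select_dnb: no cluster satisfies all DNB criteria; "
            "returning the max-CI cluster anyway",
            stacklevel=2,
        )
    winner = sorted(pool, key=lambda r: (-r.ci, -len(r.members), r.cluster_id))[0]
    logger.info(
        "select_dnb: cluster %s wins (CI=%.3g, %d members, criteria=%s)",
        winner.cluster_id, winner.ci, len(winner.members), winner.passes_criteria,
    )
    return winner


def build_panel(dnb_members, plsda_selection, contrast: str = "all", cluster_id: str = "") -> DnbPanel:
    """Intersect the winning DNB cluster with the PLS-DA selection."""
    dnb_members = list(dnb_members)
    plsda_ids = set(getattr(plsda_selection, "index", plsda_selection))
    if not dnb_members or not plsda_ids:
        raise ValueError("both input sets must be non-empty")
    overlap = [p for p in dnb_members if p in plsda_ids]
    if not overlap:
        warnings.warn("build_panel: empty DNB/PLS-DA overlap", stacklevel=2)
    return DnbPanel(proteins=overlap, dnb_cluster=cluster_id, contrast=contrast)


def detect_dnb(
    m: NpxMatrix,
    fold: float = 2.0,
    mode: str = "conjunctive",
    c: int | None = None,
    m_fuzz: float = 1.25,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    eps: float = 1e-6,
    seed: int = 0,
) -> dict:
    """Run the full four-step DNB identification and return all intermediates.

    Returns a dict with keys ``candidates``, ``sd_profile``, ``profiles``,
    ``clusters``, ``reports`` and ``winner``.
    """
    candidates, prof = sd_filter(m, fold=fold, mode=mode)
    if not candidates:
        raise ValueError("no protein passes the SD filter")
    profiles = normalize_trajectories(candidates, m)
    clusters = cluster_candidates(profiles, c=c, m_fuzz=m_fuzz, seed=seed)
    clusters = merge_correlated_clusters(clusters, m)
    reports = []
    n_total = len(m.protein_ids)
    for cid in clusters.membership.columns:
        members = list(clusters.assignment.index[clusters.assignment == cid])
        if len(members) < 2 or len(members) == n_total:
            continue
        reports.append(
            dnb_indices(
                members, m, cluster_id=cid, fold=fold,
                n_permutations=n_permutations, alpha=alpha, eps=eps, seed=seed,
            )
        )
    if not reports:
        raise ValueError("no cluster with >= 2 members to score")
    winner = select_dnb(reports)
    return {
        "candidates": candidates,
        "sd_profile": prof,
        "profiles": profiles,
        "clusters": clusters,
        "reports": reports,
        "winner": winner,
    }
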