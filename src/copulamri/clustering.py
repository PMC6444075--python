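"""Hierarchical patient clustering, cluster-count vote, and LOOCV consensus.

Patients are clustered by agglomerative hierarchical clustering with complete
linkage on Euclidean distances over z-scored features. The number of clusters
is chosen by majority vote among a battery of classical cluster-validity
indices evaluated over a candidate range (default 2..10): each index votes
for the k it considers optimal under its standard decision rule, and the
modal vote wins, ties broken toward smaller k.

Cluster stability is assessed by leave-one-out cross-validation: the cohort
is re-clustered n times with one patient removed per repetition, and the
consensus matrix M(i,j) records the fraction of repetitions in which patients
i and j landed in the same cluster, among repetitions where both were
present. Co-membership is label-free, so labels are never matched across
repetitions; for i != j both patients are present in exactly n-2 repetitions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

logger = logging.getLogger(__name__)

LINKAGE_METHOD = "complete"


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) for a cohort, with the vote table that chose k."""

    patient_ids: list[str]
    labels: np.ndarray
    k: int
    linkage_method: str = LINKAGE_METHOD
    vote_table: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.patient_ids) != self.labels.size:
            raise ValueError("labels length must equal patient count")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.patient_ids, "subtype": self.labels}
        )


@dataclass
class ConsensusMatrix:
    """Patient x patient co-clustering frequencies from LOOCV repetitions."""

    patient_ids: list[str]
    m: np.ndarray
    co_presence: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        n = len(self.patient_ids)
        if self.m.shape != (n, n):
            raise ValueError("consensus matrix shape mismatch")
        if not np.allclose(self.m, self.m.T):
            raise ValueError("consensus matrix must be symmetric")
        if np.any((self.m < 0) | (self.m > 1)):
            raise ValueError("consensus entries must lie in [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.m, index=self.patient_ids, columns=self.patient_ids)


def standardize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column (ddof=0); zero-variance columns become 0.

    The nine matrix features live on very different scales (entropy near
    log2(bins^2) vs energy near 1/bins^2), and complete linkage on Euclidean
    distance is scale-sensitive, so standardization precedes clustering.
    Idempotent: standardizing twice equals standardizing once.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 patients to standardize")
    mean = table.mean(axis=0)
    std = table.std(axis=0, ddof=0)
    # a column whose spread is at machine precision relative to its location
    # is constant in substance; rescaling it would amplify rounding noise
    zero_var = std <= 1e-10 * np.maximum(1.0, mean.abs())
    if zero_var.any():
        logger.warning(
            "zero-variance feature column(s) set to 0: %s",
            list(table.columns[zero_var]),
        )
    out = (table - mean).div(std.where(~zero_var, 1.0), axis=1)
    out.loc[:, zero_var] = 0.0
    return out


def _linkage_matrix(table: pd.DataFrame, standardize: bool) -> np.ndarray:
    x = standardize_features(table) if standardize else table
    return linkage(x.to_numpy(), method=LINKAGE_METHOD, metric="euclidean")


def hierarchical_cluster(
    table: pd.DataFrame, k: int, standardize: bool = True
) -> ClusterAssignment:
    """Cut the complete-linkage dendrogram of the (standardized) table at k clusters.

    Deterministic given the table; labels are renumbered 1..k in order of
    first appearance so the numbering does not depend on dendrogram internals.
    """
    n = len(table)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} out of range [2, {n - 1}]")
    z = _linkage_matrix(table, standardize)
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(set(raw.tolist())) != k:
        raise ValueError(f"dendrogram cut produced {len(set(raw.tolist()))} != {k} clusters")
    # renumber by first appearance for stable output
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return ClusterAssignment(
        patient_ids=[str(p) for p in table.index], labels=labels, k=k
    )


# ---------------------------------------------------------------------------
# Cluster-validity indices
# ---------------------------------------------------------------------------
# Each index is evaluated on the standardized feature matrix and the labels of
# every candidate k cut from the same dendrogram; its standard "best k" rule
# (maximize, minimize, largest difference between successive hierarchy levels,
# or a critical-value test) selects its vote. The battery follows the classical
# roster of the cluster-validity literature; determinant-based members
# (Scott, Marriott, Rubin, Friedman) are computed on the non-degenerate
# feature columns and abstain when the scatter matrices are singular.

_Z_CRIT = 3.20  # standard score for the Duda-Hart / pseudo-t2 critical values


def _within_between_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    within = same[iu]
    return within, ~within


def _dunn(dmat: np.ndarray, labels: np.ndarray) -> float:
    ks = np.unique(labels)
    diam = max(
        dmat[np.ix_(labels == c, labels == c)].max() for c in ks
    )
    sep = min(
        dmat[np.ix_(labels == a, labels == b)].min()
        for ai, a in enumerate(ks)
        for b in ks[ai + 1:]
    )
    return sep / diam if diam > 0 else np.inf


def _c_index(dcond: np.ndarray, labels: np.ndarray) -> float:
    within, _ = _within_between_masks(labels)
    nw = int(within.sum())
    if nw == 0:
        return np.nan
    s = dcond[within].sum()
    dsorted = np.sort(dcond)
    smin = dsorted[:nw].sum()
    smax = dsorted[-nw:].sum()
    return (s - smin) / (smax - smin) if smax > smin else 0.0


def _mcclain_rao(dcond: np.ndarray, labels: np.ndarray) -> float:
    within, between = _within_between_masks(labels)
    if not within.any() or not between.any():
        return np.nan
    return dcond[within].mean() / dcond[between].mean()


def _point_biserial(dcond: np.ndarray, labels: np.ndarray) -> float:
    within, between = _within_between_masks(labels)
    nw, nb = int(within.sum()), int(between.sum())
    nt = nw + nb
    sd = dcond.std()
    if sd == 0 or nw == 0 or nb == 0:
        return np.nan
    return (dcond[between].mean() - dcond[within].mean()) * np.sqrt(nw * nb / nt**2) / sd


def _wgss(x: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squares about cluster centroids."""
    total = 0.0
    for c in np.unique(labels):
        xc = x[labels == c]
        total += ((xc - xc.mean(axis=0)) ** 2).sum()
    return total


def _ratkowsky_lance(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    tss_j = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
    bgss_j = np.zeros(x.shape[1])
    for c in np.unique(labels):
        xc = x[labels == c]
        bgss_j += len(xc) * (xc.mean(axis=0) - x.mean(axis=0)) ** 2
    ok = tss_j > 0
    if not ok.any():
        return np.nan
    cbar = np.sqrt(bgss_j[ok] / tss_j[ok]).mean()
    return cbar / np.sqrt(k)


def _split_between_levels(
    x: np.ndarray, lab_k: np.ndarray, lab_k1: np.ndarray
) -> tuple[float, float, float, int] | None:
    """Scatter bookkeeping for the cluster that splits between levels k and k+1.

    Hierarchy cuts are nested, so exactly one cluster at level k divides into
    two at level k+1. Returns (W_parent, W_child1, W_child2, n_parent), or
    None if no clean two-way split is found.
    """
    for c in np.unique(lab_k):
        members = lab_k == c
        children = np.unique(lab_k1[members])
        if len(children) == 2:
            xm = x[members]
            w_m = float(((xm - xm.mean(axis=0)) ** 2).sum())
            w_ch = []
            for ch in children:
                xc = x[members & (lab_k1 == ch)]
                w_ch.append(float(((xc - xc.mean(axis=0)) ** 2).sum()))
            return w_m, w_ch[0], w_ch[1], int(members.sum())
    return None


def _duda_family_votes(
    x: np.ndarray, labels_at: dict[int, np.ndarray], k_range: range
) -> dict[str, int | None]:
    """Duda-Hart, pseudo-t2 and Beale stopping rules over the hierarchy.

    Each examines the two clusters produced by the split between successive
    levels and votes the smallest k at which the split is *not* warranted
    (Duda ratio above its critical value; pseudo-t2 below its critical value;
    Beale's F-test non-significant at 0.1).
    """
    p = x.shape[1]
    duda_vote = t2_vote = beale_vote = None
    for k in sorted(k_range):
        if k + 1 not in labels_at:
            continue
        split = _split_between_levels(x, labels_at[k], labels_at[k + 1])
        if split is None:
            continue
        w_m, w_l, w_r, n_m = split
        if w_m <= 0 or n_m <= 2:
            continue
        duda = (w_l + w_r) / w_m
        crit = 1.0 - 2.0 / (np.pi * p) - _Z_CRIT * np.sqrt(
            2.0 * (1.0 - 8.0 / (np.pi**2 * p)) / (n_m * p)
        )
        if duda_vote is None and duda >= crit:
            duda_vote = k
        b_m = w_m - w_l - w_r
        if w_l + w_r > 0:
            t2 = b_m / ((w_l + w_r) / (n_m - 2))
            if t2_vote is None and 0 < crit < 1 and t2 <= ((1 - crit) / crit) * (n_m - 2):
                t2_vote = k
            f_beale = (b_m / (w_l + w_r)) / (
                ((n_m - 1) / (n_m - 2)) * 2.0 ** (2.0 / p) - 1.0
            )
            p_beale = scipy.stats.f.sf(f_beale, p, (n_m - 2) * p) if f_beale > 0 else 1.0
            if beale_vote is None and p_beale >= 0.1:
                beale_vote = k
    return {"duda": duda_vote, "pseudo_t2": t2_vote, "beale": beale_vote}


def _sd_indices(
    x: np.ndarray, labels_at: dict[int, np.ndarray], k_range: range
) -> tuple[dict[int, float], dict[int, float]]:
    """SD validity index and S_Dbw for every candidate k (both minimized).

    SD = alpha * Scat + Dis (alpha = Dis at k_max); S_Dbw = Scat + Dens_bw,
    where Scat is mean within-cluster variance-norm relative to the data,
    Dis a centroid-separation term, and Dens_bw the mean midpoint-to-cluster
    density ratio.
    """
    norm_sx = np.linalg.norm(x.var(axis=0))
    scat: dict[int, float] = {}
    dis: dict[int, float] = {}
    dens: dict[int, float] = {}
    for k in k_range:
        lab = labels_at[k]
        clusters = np.unique(lab)
        cents = np.array([x[lab == c].mean(axis=0) for c in clusters])
        var_norms = [np.linalg.norm(x[lab == c].var(axis=0)) for c in clusters]
        scat[k] = float(np.mean(var_norms)) / norm_sx
        dd = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
        iu = np.triu_indices(len(cents), k=1)
        dmin = dd[iu].min()
        if dmin <= 0:
            scat.pop(k)
            continue
        dis[k] = (dd[iu].max() / dmin) * sum(
            1.0 / dd[i][dd[i] > 0].sum() for i in range(len(cents))
        )
        stdev = float(np.sqrt(np.mean(var_norms)))

        def density(point: np.ndarray) -> int:
            return int(np.sum(np.linalg.norm(x - point, axis=1) <= stdev))

        total = 0.0
        for a in range(len(cents)):
            for b in range(a + 1, len(cents)):
                d_max = max(density(cents[a]), density(cents[b]))
                total += density((cents[a] + cents[b]) / 2) / d_max if d_max else 0.0
        dens[k] = 2.0 * total / (len(cents) * (len(cents) - 1))
    if not scat:
        return {}, {}
    alpha = dis[max(scat)]
    sd = {k: alpha * scat[k] + dis[k] for k in scat}
    sdbw = {k: scat[k] + dens[k] for k in scat}
    return sd, sdbw


def _determinant_votes(
    x: np.ndarray, labels_at: dict[int, np.ndarray], k_range: range
) -> dict[str, int | None]:
    """Scott, Marriott, Rubin and Friedman votes from scatter determinants.

    Computed on the feature columns with nonzero variance, in log-determinant
    form so small determinants do not underflow; all four abstain when a
    scatter matrix is singular. Marriott's and Rubin's second-difference
    rules and Scott's/Friedman's level-difference rules are invariant to a
    common scale factor, which the log-space rescaling exploits.
    """
    keep = x.var(axis=0) > 1e-20
    xd = x[:, keep]
    n, p = xd.shape
    if p == 0 or n <= p:
        return {}
    gm = xd.mean(axis=0)
    t_mat = (xd - gm).T @ (xd - gm)
    sign_t, logdet_t = np.linalg.slogdet(t_mat)
    if sign_t <= 0:
        return {}
    logdet_w: dict[int, float] = {}
    friedman: dict[int, float] = {}
    for k, lab in labels_at.items():
        w = np.zeros((p, p))
        b = np.zeros((p, p))
        for c in np.unique(lab):
            xc = xd[lab == c]
            d = xc - xc.mean(axis=0)
            w += d.T @ d
            diff = xc.mean(axis=0) - gm
            b += len(xc) * np.outer(diff, diff)
        sign_w, ld = np.linalg.slogdet(w)
        if sign_w > 0:
            logdet_w[k] = ld
            friedman[k] = float(np.trace(np.linalg.solve(w, b)))
    votes: dict[str, int | None] = {}
    scott = {k: n * (logdet_t - ld) for k, ld in logdet_w.items()}
    votes["scott"] = _vote_max(
        {k: scott[k] - scott[k - 1] for k in k_range if k in scott and k - 1 in scott}
    )
    ref = max(logdet_w.values(), default=0.0)
    marriott = {k: k**2 * np.exp(ld - ref) for k, ld in logdet_w.items()}
    votes["marriott"] = _vote_max(
        {
            k: marriott[k + 1] + marriott[k - 1] - 2 * marriott[k]
            for k in k_range
            if {k - 1, k, k + 1} <= set(marriott)
        }
    )
    rub_ref = max(logdet_t - ld for ld in logdet_w.values())
    rubin = {k: np.exp(logdet_t - ld - rub_ref) for k, ld in logdet_w.items()}
    votes["rubin"] = _vote_min(
        {
            k: rubin[k + 1] + rubin[k - 1] - 2 * rubin[k]
            for k in k_range
            if {k - 1, k, k + 1} <= set(rubin)
        }
    )
    votes["friedman"] = _vote_max(
        {
            k: friedman[k] - friedman[k - 1]
            for k in k_range
            if k in friedman and k - 1 in friedman
        }
    )
    return votes


def _vote_max(values: dict[int, float]) -> int | None:
    finite = {k: v for k, v in values.items() if np.isfinite(v)}
    if not finite:
        return None
    best = max(finite.values())
    return min(k for k, v in finite.items() if v == best)


def _vote_min(values: dict[int, float]) -> int | None:
    finite = {k: v for k, v in values.items() if np.isfinite(v)}
    if not finite:
        return None
    best = min(finite.values())
    return min(k for k, v in finite.items() if v == best)


def _vote_max_drop(values: dict[int, float], k_range: range) -> int | None:
    # vote the k in range with the largest decrease value(k-1) - value(k)
    drops = {
        k: values[k - 1] - values[k]
        for k in k_range
        if k - 1 in values and np.isfinite(values.get(k, np.nan)) and np.isfinite(values[k - 1])
    }
    return _vote_max(drops)


def select_k(
    table: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    standardize: bool = True,
) -> tuple[int, dict[str, int]]:
    """Choose the cluster count by majority vote among validity indices.

    Evaluates a battery of classical indices — silhouette, Calinski-Harabasz,
    Davies-Bouldin, Dunn, C-index, McClain-Rao, point-biserial,
    Ratkowsky-Lance, Ball-Hall, Hartigan, Krzanowski-Lai, TraceW, Duda-Hart,
    pseudo-t2, Beale, SD, S_Dbw, Scott, Marriott, Rubin, Friedman — on
    complete-linkage cuts for every k in [k_min, k_max]; each votes for its
    optimal k under its standard rule and the modal vote wins, ties broken
    toward smaller k. Indices that are undefined on the data (e.g. the
    determinant-based ones on rank-deficient features, or the stopping rules
    when no level satisfies their criterion) abstain. Returns
    (k_best, vote_table).
    """
    n = len(table)
    if k_max > n - 1:
        raise ValueError(f"k_max={k_max} exceeds patients-1={n - 1}")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    x = (standardize_features(table) if standardize else table).to_numpy()
    z = linkage(x, method=LINKAGE_METHOD, metric="euclidean")
    dcond = pdist(x)
    dmat = squareform(dcond)

    k_range = range(k_min, k_max + 1)
    # W(k) also needed one step outside the range for the drop-rule indices
    wk_range = range(max(1, k_min - 1), min(n - 1, k_max + 1) + 1)
    labels_at: dict[int, np.ndarray] = {}
    for k in sorted(set(k_range) | set(wk_range)):
        if k == 1:
            labels_at[k] = np.ones(n, dtype=int)
        else:
            labels_at[k] = fcluster(z, t=k, criterion="maxclust")

    sil, ch, db, dunn, cidx, mcr, pb, rl = ({} for _ in range(8))
    wk: dict[int, float] = {}
    for k, lab in labels_at.items():
        wk[k] = _wgss(x, lab)
        if k not in k_range or len(set(lab.tolist())) != k:
            continue
        sil[k] = silhouette_score(x, lab, metric="euclidean")
        ch[k] = calinski_harabasz_score(x, lab)
        db[k] = davies_bouldin_score(x, lab)
        dunn[k] = _dunn(dmat, lab)
        cidx[k] = _c_index(dcond, lab)
        mcr[k] = _mcclain_rao(dcond, lab)
        pb[k] = _point_biserial(dcond, lab)
        rl[k] = _ratkowsky_lance(x, lab, k)

    ball = {k: w / k for k, w in wk.items()}
    hartigan = {
        k: (wk[k] / wk[k + 1] - 1.0) * (n - k - 1)
        for k in wk
        if k + 1 in wk and wk[k + 1] > 0
    }
    p_dim = x.shape[1]
    kl = {}
    for k in k_range:
        if k - 1 in wk and k + 1 in wk:
            d1 = (k - 1) ** (2 / p_dim) * wk[k - 1] - k ** (2 / p_dim) * wk[k]
            d2 = k ** (2 / p_dim) * wk[k] - (k + 1) ** (2 / p_dim) * wk[k + 1]
            if d2 != 0:
                kl[k] = abs(d1) / abs(d2)
    tracew_2nd = {
        k: wk[k + 1] + wk[k - 1] - 2 * wk[k]
        for k in k_range
        if k - 1 in wk and k + 1 in wk
    }
    sd_index, sdbw = _sd_indices(x, labels_at, k_range)

    votes: dict[str, int | None] = {
        "silhouette": _vote_max(sil),
        "calinski_harabasz": _vote_max(ch),
        "davies_bouldin": _vote_min(db),
        "dunn": _vote_max(dunn),
        "c_index": _vote_min(cidx),
        "mcclain_rao": _vote_min(mcr),
        "point_biserial": _vote_max(pb),
        "ratkowsky_lance": _vote_max(rl),
        "ball_hall": _vote_max_drop(ball, k_range),
        "hartigan": _vote_max_drop(hartigan, k_range),
        "krzanowski_lai": _vote_max(kl),
        "trace_w": _vote_max(tracew_2nd),
        "sd_index": _vote_min(sd_index),
        "s_dbw": _vote_min(sdbw),
    }
    votes.update(_duda_family_votes(x, labels_at, k_range))
    votes.update(_determinant_votes(x, labels_at, k_range))
    vote_table = {name: k for name, k in votes.items() if k is not None}
    if len(vote_table) < 2:
        raise ValueError("fewer than 2 validity indices were computable")
    counts = Counter(vote_table.values())
    top = max(counts.values())
    k_best = min(k for k, c in counts.items() if c == top)
    logger.info("select_k votes: %s -> k=%d", vote_table, k_best)
    return k_best, vote_table


def loocv_consensus(
    table: pd.DataFrame, k: int, standardize: bool = True
) -> ConsensusMatrix:
    """Leave-one-out consensus: re-cluster n times, each time dropping one patient.

    Features are re-standardized within each fold so the left-out patient
    cannot influence the fold's scaling. M(i,j) = (repetitions with i, j
    co-clustered) / (repetitions with both present); diagonal is 1.
    """
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 patients for LOOCV")
    if not 2 <= k <= n - 2:
        raise ValueError(f"k={k} infeasible for LOOCV folds of size {n - 1}")
    together = np.zeros((n, n))
    both = np.zeros((n, n), dtype=int)
    for left_out in range(n):
        keep = np.arange(n) != left_out
        fold = table.iloc[keep]
        assign = hierarchical_cluster(fold, k=k, standardize=standardize)
        lab = assign.labels
        same = (lab[:, None] == lab[None, :]).astype(float)
        ix = np.ix_(keep, keep)
        together[ix] += same
        both[ix] += 1
    with np.errstate(invalid="ignore"):
        m = np.where(both > 0, together / np.maximum(both, 1), 0.0)
    np.fill_diagonal(m, 1.0)
    return ConsensusMatrix(
        patient_ids=[str(p) for p in table.index], m=m, co_presence=both
    )


def cluster_consensus_means(
    cm: ConsensusMatrix, labels: np.ndarray | list[int]
) -> dict[int, float]:
    """Mean consensus over unordered within-cluster pairs, per cluster.

    A singleton cluster has no pairs; its mean is reported as NaN with a
    warning.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != len(cm.patient_ids):
        raise ValueError("labels length must match consensus matrix")
    out: dict[int, float] = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            logger.warning("cluster %d is a singleton; consensus mean undefined", c)
            out[int(c)] = float("nan")
            continue
        sub = cm.m[np.ix_(members, members)]
        iu = np.triu_indices(members.size, k=1)
        out[int(c)] = float(sub[iu].mean())
    return out
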