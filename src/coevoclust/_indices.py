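"""Cluster-validity indices and their optimal-k decision rules.

Each index scores a family of partitions (here: Ward-linkage cuts of the 3-D
PCA scores for k in [k_min, k_max]) and votes for one k according to the
optimum rule of its original publication: a plain maximum/minimum, the
largest jump or drop between successive k, a second-difference (elbow), or a
published critical value (Hartigan).  Indices whose value is numerically
undefined for the data at hand (zero variance, singular within-group
scatter, ...) abstain rather than casting an arbitrary vote.

Implemented electorate (21): CH, Silhouette, DB, Dunn, C-index, Gamma,
Gplus, Tau, Ptbiserial, McClain, Ratkowsky, Ball, Hartigan, KL, TraceW,
TrCovW, Scott, Marriot, Friedman, Rubin, SD.  Not implemented (always
logged as excluded so the electorate is explicit): CCC, Gap, Duda,
Pseudot2, Frey, SDbw, Beale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

logger = logging.getLogger(__name__)

__all__ = ["IMPLEMENTED_INDICES", "EXCLUDED_INDICES", "compute_index_votes"]

EXCLUDED_INDICES = ("CCC", "Gap", "Duda", "Pseudot2", "Frey", "SDbw", "Beale")

#: Threshold of Hartigan's original stopping rule: the smallest k with
#: H(k) <= 10 is taken as optimal.
_HARTIGAN_CRIT = 10.0


@dataclass
class _PartitionStats:
    k: int
    labels: np.ndarray
    sizes: np.ndarray
    centroids: np.ndarray
    tr_w: float          # total within-cluster sum of squares
    w_scatter: np.ndarray  # pooled within-group scatter matrix (p x p)
    wgss_var: np.ndarray   # per-variable within-group sum of squares


def _partition_stats(x: np.ndarray, labels: np.ndarray) -> _PartitionStats:
    ks = np.unique(labels)
    p = x.shape[1]
    w = np.zeros((p, p))
    wgss_var = np.zeros(p)
    centroids = np.zeros((len(ks), p))
    sizes = np.zeros(len(ks), dtype=int)
    for idx, lab in enumerate(ks):
        pts = x[labels == lab]
        c = pts.mean(axis=0)
        centroids[idx] = c
        sizes[idx] = len(pts)
        dev = pts - c
        w += dev.T @ dev
        wgss_var += (dev ** 2).sum(axis=0)
    return _PartitionStats(
        k=len(ks), labels=labels, sizes=sizes, centroids=centroids,
        tr_w=float(np.trace(w)), w_scatter=w, wgss_var=wgss_var,
    )


class _Geometry:
    """Shared per-dataset quantities: total scatter and pairwise distances."""

    def __init__(self, x: np.ndarray):
        self.x = x
        self.n, self.p = x.shape
        dev = x - x.mean(axis=0)
        self.t_scatter = dev.T @ dev
        self.tr_t = float(np.trace(self.t_scatter))
        self.tgss_var = (dev ** 2).sum(axis=0)
        self.dvec = pdist(x)
        self.dmat = squareform(self.dvec)
        iu = np.triu_indices(self.n, 1)
        self._iu = iu

    def within_mask(self, labels: np.ndarray) -> np.ndarray:
        return labels[self._iu[0]] == labels[self._iu[1]]


# ---------------------------------------------------------------------------
# per-k index values


def _sum_pair_stats(geo: _Geometry, st: _PartitionStats):
    within = geo.within_mask(st.labels)
    dw = geo.dvec[within]
    db = geo.dvec[~within]
    return dw, db


def _v_cindex(geo, st):
    dw, db = _sum_pair_stats(geo, st)
    nw = dw.size
    if nw == 0:
        return np.nan
    ds = np.sort(geo.dvec)
    smin = ds[:nw].sum()
    smax = ds[-nw:].sum()
    if smax == smin:
        return np.nan
    return (dw.sum() - smin) / (smax - smin)


def _concordance(geo, st):
    dw, db = _sum_pair_stats(geo, st)
    if dw.size == 0 or db.size == 0:
        return None
    # s_plus: within-pair distance smaller than between-pair distance
    db_sorted = np.sort(db)
    n_db_below = np.searchsorted(db_sorted, dw, side="left")
    n_db_at_or_below = np.searchsorted(db_sorted, dw, side="right")
    s_plus = float((db.size - n_db_at_or_below).sum())
    s_minus = float(n_db_below.sum())
    return dw.size, db.size, s_plus, s_minus


def _v_gamma(geo, st):
    c = _concordance(geo, st)
    if c is None:
        return np.nan
    _, _, sp, sm = c
    return (sp - sm) / (sp + sm) if sp + sm > 0 else np.nan


def _v_gplus(geo, st):
    c = _concordance(geo, st)
    if c is None:
        return np.nan
    _, _, _, sm = c
    nt = geo.dvec.size
    return 2.0 * sm / (nt * (nt - 1))


def _v_tau(geo, st):
    c = _concordance(geo, st)
    if c is None:
        return np.nan
    nw, nb, sp, sm = c
    nt = geo.dvec.size
    v0 = nt * (nt - 1) / 2.0
    ties = nw * (nw - 1) / 2.0 + nb * (nb - 1) / 2.0
    denom = np.sqrt((v0 - ties) * v0)
    return (sp - sm) / denom if denom > 0 else np.nan


def _v_ptbiserial(geo, st):
    dw, db = _sum_pair_stats(geo, st)
    if dw.size == 0 or db.size == 0:
        return np.nan
    nt = geo.dvec.size
    sd = geo.dvec.std()
    if sd == 0:
        return np.nan
    return (db.mean() - dw.mean()) * np.sqrt(dw.size * db.size / nt**2) / sd


def _v_mcclain(geo, st):
    dw, db = _sum_pair_stats(geo, st)
    if dw.size == 0 or db.size == 0 or db.mean() == 0:
        return np.nan
    return dw.mean() / db.mean()


def _v_dunn(geo, st):
    labels = st.labels
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return np.nan
    max_diam = 0.0
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        if idx.size > 1:
            max_diam = max(max_diam, geo.dmat[np.ix_(idx, idx)].max())
    if max_diam == 0:
        return np.nan
    min_between = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            ia = np.flatnonzero(labels == a)
            ib = np.flatnonzero(labels == b)
            min_between = min(min_between, geo.dmat[np.ix_(ia, ib)].min())
    return min_between / max_diam


def _v_ratkowsky(geo, st):
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (geo.tgss_var - st.wgss_var) / geo.tgss_var
    ratio = np.clip(ratio, 0.0, 1.0)
    if not np.all(np.isfinite(ratio)):
        return np.nan
    return float(np.mean(np.sqrt(ratio))) / np.sqrt(st.k)


def _v_sd_scat(geo, st):
    norm_tot = np.linalg.norm(geo.x.var(axis=0))
    if norm_tot == 0:
        return np.nan
    acc = 0.0
    for lab in np.unique(st.labels):
        pts = geo.x[st.labels == lab]
        acc += np.linalg.norm(pts.var(axis=0))
    return acc / (st.k * norm_tot)


def _v_sd_dis(geo, st):
    c = st.centroids
    if len(c) < 2:
        return np.nan
    cd = squareform(pdist(c))
    off = cd[~np.eye(len(c), dtype=bool)]
    dmax, dmin = off.max(), off.min()
    if dmin == 0:
        return np.nan
    return (dmax / dmin) * float(np.sum(1.0 / cd.sum(axis=1)))


# ---------------------------------------------------------------------------
# vote computation


def compute_index_votes(
    x: np.ndarray,
    labels_by_k: dict[int, np.ndarray],
    k_min: int,
    k_max: int,
) -> dict[str, int]:
    """Vote of every implemented index over partitions for k in [k_min, k_max].

    ``labels_by_k`` should also contain partitions for k_min-1 and k_max+1
    where available; jump/elbow rules and the Hartigan/KL indices consume the
    flanking values.  An index abstains (is absent from the result, with a
    log record) when its value is undefined for any k it needs.
    """
    geo = _Geometry(x)
    n, p = geo.n, geo.p
    if geo.tr_t <= 1e-12:  # no variance at all: every index is undefined
        logger.info("degenerate geometry (zero total scatter); all indices abstain")
        return {}
    stats = {k: _partition_stats(x, lab) for k, lab in labels_by_k.items()}
    ks = list(range(k_min, k_max + 1))

    def values_over(fn, krange):
        out = {}
        for k in krange:
            if k not in stats:
                return None
            with np.errstate(all="ignore"):
                try:
                    v = float(fn(geo, stats[k]))
                except (ZeroDivisionError, ValueError, np.linalg.LinAlgError):
                    v = np.nan
            if not np.isfinite(v):
                return None
            out[k] = v
        return out

    def argbest(vals, direction):
        items = sorted(vals.items())  # ties resolved toward smaller k
        if direction == "max":
            return max(items, key=lambda kv: kv[1])[0]
        return min(items, key=lambda kv: kv[1])[0]

    votes: dict[str, int] = {}
    abstained: list[str] = []

    def cast(name, k):
        if k is None:
            abstained.append(name)
        else:
            votes[name] = int(k)

    # --- plain max/min indices on [k_min, k_max] -------------------------
    def sk_metric(metric):
        def fn(geo, st):
            if len(np.unique(st.labels)) < 2:
                return np.nan
            return metric(geo.x, st.labels)
        return fn

    plain = [
        ("CH", sk_metric(calinski_harabasz_score), "max"),
        ("Silhouette", sk_metric(silhouette_score), "max"),
        ("DB", sk_metric(davies_bouldin_score), "min"),
        ("Dunn", _v_dunn, "max"),
        ("Cindex", _v_cindex, "min"),
        ("Gamma", _v_gamma, "max"),
        ("Gplus", _v_gplus, "min"),
        ("Tau", _v_tau, "max"),
        ("Ptbiserial", _v_ptbiserial, "max"),
        ("McClain", _v_mcclain, "min"),
        ("Ratkowsky", _v_ratkowsky, "max"),
    ]
    for name, fn, direction in plain:
        vals = values_over(fn, ks)
        cast(name, argbest(vals, direction) if vals else None)

    # --- scatter-based indices needing flanking k ------------------------
    trw = values_over(lambda g, s: s.tr_w, sorted(stats))
    detw = values_over(
        lambda g, s: np.linalg.det(s.w_scatter), sorted(stats)
    )
    det_t = float(np.linalg.det(geo.t_scatter))

    def jumps(vals, krange, kind):
        """Pick k by jump ('up'), drop ('down') or elbow rule.

        Differences are taken between levels of the candidate range only,
        so these rules vote on its interior: a first/last k has no
        neighbouring level to differ against.
        """
        krange = [k for k in krange if k - 1 in vals and k - 1 >= k_min]
        if kind == "elbow":
            krange = [k for k in krange if k + 1 in vals and k + 1 <= k_max]
        if not krange:
            return None
        best_k, best_v = None, -np.inf
        for k in krange:
            if kind == "up":
                if k - 1 not in vals:
                    return None
                v = vals[k] - vals[k - 1]
            elif kind == "down":
                if k - 1 not in vals:
                    return None
                v = vals[k - 1] - vals[k]
            else:  # second difference
                if k - 1 not in vals or k + 1 not in vals:
                    return None
                v = vals[k + 1] + vals[k - 1] - 2 * vals[k]
            if v > best_v:
                best_k, best_v = k, v
        return best_k

    # Ball: mean within-cluster dispersion trW/k; optimum at largest drop.
    if trw:
        ball = {k: trw[k] / k for k in trw}
        cast("Ball", jumps(ball, ks, "down"))
    else:
        cast("Ball", None)

    # TraceW: elbow (maximum second difference) of trW.
    cast("TraceW", jumps(trw, ks, "elbow") if trw else None)

    # Hartigan: H(k) = (trW_k/trW_{k+1} - 1)(n-k-1); smallest k with H <= 10.
    hart_k = None
    if trw:
        for k in ks:
            if k in trw and k + 1 in trw and trw[k + 1] > 0:
                h = (trw[k] / trw[k + 1] - 1.0) * (n - k - 1)
                if h <= _HARTIGAN_CRIT:
                    hart_k = k
                    break
    cast("Hartigan", hart_k)

    # KL: |DIFF_k / DIFF_{k+1}|, DIFF_k = (k-1)^{2/p} trW_{k-1} - k^{2/p} trW_k.
    def _diff(k):
        return (k - 1) ** (2.0 / p) * trw[k - 1] - k ** (2.0 / p) * trw[k]

    kl_vals = None
    if trw and all(k in trw for k in range(k_min - 1, k_max + 2)):
        kl_vals = {}
        for k in ks:
            d2 = _diff(k + 1)
            kl_vals[k] = abs(_diff(k) / d2) if d2 != 0 else np.nan
        if not all(np.isfinite(v) for v in kl_vals.values()):
            kl_vals = None
    cast("KL", argbest(kl_vals, "max") if kl_vals else None)

    # Determinant-based: Scott, Marriot, Rubin, TrCovW, Friedman.
    if detw and det_t > 0 and all(v > 0 for v in detw.values()):
        scott = {k: n * np.log(det_t / detw[k]) for k in detw}
        cast("Scott", jumps(scott, ks, "up"))
        marriot = {k: k**2 * detw[k] for k in detw}
        cast("Marriot", jumps(marriot, ks, "elbow"))
        # Rubin: minimum second difference = elbow of the negated values
        rubin = {k: -det_t / detw[k] for k in detw}
        cast("Rubin", jumps(rubin, ks, "elbow"))
    else:
        cast("Scott", None)
        cast("Marriot", None)
        cast("Rubin", None)

    trcovw = values_over(
        lambda g, s: np.trace(np.cov(s.w_scatter)), sorted(stats)
    )
    cast("TrCovW", jumps(trcovw, ks, "down") if trcovw else None)

    def _friedman(geo, st):
        b = geo.t_scatter - st.w_scatter
        return np.trace(np.linalg.solve(st.w_scatter, b))

    fried = values_over(_friedman, sorted(stats))
    cast("Friedman", jumps(fried, ks, "up") if fried else None)

    # SD index: alpha * Scat + Dis with alpha = Dis(k_max); minimum.
    scat = values_over(_v_sd_scat, ks)
    dis = values_over(_v_sd_dis, ks)
    if scat and dis:
        alpha = dis[k_max]
        sd_vals = {k: alpha * scat[k] + dis[k] for k in ks}
        cast("SD", argbest(sd_vals, "min"))
    else:
        cast("SD", None)

    if abstained:
        logger.info("indices abstaining: %s", ", ".join(sorted(abstained)))
    logger.debug(
        "indices excluded from the electorate (not implemented): %s",
        ", ".join(EXCLUDED_INDICES),
    )
    return votes


IMPLEMENTED_INDICES = (
    "CH", "Silhouette", "DB", "Dunn", "Cindex", "Gamma", "Gplus", "Tau",
    "Ptbiserial", "McClain", "Ratkowsky", "Ball", "TraceW", "Hartigan",
    "KL", "Scott", "Marriot", "Rubin", "TrCovW", "Friedman", "SD",
)
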