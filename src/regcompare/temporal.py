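"""Temporal expression dynamics: dynamic-gene selection, z-scaling, fuzzy
c-means soft clustering, and Calinski-Harabasz selection of the cluster count.

The clusterer is standard Bezdek fuzzy c-means with Euclidean distance:

    u_ij = 1 / sum_l (d_ij / d_lj)^(2/(m-1))        (memberships)
    c_i  = sum_j u_ij^m x_j / sum_j u_ij^m          (centers)

iterated until the maximum center shift drops below ``tol``. The fuzzifier
``m`` (default 2) controls softness; as m -> 1 the partition hardens. A point
coincident with a center receives membership 1 there. The alternating updates
never increase the objective sum_ij u_ij^m d_ij^2.

Cluster-count selection uses hard k-means partitions scored by the
Calinski-Harabasz index CH(k) = [B(k)/(k-1)] / [W(k)/(n-k)] (between- over
within-cluster dispersion); CH is undefined at k=1, which is reported but
excluded from the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .io_formats import ValidationError


def dynamic_genes(
    mean_cpm: pd.DataFrame, logfc_threshold: float = 2.0, pseudocount: float = 0.5
) -> set[str]:
    """Genes whose expression changes by more than ``logfc_threshold`` in
    log2 units relative to the first stage (column order defines time).

    A gene is kept iff max_{t>0} |log2((cpm_t + pc) / (cpm_0 + pc))| is
    strictly greater than the threshold.
    """
    if mean_cpm.shape[1] < 2:
        raise ValidationError("need >= 2 stages")
    vals = mean_cpm.to_numpy(dtype=float) + pseudocount
    lfc = np.log2(vals[:, 1:]) - np.log2(vals[:, [0]])
    keep = np.abs(lfc).max(axis=1) > logfc_threshold
    return set(mean_cpm.index[keep])


def zscale(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scaling (population standard deviation): each gene's
    profile gets mean 0 and sd 1 across stages."""
    if profiles.shape[1] < 2:
        raise ValidationError("need >= 2 stages")
    vals = profiles.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population sd (ddof=0)
    zero = sd[:, 0] == 0
    if zero.any():
        bad = list(profiles.index[zero])[:5]
        raise ValidationError(f"zero-variance profile(s): {bad}")
    return pd.DataFrame((vals - mu) / sd, index=profiles.index, columns=profiles.columns)


@dataclass
class TemporalClustering:
    centers: np.ndarray  # k x T
    membership: pd.DataFrame  # n x k, rows sum to 1
    m: float
    k: int
    converged: bool
    n_iter: int
    objective: list = field(default_factory=list)

    @property
    def assigned(self) -> pd.Series:
        """Per-gene argmax cluster (0-based)."""
        return self.membership.idxmax(axis=1)


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    # squared Euclidean distances n x k
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero_rows = (d2 == 0).any(axis=1)
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power)
        u = inv / inv.sum(axis=1, keepdims=True)
    if zero_rows.any():
        # a point coincident with a center gets full membership there
        # (split evenly if coincident with several)
        hit = d2[zero_rows] == 0
        u[zero_rows] = hit / hit.sum(axis=1, keepdims=True)
    return u, d2


def cmeans(
    profiles: pd.DataFrame,
    k: int = 5,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_init: int = 5,
) -> TemporalClustering:
    """Fuzzy c-means soft clustering of (z-scaled) temporal profiles.

    Initial centers are drawn from ``k`` distinct data points; the
    alternating optimization is restarted ``n_init`` times (the objective is
    non-convex and a single start can settle in a poor local optimum) and
    the run with the lowest final objective is returned. All restarts are
    driven by ``seed``. Raises if k > n; ``converged=False`` when
    ``max_iter`` is reached before the center shift drops below ``tol``.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"need 1 <= k <= n, got k={k}, n={n}")
    if m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    if n_init < 1:
        raise ValidationError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best: TemporalClustering | None = None
    for _restart in range(n_init):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        converged = False
        objective: list[float] = []
        it = 0
        for it in range(1, max_iter + 1):
            u, d2 = _memberships(X, centers, m)
            um = u**m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            objective.append(float((um * d2).sum()))
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                converged = True
                break
        u, d2 = _memberships(X, centers, m)
        final_obj = float(((u**m) * d2).sum())
        if best is None or final_obj < best.objective[-1]:
            membership = pd.DataFrame(u, index=profiles.index, columns=range(k))
            best = TemporalClustering(
                centers=centers, membership=membership, m=m, k=k,
                converged=converged, n_iter=it, objective=objective + [final_obj],
            )
    return best


def calinski_select(
    profiles: pd.DataFrame,
    k_range: range = range(1, 11),
    n_restarts: int = 10,
    seed: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count by the Calinski-Harabasz criterion over hard
    k-means partitions. Returns (best_k, {k: CH score}); k=1 is reported with
    NaN and excluded from the argmax."""
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    scores: dict[int, float] = {}
    for k in k_range:
        if k < 1 or k >= n:
            raise ValidationError(f"k={k} outside [1, n-1]")
        if k == 1:
            scores[k] = float("nan")
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < 2:
            scores[k] = float("nan")
            continue
        scores[k] = float(calinski_harabasz_score(X, labels))
    valid = {k: s for k, s in scores.items() if not np.isnan(s)}
    if not valid:
        raise ValidationError("no k >= 2 in k_range")
    best_k = max(valid, key=lambda k: (valid[k], -k))
    return best_k, scores


def cluster_report(
    clustering: TemporalClustering, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene cluster assignment with membership values, plus the center
    profiles — the serialization used for plotting and enrichment.

    Returns (members, centers): members has one row per gene (no loss) with
    columns gene_id, cluster, membership; centers is k x T.
    """
    assigned = clustering.assigned
    mem = clustering.membership
    rows = [
        {
            "gene_id": g,
            "cluster": int(assigned[g]),
            "membership": float(mem.loc[g, assigned[g]]),
        }
        for g in mem.index
    ]
    members = pd.DataFrame(rows, columns=["gene_id", "cluster", "membership"])
    centers = pd.DataFrame(
        clustering.centers,
        index=[f"cluster_{i}" for i in range(clustering.k)],
        columns=profiles.columns,
    )
    return members, centers
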