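"""Temporal-profile clustering with a permutation-null choice of k.

Reporter mean activity profiles are clustered by k-means (Euclidean,
best of ``n_starts`` random starts).  For each candidate k the
within-cluster sum of squared error SSE(k) is compared with the mean SSE
of the same procedure run on permuted datasets in which every timepoint
column is shuffled independently across reporters — a null that keeps
each timepoint's marginal distribution but destroys temporal coherence.
The chosen k maximizes the gap SSE_perm(k) - SSE(k), taking the smallest
k on ties (note gap(1) = 0 identically, since the total sum of squares is
invariant under column-wise permutation).  Clusters are then ranked from
most to least active by their mean reporter activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._seeds import substream

__all__ = ["ClusterModel", "cluster_profiles"]


@dataclass
class ClusterModel:
    """k-means assignment with the SSE/gap curves that selected k."""

    k: int
    labels: pd.Series = field(repr=False)        # reporter -> cluster label
    cluster_rank: pd.Series = field(repr=False)  # cluster label -> rank (1 = most active)
    sse: dict[int, float] = field(repr=False)
    sse_perm: dict[int, float] = field(repr=False)
    features: pd.DataFrame = field(repr=False)   # reporter x timepoint matrix used

    @property
    def gap(self) -> dict[int, float]:
        return {k: self.sse_perm[k] - self.sse[k] for k in self.sse}

    def assignments(self) -> pd.DataFrame:
        out = pd.DataFrame({"cluster": self.labels})
        out["cluster_rank"] = self.cluster_rank.reindex(out["cluster"]).to_numpy()
        out.index.name = "reporter"
        return out.sort_values(["cluster_rank", "cluster"]).sort_index(kind="stable")

    def top_cluster_members(self) -> list[str]:
        top = self.cluster_rank.index[self.cluster_rank == 1][0]
        return sorted(self.labels.index[self.labels == top])

    def curves_dict(self) -> dict:
        return {
            "k": int(self.k),
            "sse": {str(k): v for k, v in self.sse.items()},
            "sse_perm": {str(k): v for k, v in self.sse_perm.items()},
            "gap": {str(k): v for k, v in self.gap.items()},
        }


def _best_sse(x: np.ndarray, k: int, n_starts: int, seed: int) -> tuple[float, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=n_starts, init="random", random_state=seed)
    labels = km.fit_predict(x)
    return float(km.inertia_), labels


def cluster_profiles(
    profiles,
    k_range=range(1, 11),
    n_starts: int = 50,
    n_perm: int = 100,
    seed: int = 0,
) -> ClusterModel:
    """Cluster reporter mean profiles, choosing k by the permutation gap.

    ``profiles`` is an ActivityProfileSet or a reporter x timepoint
    DataFrame of mean activities.  Missing entries are imputed with the
    reporter's own temporal mean.  ``k_range`` values that reach the
    number of reporters are dropped with a warning.
    """
    feats = profiles.mean_profiles() if hasattr(profiles, "mean_profiles") else profiles.copy()
    n = len(feats)
    if n < 2:
        raise ValueError("need >=2 reporters to cluster")
    row_means = feats.mean(axis=1)
    feats = feats.apply(lambda col: col.fillna(row_means))
    if feats.isna().any().any():
        raise ValueError("reporter with no observed activity at any timepoint")

    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 for k in ks):
        raise ValueError("k must be >= 1")
    if ks[-1] >= n:
        warnings.warn(f"k_range truncated to < {n} reporters", stacklevel=2)
        ks = [k for k in ks if k < n]
        if not ks:
            ks = [1]

    x = feats.to_numpy(dtype=float)
    rng = substream(seed, "cluster")
    kmeans_seed = int(rng.integers(2**31))

    sse: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        sse[k], labels_by_k[k] = _best_sse(x, k, n_starts, kmeans_seed)

    perm_rng = substream(seed, "cluster-null")
    perm_sse = {k: [] for k in ks}
    for _ in range(n_perm):
        xp = x.copy()
        for j in range(xp.shape[1]):
            xp[:, j] = perm_rng.permutation(xp[:, j])
        pseed = int(perm_rng.integers(2**31))
        for k in ks:
            perm_sse[k].append(_best_sse(xp, k, n_starts, pseed)[0])
    sse_perm = {k: float(np.mean(v)) for k, v in perm_sse.items()}

    gap = {k: sse_perm[k] - sse[k] for k in ks}
    best_gap = max(gap.values())
    chosen = min(k for k, g in gap.items() if g >= best_gap - 1e-12)

    labels = pd.Series(labels_by_k[chosen], index=feats.index, name="cluster")
    activity = feats.mean(axis=1)
    cluster_activity = activity.groupby(labels).mean().sort_values(ascending=False)
    cluster_rank = pd.Series(
        np.arange(1, len(cluster_activity) + 1), index=cluster_activity.index, name="rank"
    )
    return ClusterModel(
        k=chosen, labels=labels, cluster_rank=cluster_rank,
        sse=sse, sse_perm=sse_perm, features=feats,
    )
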