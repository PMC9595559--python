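"""Cluster-quality feedback: centroids, silhouettes, inter-cluster distances.

All analytics work in the 2m-dimensional joint feature space (m RDR values
followed by m BAF values per bin) and exclude bins carrying the reserved
labels -1 (unclustered) and -2 (erased).  Exact silhouettes cost O(n^2)
pairwise distances, which is the bottleneck at realistic bin counts
(n around 50,000), so silhouettes are approximated on a seeded uniform
subsample; a cap at or above n disables the approximation entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples


@dataclass
class CentroidTable:
    """Per-cluster, per-sample mean RDR/BAF and member counts."""

    cluster_ids: np.ndarray  # (k,) nonnegative, ascending
    counts: np.ndarray  # (k,)
    rdr: np.ndarray  # (k, m)
    baf: np.ndarray  # (k, m)
    samples: list[str]

    def feature_vectors(self) -> np.ndarray:
        """Centroids embedded in the 2m-dimensional bin feature space."""
        return np.hstack([self.rdr, self.baf])

    def to_frame(self) -> pd.DataFrame:
        data = {"CLUSTER": self.cluster_ids, "N_BINS": self.counts}
        for p, name in enumerate(self.samples):
            data[f"RD_{name}"] = self.rdr[:, p]
            data[f"BAF_{name}"] = self.baf[:, p]
        return pd.DataFrame(data)


def compute_centroids(table) -> CentroidTable:
    """Arithmetic-mean centroid of every nonnegative cluster.

    Erased (-2) and unclustered (-1) bins never contribute.  With no
    nonnegative labels at all an empty table is returned with a warning.
    """
    mask = table.cluster >= 0
    ids = np.unique(table.cluster[mask])
    if len(ids) == 0:
        warnings.warn("compute_centroids: no nonnegative cluster labels")
        return CentroidTable(
            cluster_ids=ids,
            counts=np.zeros(0, dtype=np.int64),
            rdr=np.zeros((0, table.m)),
            baf=np.zeros((0, table.m)),
            samples=list(table.samples),
        )
    counts = np.empty(len(ids), dtype=np.int64)
    rdr = np.empty((len(ids), table.m))
    baf = np.empty((len(ids), table.m))
    for row, c in enumerate(ids):
        members = table.cluster == c
        counts[row] = members.sum()
        rdr[row] = table.rdr[members].mean(axis=0)
        baf[row] = table.baf[members].mean(axis=0)
    return CentroidTable(
        cluster_ids=ids, counts=counts, rdr=rdr, baf=baf, samples=list(table.samples)
    )


def silhouette_by_cluster(
    features: np.ndarray,
    labels: np.ndarray,
    sample_cap: int = 2000,
    seed: int | None = None,
) -> dict[int, float]:
    """Per-cluster mean silhouette on a uniform subsample of at most `sample_cap` bins.

    The silhouette of a bin is (b - a) / max(a, b) with a its mean distance
    to co-members and b the smallest mean distance to another cluster; a
    cluster's coefficient is the mean over its (subsampled) members.
    Singleton clusters in the subsample score 0 by convention, with a
    warning.  Clusters missed by the subsample map to NaN.  With
    ``sample_cap >= n`` the result equals the exact silhouette.
    """
    labels = np.asarray(labels)
    if sample_cap < 2:
        raise ValueError("sample_cap must be >= 2")
    keep = np.flatnonzero(labels >= 0)
    all_ids = np.unique(labels[keep])
    if len(all_ids) < 2:
        raise ValueError("silhouette requires >= 2 nonnegative clusters")
    if len(keep) > sample_cap:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=sample_cap, replace=False))
    sub_labels = labels[keep]
    sub_ids, sub_counts = np.unique(sub_labels, return_counts=True)
    result: dict[int, float] = {int(c): float("nan") for c in all_ids}
    if len(sub_ids) < 2:
        warnings.warn("silhouette subsample hit a single cluster; scores undefined")
        return result
    if np.any(sub_counts == 1):
        warnings.warn("singleton cluster in silhouette subsample; its score is set to 0")
    values = silhouette_samples(features[keep], sub_labels)  # sklearn scores singletons 0
    for c in sub_ids:
        result[int(c)] = float(values[sub_labels == c].mean())
    return result


def mean_intercluster_distance(
    features: np.ndarray,
    labels: np.ndarray,
    target_cluster: int,
    sample_cap: int = 2000,
    seed: int | None = None,
    method: str = "points",
) -> dict[int, float]:
    """Average Euclidean distance from `target_cluster` to every other cluster.

    ``method="points"`` averages over all cross pairs of (subsampled) member
    bins — clusters with a distance near 0 are merge candidates.
    ``method="centroids"`` reports plain centroid-to-centroid distances.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels[labels >= 0])
    if target_cluster not in ids:
        raise ValueError(f"cluster {target_cluster} not in use")
    rng = np.random.default_rng(seed)

    def members(c):
        rows = np.flatnonzero(labels == c)
        if method == "points" and len(rows) > sample_cap:
            rows = np.sort(rng.choice(rows, size=sample_cap, replace=False))
        return features[rows]

    out: dict[int, float] = {}
    a = members(target_cluster)
    for c in ids:
        if c == target_cluster:
            continue
        b = members(c)
        if method == "points":
            out[int(c)] = float(cdist(a, b).mean())
        elif method == "centroids":
            out[int(c)] = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
        else:
            raise ValueError("method must be 'points' or 'centroids'")
    return out


def allelic_imbalance(baf):
    """Map BAF in [0, 0.5] to allelic imbalance 0.5 - BAF.

    0 means perfect allelic balance (BAF 0.5); 0.5 means complete loss of
    one allele (BAF 0).
    """
    baf = np.asarray(baf, dtype=float)
    if np.any((baf < 0) | (baf > 0.5)):
        raise ValueError("BAF must lie in [0, 0.5]")
    out = 0.5 - baf
    return float(out) if out.ndim == 0 else out
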