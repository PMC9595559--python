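"""Scripted cluster-editing operations with a replayable operation log.

These are headless equivalents of interactive curation actions: reassign a
selection of bins, open a new cluster, erase bins, merge clusters whose
centroids sit within per-sample RDR/BAF thresholds, and absorb individual
bins into nearby clusters.  Every operation touches only the cluster-label
vector — never coordinates, RDR or BAF — and returns an
:class:`EditLogEntry` recording the affected bins with their previous and
new labels, so the whole session can be replayed from the initial
clustering or undone step by step.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .analytics import compute_centroids
from .core import BinTable, ERASED


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-sample (t_RDR, t_BAF) gating thresholds, one pair per sample."""

    t_rdr: np.ndarray
    t_baf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_rdr", np.asarray(self.t_rdr, dtype=float))
        object.__setattr__(self, "t_baf", np.asarray(self.t_baf, dtype=float))
        if self.t_rdr.shape != self.t_baf.shape or self.t_rdr.ndim != 1:
            raise ValueError("t_rdr and t_baf must be 1-D arrays of equal length")
        if np.any(self.t_rdr < 0) or np.any(self.t_baf < 0):
            raise ValueError("thresholds must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.t_rdr)

    @classmethod
    def uniform(cls, t_rdr: float, t_baf: float, m: int) -> "ThresholdSpec":
        """Broadcast one (t_rdr, t_baf) pair to all m samples."""
        return cls(np.full(m, t_rdr), np.full(m, t_baf))


@dataclass
class EditLogEntry:
    operation: str
    params: dict
    indices: np.ndarray
    previous: np.ndarray
    new: np.ndarray
    timestamp: float = field(default_factory=time.time)

    def as_line(self) -> str:
        return "\t".join(
            [self.operation, json.dumps(self.params, sort_keys=True), str(len(self.indices))]
        )


class EditLog:
    """Ordered record of editing operations; supports replay and undo."""

    def __init__(self) -> None:
        self.entries: list[EditLogEntry] = []

    def append(self, entry: EditLogEntry) -> None:
        self.entries.append(entry)

    def replay(self, initial: np.ndarray) -> np.ndarray:
        """Apply all entries in order to a copy of `initial` labels."""
        labels = np.asarray(initial).copy()
        for entry in self.entries:
            labels[entry.indices] = entry.new
        return labels

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for entry in self.entries:
                fh.write(entry.as_line() + "\n")

    def __len__(self) -> int:
        return len(self.entries)


def _selection_array(table: BinTable, selection) -> np.ndarray:
    sel = np.unique(np.asarray(list(selection), dtype=np.int64))
    if len(sel) and (sel[0] < 0 or sel[-1] >= table.n):
        raise IndexError("selection indices out of range")
    return sel


def assign_cluster(table: BinTable, selection, cluster_id: int) -> EditLogEntry | None:
    """Reassign the selected bins to `cluster_id` (>= -2); others untouched.

    Assigning -1 marks bins unclustered; -2 erases them (excluded from
    exports).  An empty selection is a warned no-op returning None.
    """
    if cluster_id < ERASED:
        raise ValueError("cluster IDs below -2 are not allowed")
    sel = _selection_array(table, selection)
    if len(sel) == 0:
        warnings.warn("assign_cluster: empty selection, nothing to do")
        return None
    entry = EditLogEntry(
        operation="assign_cluster",
        params={"cluster_id": int(cluster_id)},
        indices=sel,
        previous=table.cluster[sel].copy(),
        new=np.full(len(sel), cluster_id, dtype=np.int64),
    )
    table.cluster[sel] = cluster_id
    return entry


def new_cluster(table: BinTable, selection) -> tuple[int, EditLogEntry]:
    """Assign the selected bins to a fresh cluster ID (max in use + 1, or 0)."""
    sel = _selection_array(table, selection)
    if len(sel) == 0:
        raise ValueError("new_cluster requires a nonempty selection")
    in_use = table.cluster[table.cluster >= 0]
    new_id = int(in_use.max()) + 1 if len(in_use) else 0
    entry = EditLogEntry(
        operation="new_cluster",
        params={"cluster_id": new_id},
        indices=sel,
        previous=table.cluster[sel].copy(),
        new=np.full(len(sel), new_id, dtype=np.int64),
    )
    table.cluster[sel] = new_id
    return new_id, entry


def plan_merge(table: BinTable, thresholds: ThresholdSpec) -> list[set[int]]:
    """Connected components of clusters flagged for merging by centroid gaps.

    A pair (j, j') is flagged iff for every sample both |dRDR| <= t_rdr and
    |dBAF| <= t_baf between the two centroids.  Flagged pairs chain: if
    (1,2) and (2,3) are flagged, {1,2,3} forms one component even when
    (1,3) is not flagged itself.  Reserved IDs -1/-2 never participate.
    """
    if thresholds.m != table.m:
        raise ValueError(f"thresholds cover {thresholds.m} samples, table has {table.m}")
    cents = compute_centroids(table)
    ids = cents.cluster_ids
    k = len(ids)
    if k < 2:
        return []
    d_rdr = np.abs(cents.rdr[:, None, :] - cents.rdr[None, :, :])
    d_baf = np.abs(cents.baf[:, None, :] - cents.baf[None, :, :])
    flagged = np.all(d_rdr <= thresholds.t_rdr, axis=2) & np.all(
        d_baf <= thresholds.t_baf, axis=2
    )
    np.fill_diagonal(flagged, False)
    n_comp, comp = connected_components(csr_matrix(flagged), directed=False)
    plan = []
    for c in range(n_comp):
        members = {int(ids[i]) for i in np.flatnonzero(comp == c)}
        if len(members) > 1:
            plan.append(members)
    plan.sort(key=min)
    return plan


def merge_by_centroids(
    table: BinTable, thresholds: ThresholdSpec, dry_run: bool = False
) -> tuple[list[set[int]], EditLogEntry | None]:
    """Merge every connected component of threshold-close clusters.

    Within each component the largest cluster (most bins; ties to the lowest
    ID) keeps its label and absorbs the others.  With ``dry_run`` the plan
    is returned and the table left untouched.
    """
    plan = plan_merge(table, thresholds)
    if dry_run or not plan:
        return plan, None
    sizes = {int(c): int(np.sum(table.cluster == c)) for comp in plan for c in comp}
    indices = []
    new_labels = []
    for comp in plan:
        target = min(comp, key=lambda c: (-sizes[c], c))
        for c in sorted(comp - {target}):
            rows = np.flatnonzero(table.cluster == c)
            indices.append(rows)
            new_labels.append(np.full(len(rows), target, dtype=np.int64))
    idx = np.concatenate(indices)
    new = np.concatenate(new_labels)
    entry = EditLogEntry(
        operation="merge_by_centroids",
        params={
            "t_rdr": thresholds.t_rdr.tolist(),
            "t_baf": thresholds.t_baf.tolist(),
            "components": [sorted(c) for c in plan],
        },
        indices=idx,
        previous=table.cluster[idx].copy(),
        new=new,
    )
    table.cluster[idx] = new
    return plan, entry


def absorb_bins(
    table: BinTable, from_ids, to_ids, thresholds: ThresholdSpec
) -> EditLogEntry | None:
    """Re-home bins of the From clusters to their nearest eligible To cluster.

    For each bin in a From cluster the candidates are the To clusters plus
    the bin's current cluster.  The nearest candidate centroid (Euclidean
    distance in the 2m-dimensional feature space, ties to the lower ID) wins
    the bin iff it is a To cluster different from the current one and the
    per-sample RDR/BAF gaps to it all sit within the thresholds.  Centroids
    are frozen at entry, so reassignment order cannot matter within a call;
    iterate the call to cascade.
    """
    from_ids = sorted({int(c) for c in from_ids})
    to_ids = sorted({int(c) for c in to_ids})
    if not from_ids or not to_ids:
        raise ValueError("from_ids and to_ids must be nonempty")
    if any(c < 0 for c in from_ids + to_ids):
        raise ValueError("reserved cluster IDs cannot participate in absorb")
    if thresholds.m != table.m:
        raise ValueError(f"thresholds cover {thresholds.m} samples, table has {table.m}")
    cents = compute_centroids(table)
    id_to_row = {int(c): i for i, c in enumerate(cents.cluster_ids)}
    missing = [c for c in from_ids + to_ids if c not in id_to_row]
    if missing:
        raise ValueError(f"cluster IDs not in use: {missing}")
    cent_feat = np.hstack([cents.rdr, cents.baf])  # (k, 2m)
    feat = np.hstack([table.rdr, table.baf])  # (n, 2m)

    moved_idx: list[int] = []
    moved_new: list[int] = []
    for i in np.flatnonzero(np.isin(table.cluster, from_ids)):
        cur = int(table.cluster[i])
        candidates = sorted(set(to_ids) | {cur})
        dists = [np.linalg.norm(feat[i] - cent_feat[id_to_row[c]]) for c in candidates]
        nearest = candidates[int(np.argmin(dists))]
        if nearest == cur or nearest not in to_ids:
            continue
        row = id_to_row[nearest]
        ok = np.all(np.abs(table.rdr[i] - cents.rdr[row]) <= thresholds.t_rdr) and np.all(
            np.abs(table.baf[i] - cents.baf[row]) <= thresholds.t_baf
        )
        if ok:
            moved_idx.append(int(i))
            moved_new.append(nearest)
    if not moved_idx:
        return None
    idx = np.asarray(moved_idx, dtype=np.int64)
    new = np.asarray(moved_new, dtype=np.int64)
    entry = EditLogEntry(
        operation="absorb_bins",
        params={
            "from": from_ids,
            "to": to_ids,
            "t_rdr": thresholds.t_rdr.tolist(),
            "t_baf": thresholds.t_baf.tolist(),
        },
        indices=idx,
        previous=table.cluster[idx].copy(),
        new=new,
    )
    table.cluster[idx] = new
    return entry


def undo(table: BinTable, log: EditLog) -> EditLogEntry | None:
    """Invert the most recent log entry using its stored previous labels."""
    if not log.entries:
        warnings.warn("undo: empty log, nothing to do")
        return None
    entry = log.entries.pop()
    table.cluster[entry.indices] = entry.previous
    return entry
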