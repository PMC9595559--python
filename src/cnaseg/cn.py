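"""Integer allele-specific copy-state inference under purity/ploidy anchors.

A bin's allele-specific state is an integer pair (a, b) with a >= b >= 0
major/minor copies.  In a bulk sample of purity mu (tumor-cell fraction)
mixed with normal diploid cells, the expected observations under the
standard normal-contamination model are

    E[BAF] = (mu * b + (1 - mu) * 1) / (mu * (a + b) + (1 - mu) * 2)
    E[RDR] = (mu * (a + b) + (1 - mu) * 2) / (mu * rho + (1 - mu) * 2)

where rho is the tumor ploidy (average copies per position in tumor
cells).  At mu = 1 these reproduce the textbook anchors: state (2,1) gives
BAF 1/3 (~0.33), (3,0) gives 0.0, and (1,1) gives 0.5 at any purity.

Cluster centroids are mapped to the state minimizing the squared RDR/BAF
residual summed over samples; scanning a purity/ploidy grid ranks candidate
(mu, rho) pairs by the member-count-weighted total residual.  Driver genes
are called amplified / deleted / unaffected against a diploid total-copy
baseline of 2 (so copy-neutral LOH (2,0) counts as unaffected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .analytics import CentroidTable
from .core import BinTable, DriverGene, bins_overlapping


class CopyState(NamedTuple):
    """Allele-specific copies: a major, b minor, a >= b >= 0."""

    a: int
    b: int

    @property
    def total(self) -> int:
        return self.a + self.b


def _check_state(state: CopyState) -> CopyState:
    a, b = int(state[0]), int(state[1])
    if not a >= b >= 0:
        raise ValueError(f"copy state must satisfy a >= b >= 0, got ({a}, {b})")
    return CopyState(a, b)


@dataclass(frozen=True)
class SampleComposition:
    """Tumor purity mu in [0, 1] and tumor ploidy rho > 0 of one sample."""

    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        if not self.ploidy > 0:
            raise ValueError("ploidy must be positive")


def expected_baf(state: CopyState, mu: float) -> float:
    """Expected mirrored B-allele frequency of `state` at purity `mu`.

    Equals 0.5 whenever a == b or mu == 0.  Undefined (domain error) for
    state (0,0) at mu == 1: a pure-tumor homozygous deletion yields no DNA.
    """
    a, b = _check_state(state)
    if not 0.0 <= mu <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    den = mu * (a + b) + 2.0 * (1.0 - mu)
    if den == 0.0:
        raise ValueError("state (0,0) at purity 1 has no DNA; BAF undefined")
    return (mu * b + (1.0 - mu)) / den


def expected_rdr(state: CopyState, comp: SampleComposition) -> float:
    """Expected read-depth ratio of `state` in a sample of the given composition.

    Equals 1 for (1,1) at ploidy 2 and increases with total copies a+b.
    """
    a, b = _check_state(state)
    mu = comp.purity
    return (mu * (a + b) + 2.0 * (1.0 - mu)) / (mu * comp.ploidy + 2.0 * (1.0 - mu))


def enumerate_states(max_total: int) -> list[CopyState]:
    """All states with a >= b >= 0 and a + b <= max_total, ordered for tie-breaks.

    Sorted by total ascending then minor copies descending, so the first
    minimum of a residual scan is the preferred state under the tie rule
    (smaller total, then larger b).
    """
    if max_total < 1:
        raise ValueError("max_total must be >= 1")
    states = [
        CopyState(a, b)
        for t in range(max_total + 1)
        for b in range(t // 2, -1, -1)
        for a in [t - b]
    ]
    return states


def _residual_matrix(
    centroids: CentroidTable, comps: list[SampleComposition], states: list[CopyState]
) -> np.ndarray:
    """(n_clusters, n_states) squared residuals; undefined expectations get inf."""
    k, m = centroids.rdr.shape
    if len(comps) != m:
        raise ValueError(f"need one SampleComposition per sample ({m})")
    exp_rdr = np.empty((len(states), m))
    exp_baf = np.empty((len(states), m))
    for si, state in enumerate(states):
        for p, comp in enumerate(comps):
            exp_rdr[si, p] = expected_rdr(state, comp)
            try:
                exp_baf[si, p] = expected_baf(state, comp.purity)
            except ValueError:
                exp_baf[si, p] = np.nan
    res = ((centroids.rdr[:, None, :] - exp_rdr[None, :, :]) ** 2).sum(axis=2) + (
        (centroids.baf[:, None, :] - exp_baf[None, :, :]) ** 2
    ).sum(axis=2)
    return np.where(np.isnan(res), np.inf, res)


def assign_states(
    centroids: CentroidTable,
    comps: list[SampleComposition],
    max_total: int = 6,
) -> dict[int, CopyState]:
    """Best-fitting integer state per cluster under the given compositions.

    Minimizes the squared (RDR, BAF) residual summed over samples; exact
    ties resolve to the smaller total and then the larger minor count.
    """
    if len(centroids.cluster_ids) == 0:
        raise ValueError("empty centroid table")
    states = enumerate_states(max_total)
    res = _residual_matrix(centroids, comps, states)
    best = np.argmin(res, axis=1)  # first minimum = preferred tie-break order
    return {int(c): states[best[i]] for i, c in enumerate(centroids.cluster_ids)}


def scan_purity_ploidy(
    centroids: CentroidTable,
    mu_grid,
    rho_grid,
    max_total: int = 6,
    sample: int | None = None,
) -> pd.DataFrame:
    """Rank (purity, ploidy) grid points by state-fit score, best first.

    The score of a grid point is the member-count-weighted sum over
    clusters of the minimized residual from state assignment.  By default
    one (mu, rho) pair is applied to every sample; pass ``sample`` (an
    index) to score a single sample's centroid columns alone, which is the
    right mode when purities differ across samples.  A near-zero score at
    every grid point (all clusters diploid-like) means purity is
    unidentifiable; this is flagged with a warning.
    """
    mu_grid = np.atleast_1d(np.asarray(mu_grid, dtype=float))
    rho_grid = np.atleast_1d(np.asarray(rho_grid, dtype=float))
    # snap float-arange endpoints back onto the purity domain
    mu_grid[np.isclose(mu_grid, 0.0)] = 0.0
    mu_grid[np.isclose(mu_grid, 1.0)] = 1.0
    if len(mu_grid) == 0 or len(rho_grid) == 0:
        raise ValueError("grids must be nonempty")
    if sample is not None:
        centroids = CentroidTable(
            cluster_ids=centroids.cluster_ids,
            counts=centroids.counts,
            rdr=centroids.rdr[:, [sample]],
            baf=centroids.baf[:, [sample]],
            samples=[centroids.samples[sample]],
        )
    m = centroids.rdr.shape[1]
    states = enumerate_states(max_total)
    rows = []
    for mu in mu_grid:
        for rho in rho_grid:
            comps = [SampleComposition(mu, rho)] * m
            res = _residual_matrix(centroids, comps, states)
            score = float((centroids.counts * res.min(axis=1)).sum())
            rows.append((float(mu), float(rho), score))
    out = pd.DataFrame(rows, columns=["purity", "ploidy", "score"])
    out = out.sort_values(["score", "purity", "ploidy"], kind="stable").reset_index(drop=True)
    if out["score"].max() < 1e-12:
        warnings.warn(
            "all grid points fit perfectly; purity/ploidy are unidentifiable "
            "(clusters look diploid)"
        )
    return out


def classify_gene(
    gene: DriverGene, table: BinTable, states: Mapping[int, CopyState]
) -> str:
    """Call a driver gene unaffected / deleted / amplified / ambiguous.

    Each bin overlapping the gene votes by the total copies of its
    cluster's state against a diploid baseline: total > 2 amplified, < 2
    deleted, == 2 unaffected (copy-neutral LOH (2,0) is therefore
    unaffected).  Mixed votes resolve by bin-count majority, exact ties to
    'ambiguous'.  A gene overlapping no informative bin returns 'no-data'
    with a warning.
    """
    idx = bins_overlapping(table, gene.chrom, gene.start, gene.end)
    votes: dict[str, int] = {}
    for i in idx:
        c = int(table.cluster[i])
        if c < 0 or c not in states:
            continue
        total = states[c].total
        verdict = "amplified" if total > 2 else "deleted" if total < 2 else "unaffected"
        votes[verdict] = votes.get(verdict, 0) + 1
    if not votes:
        warnings.warn(f"gene {gene.symbol} overlaps no bin with a called state")
        return "no-data"
    best = max(votes.values())
    winners = [v for v, n in votes.items() if n == best]
    return winners[0] if len(winners) == 1 else "ambiguous"
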