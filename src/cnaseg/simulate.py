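"""Synthetic multi-sample tumor bin data with known clonal ground truth.

The generator emulates multi-sample bulk DNA sequencing of a tumor with a
small number of clones: the genome (a few chromosomes of fixed-width bins)
is partitioned into contiguous segments, each tumor clone receives an
integer allele-specific copy state per segment, and each sample mixes the
clones with normal diploid cells at a sample-specific purity.  Expected
RDR/BAF per bin follow the normal-contamination closed forms generalized
to multiple clones,

    E[RDR](i, p) = sum_c u_cp * t_c(i) / sum_c u_cp * rho_c
    E[BAF](i, p) = sum_c u_cp * b_c(i) / sum_c u_cp * t_c(i)

with the normal clone fixed at (1,1) everywhere (t = 2, rho = 2) and
rho_c the bin-weighted mean total copy number of clone c, so each clone's
read-depth normalization is internally consistent.  Observed RDR adds
truncated Gaussian noise; observed BAF is binomially resampled at a
configurable per-bin SNP coverage (respecting the [0, 0.5] support) and
mirrored.  The ground-truth cluster of a bin is the tuple of clone states
at its segment, so segments sharing a state tuple share a label — the
premise of global segmentation.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cn import CopyState, enumerate_states
from .core import BinTable, UNCLUSTERED, write_bin_table


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a desk-scale but nontrivial instance: 2 chromosomes of
    250 bins x 50 kb, two samples, two tumor clones over 20 planted
    segments (60% of segments shared across clones), purities 0.6 and 0.8,
    RDR noise sd 0.05 and 500 SNP reads per bin for binomial BAF noise.
    """

    seed: int = 0
    n_chromosomes: int = 2
    bins_per_chromosome: int = 250
    bin_width: int = 50_000
    n_samples: int = 2
    n_clones: int = 2
    n_segments: int = 20
    max_total: int = 6
    fraction_shared: float = 0.6
    purities: tuple = (0.6, 0.8)
    clone_proportions: np.ndarray | None = None  # (m, n_clones), row p sums to purity p
    rdr_noise_sd: float = 0.05
    baf_coverage: float = 500.0  # math.inf disables BAF noise

    def __post_init__(self) -> None:
        if self.n_clones < 1 or self.n_samples < 1 or self.n_chromosomes < 1:
            raise ValueError("counts must be positive")
        if len(self.purities) != self.n_samples:
            raise ValueError("need one purity per sample")
        if any(not 0.0 <= mu <= 1.0 for mu in self.purities):
            raise ValueError("purities must lie in [0, 1]")
        if not self.n_chromosomes <= self.n_segments <= self.total_bins:
            raise ValueError("n_segments must lie in [n_chromosomes, total bins]")
        if self.rdr_noise_sd < 0:
            raise ValueError("rdr_noise_sd must be >= 0")
        if not (self.baf_coverage >= 1):
            raise ValueError("baf_coverage must be >= 1 (math.inf for noise-free)")
        if not 0.0 <= self.fraction_shared <= 1.0:
            raise ValueError("fraction_shared must lie in [0, 1]")
        if self.clone_proportions is not None:
            u = np.asarray(self.clone_proportions, dtype=float)
            if u.shape != (self.n_samples, self.n_clones) or np.any(u < 0):
                raise ValueError("clone_proportions must be (m, n_clones) nonnegative")
            if not np.allclose(u.sum(axis=1), self.purities):
                raise ValueError("clone proportions of sample p must sum to purity p")
            object.__setattr__(self, "clone_proportions", u)

    @property
    def total_bins(self) -> int:
        return self.n_chromosomes * self.bins_per_chromosome

    def proportions(self) -> np.ndarray:
        """(m, n_clones) tumor-clone proportions; row p sums to purity p.

        The default tilts sample p toward clone (p mod n_clones) so distinct
        clones dominate distinct samples and the samples are jointly
        informative about the clone structure.
        """
        if self.clone_proportions is not None:
            return self.clone_proportions
        u = np.empty((self.n_samples, self.n_clones))
        for p, mu in enumerate(self.purities):
            w = np.ones(self.n_clones)
            w[p % self.n_clones] = self.n_clones
            u[p] = mu * w / w.sum()
        return u


@dataclass
class GroundTruth:
    """Planted clone profiles and the segment structure they live on."""

    segment_of_bin: np.ndarray  # (n,) segment index per bin
    a: np.ndarray  # (n_clones, n_segments) major copies
    b: np.ndarray  # (n_clones, n_segments) minor copies
    boundaries: list[tuple[int, int]] = field(default_factory=list)  # bin ranges

    def labels(self) -> np.ndarray:
        """Ground-truth cluster per bin: segments with identical clone-state
        tuples share a label (numbered by first appearance)."""
        tuples = [tuple(zip(self.a[:, s], self.b[:, s])) for s in range(self.a.shape[1])]
        seen: dict[tuple, int] = {}
        seg_label = np.empty(len(tuples), dtype=np.int64)
        for s, t in enumerate(tuples):
            seg_label[s] = seen.setdefault(t, len(seen))
        return seg_label[self.segment_of_bin]

    def clone_states(self, clone: int, segment: int) -> CopyState:
        return CopyState(int(self.a[clone, segment]), int(self.b[clone, segment]))


def plant_profiles(config: SimulationConfig) -> GroundTruth:
    """Partition the genome into contiguous segments and draw clone states.

    Segments never cross chromosome boundaries.  Each segment is either
    shared (all clones get one common state, probability fraction_shared)
    or clone-specific (independent states per clone).  States are drawn
    uniformly from {(a, b): a >= b >= 0, 1 <= a + b <= max_total} — the
    all-zero state is excluded so every clone retains DNA everywhere.
    """
    rng = np.random.default_rng([config.seed, 0])
    per_chrom = np.full(config.n_chromosomes, config.n_segments // config.n_chromosomes)
    per_chrom[: config.n_segments % config.n_chromosomes] += 1
    if np.any(per_chrom > config.bins_per_chromosome):
        raise ValueError("more segments than bins on a chromosome")
    segment_of_bin = np.empty(config.total_bins, dtype=np.int64)
    boundaries: list[tuple[int, int]] = []
    seg = 0
    offset = 0
    for s_count in per_chrom:
        cuts = rng.choice(config.bins_per_chromosome - 1, size=s_count - 1, replace=False)
        edges = np.concatenate([[0], np.sort(cuts) + 1, [config.bins_per_chromosome]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            segment_of_bin[offset + lo : offset + hi] = seg
            boundaries.append((offset + int(lo), offset + int(hi)))
            seg += 1
        offset += config.bins_per_chromosome
    states = [s for s in enumerate_states(config.max_total) if s.total >= 1]
    a = np.empty((config.n_clones, config.n_segments), dtype=np.int64)
    b = np.empty_like(a)
    for s in range(config.n_segments):
        if rng.random() < config.fraction_shared:
            st = states[rng.integers(len(states))]
            a[:, s], b[:, s] = st.a, st.b
        else:
            for c in range(config.n_clones):
                st = states[rng.integers(len(states))]
                a[c, s], b[c, s] = st.a, st.b
    return GroundTruth(segment_of_bin=segment_of_bin, a=a, b=b, boundaries=boundaries)


def expected_signals(truth: GroundTruth, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (n, m) expected RDR and mirrored BAF matrices."""
    u = config.proportions()  # (m, n_clones)
    total = (truth.a + truth.b)[:, truth.segment_of_bin]  # (n_clones, n)
    minor = truth.b[:, truth.segment_of_bin]
    rho = total.mean(axis=1)  # bin-weighted clone ploidies
    m = config.n_samples
    n = config.total_bins
    e_rdr = np.empty((n, m))
    e_baf = np.empty((n, m))
    for p in range(m):
        u_norm = 1.0 - config.purities[p]
        mass = u_norm * 2.0 + u[p] @ total  # (n,) DNA per bin
        e_rdr[:, p] = mass / (u_norm * 2.0 + float(u[p] @ rho))
        e_baf[:, p] = (u_norm * 1.0 + u[p] @ minor) / mass
    e_baf = np.minimum(e_baf, 1.0 - e_baf)
    return e_rdr, e_baf


def emit_observations(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[BinTable, np.ndarray]:
    """Draw a noisy BinTable from the planted profiles plus its truth labels.

    RDR = expectation + Gaussian noise (sd rdr_noise_sd, truncated at 0);
    BAF ~ Binomial(baf_coverage, expectation) / coverage, mirrored.  With
    rdr_noise_sd = 0 and infinite coverage the expectations are emitted
    exactly.
    """
    rng = np.random.default_rng([config.seed, 1])
    e_rdr, e_baf = expected_signals(truth, config)
    rdr = e_rdr.copy()
    if config.rdr_noise_sd > 0:
        rdr = np.clip(e_rdr + rng.normal(0.0, config.rdr_noise_sd, e_rdr.shape), 0.0, None)
    baf = e_baf.copy()
    if math.isfinite(config.baf_coverage):
        cov = int(config.baf_coverage)
        baf = rng.binomial(cov, e_baf) / cov
        baf = np.minimum(baf, 1.0 - baf)
    n = config.total_bins
    chrom = np.repeat(
        [f"chr{c + 1}" for c in range(config.n_chromosomes)], config.bins_per_chromosome
    ).astype(str)
    within = np.tile(np.arange(config.bins_per_chromosome), config.n_chromosomes)
    start = within * config.bin_width
    end = start + config.bin_width
    table = BinTable(
        chrom=chrom,
        start=start.astype(np.int64),
        end=end.astype(np.int64),
        samples=[f"sample{p + 1}" for p in range(config.n_samples)],
        rdr=rdr,
        baf=baf,
        cluster=np.full(n, UNCLUSTERED, dtype=np.int64),
    )
    table.validate()
    return table, truth.labels()


def simulate(config: SimulationConfig) -> tuple[BinTable, np.ndarray, GroundTruth]:
    """Plant profiles and emit one dataset in a single call."""
    truth = plant_profiles(config)
    table, labels = emit_observations(truth, config)
    return table, labels, truth


def simulate_to_files(config: SimulationConfig, out_dir) -> tuple[str, str]:
    """Write bins.tsv (dialect-valid, CLUSTER = -1) and truth.tsv to `out_dir`.

    truth.tsv maps each bin to its ground-truth label and the per-clone
    allele-specific states.  Outputs are byte-identical across runs with
    the same config.
    """
    os.makedirs(out_dir, exist_ok=True)
    table, labels, truth = simulate(config)
    bins_path = os.path.join(out_dir, "bins.tsv")
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_bin_table(table, bins_path)
    seg = truth.segment_of_bin
    data = {
        "CHR": table.chrom,
        "START": table.start,
        "END": table.end,
        "TRUTH": labels,
        "SEGMENT": seg,
    }
    for c in range(config.n_clones):
        data[f"clone{c + 1}_a"] = truth.a[c, seg]
        data[f"clone{c + 1}_b"] = truth.b[c, seg]
    pd.DataFrame(data).to_csv(truth_path, sep="\t", index=False)
    return bins_path, truth_path
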