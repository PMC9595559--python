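"""Domain types and I/O for binned tumor copy-number data.

The central container is :class:`BinTable`: ``n`` genomic bins observed in
``m`` samples, each bin carrying a read-depth ratio (RDR, proportional to
total copy number) and a B-allele frequency (BAF, measuring allelic
imbalance; mirrored onto [0, 0.5] on load), plus an integer cluster label
per bin.  Cluster IDs -1 ("not clustered") and -2 ("erased") are reserved.

The on-disk dialect is a TSV with header columns CHR, START, END, RD, BAF
and optionally CLUSTER and SAMPLE, one row per bin per sample, subject to
three ordering rules:

(1) all bins of one chromosome are grouped together and sorted by position;
(2) rows for the same genomic bin in different samples are adjacent;
(3) every bin is present in every sample.

Unknown columns are preserved verbatim and re-emitted on export; bins with
cluster -2 are dropped from exports.  Coordinates are 0-based,
inclusive-start / exclusive-end throughout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("CHR", "START", "END", "RD", "BAF")
RESERVED_COLUMNS = REQUIRED_COLUMNS + ("CLUSTER", "SAMPLE")

#: reserved cluster IDs
UNCLUSTERED = -1
ERASED = -2


class BinTableError(ValueError):
    """Malformed bin-table input (missing column, broken ordering rule...)."""


class DriverGeneError(ValueError):
    """Malformed driver-gene file."""


@dataclass(frozen=True, order=True)
class GenomicBin:
    """A genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.end > self.start >= 0:
            raise ValueError(f"invalid bin interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class DriverGene:
    """A named gene with its genomic location."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"invalid gene interval for {self.symbol}")


@dataclass(frozen=True)
class SegmentRecord:
    """A maximal run of consecutive same-cluster bins within one chromosome."""

    chrom: str
    start: int
    end: int
    cluster: int
    n_bins: int


@dataclass
class BinTable:
    """n bins x m samples of RDR/BAF values with one cluster label per bin.

    Attributes
    ----------
    chrom, start, end
        Length-n arrays of bin coordinates (0-based, half-open intervals).
    samples
        Ordered sample names (length m).
    rdr, baf
        (n, m) arrays; BAF is kept mirrored onto [0, 0.5].
    cluster
        Length-n integer labels, >= -2; -1 unclustered, -2 erased.
    extra
        Optional pass-through payload of any additional input columns, one
        row per bin per sample in bin-major order (n*m rows).
    columns
        Header order of the source file, used to write exports in the same
        column order.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    samples: list[str]
    rdr: np.ndarray
    baf: np.ndarray
    cluster: np.ndarray
    extra: pd.DataFrame | None = None
    columns: list[str] | None = None
    had_sample_column: bool = False

    @property
    def n(self) -> int:
        return len(self.chrom)

    @property
    def m(self) -> int:
        return len(self.samples)

    def bins(self) -> list[GenomicBin]:
        return [
            GenomicBin(c, int(s), int(e))
            for c, s, e in zip(self.chrom, self.start, self.end)
        ]

    def copy(self) -> "BinTable":
        return replace(
            self,
            chrom=self.chrom.copy(),
            start=self.start.copy(),
            end=self.end.copy(),
            samples=list(self.samples),
            rdr=self.rdr.copy(),
            baf=self.baf.copy(),
            cluster=self.cluster.copy(),
            extra=None if self.extra is None else self.extra.copy(),
            columns=None if self.columns is None else list(self.columns),
        )

    def validate(self) -> None:
        """Re-assert all structural invariants; raise BinTableError on failure."""
        n, m = self.n, self.m
        if not (len(self.start) == len(self.end) == len(self.cluster) == n):
            raise BinTableError("coordinate/cluster arrays have inconsistent lengths")
        if self.rdr.shape != (n, m) or self.baf.shape != (n, m):
            raise BinTableError("rdr/baf matrices must have shape (n, m)")
        if np.any(self.end <= self.start):
            raise BinTableError("every bin must satisfy end > start")
        if np.any(self.rdr < 0):
            raise BinTableError("RDR values must be nonnegative")
        if np.any((self.baf < 0) | (self.baf > 0.5)):
            raise BinTableError("BAF values must lie in [0, 0.5] after mirroring")
        if np.any(self.cluster < ERASED):
            raise BinTableError("cluster IDs must be >= -2")
        # rule (1): chromosomes contiguous, sorted by start within each
        seen: set[str] = set()
        prev_chrom: str | None = None
        for i in range(n):
            c = self.chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise BinTableError(
                        f"ordering rule (1) violated: chromosome {c!r} occurs in "
                        f"multiple blocks (row for bin index {i})"
                    )
                seen.add(c)
                prev_chrom = c
            elif self.start[i] <= self.start[i - 1]:
                raise BinTableError(
                    f"ordering rule (1) violated: bins of chromosome {c!r} are not "
                    f"sorted by genomic position (bin index {i})"
                )
        triples = set(zip(self.chrom.tolist(), self.start.tolist(), self.end.tolist()))
        if len(triples) != n:
            raise BinTableError("duplicate (CHR, START, END) triple")
        if np.any(~np.isfinite(self.rdr)) or np.any(~np.isfinite(self.baf)):
            raise BinTableError("RDR/BAF must be finite")


def _position_groups(df: pd.DataFrame) -> np.ndarray:
    """Codes identifying runs of identical (CHR, START, END) triples, checking rule (2)."""
    key = df["CHR"].astype(str) + ":" + df["START"].astype(str) + "-" + df["END"].astype(str)
    codes, _ = pd.factorize(key)
    # rule (2): occurrences of each triple must form a single contiguous run
    change = np.flatnonzero(np.diff(codes) != 0)
    run_starts = np.concatenate([[0], change + 1])
    run_codes = codes[run_starts]
    if len(np.unique(run_codes)) != len(run_codes):
        dup = run_codes[pd.Series(run_codes).duplicated().to_numpy()][0]
        row = int(np.flatnonzero(codes == dup)[0])
        raise BinTableError(
            f"ordering rule (2) violated: rows for bin {key.iloc[row]!r} are not "
            f"grouped together (first at input row {row})"
        )
    return codes


def read_bin_table(path) -> BinTable:
    """Read and validate a bin TSV.

    When the CLUSTER column is absent every bin is marked unclustered (-1).
    BAF values above 0.5 are mirrored to 1 - BAF.  A SAMPLE column names the
    samples; without one, samples are inferred from the repeat count per
    genomic position and numbered by within-position row order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SAMPLE": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise BinTableError(f"missing required column {col!r}")
    if len(df) == 0:
        raise BinTableError("empty bin table")
    for col in ("RD", "BAF"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise BinTableError(f"non-numeric value in column {col!r}: {exc}") from None
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise BinTableError(f"missing {col} value at input row {row}")
    for col in ("START", "END"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise BinTableError(f"non-integer value in column {col!r}: {exc}") from None

    codes = _position_groups(df)
    n_groups = int(codes.max()) + 1

    # sample identification (rule 3: every bin present in every sample)
    counts = np.bincount(codes, minlength=n_groups)
    if "SAMPLE" in df.columns:
        samples = list(pd.unique(df["SAMPLE"]))
        m = len(samples)
        sample_idx = df["SAMPLE"].map({s: i for i, s in enumerate(samples)}).to_numpy()
        had_sample = True
    else:
        m = int(counts[0])
        if np.any(counts != m):
            bad = int(np.argmax(counts != m))
            raise BinTableError(
                f"ordering rule (3) violated: bin group {bad} has {counts[bad]} rows "
                f"but the first bin has {m} (every bin must be present in every sample)"
            )
        samples = [f"sample{i + 1}" for i in range(m)] if m > 1 else ["sample1"]
        # within-position row order assigns the sample index
        sample_idx = np.empty(len(df), dtype=np.int64)
        for g in range(n_groups):
            rows = np.flatnonzero(codes == g)
            sample_idx[rows] = np.arange(len(rows))
        had_sample = False
    if np.any(counts != m):
        bad = int(np.argmax(counts != m))
        raise BinTableError(
            f"ordering rule (3) violated: bin group {bad} has {counts[bad]} rows, "
            f"expected one per sample ({m} samples)"
        )
    # each (bin, sample) pair exactly once
    pair_seen = np.full((n_groups, m), False)
    for row, (g, s) in enumerate(zip(codes, sample_idx)):
        if pair_seen[g, s]:
            raise BinTableError(
                f"ordering rule (3) violated: duplicate row for one bin/sample "
                f"pair at input row {row}"
            )
        pair_seen[g, s] = True

    first_rows = np.full(n_groups, -1, dtype=np.int64)
    for row, g in enumerate(codes):
        if first_rows[g] < 0:
            first_rows[g] = row
    chrom = df["CHR"].to_numpy(dtype=object)[first_rows].astype(str)
    start = df["START"].to_numpy()[first_rows]
    end = df["END"].to_numpy()[first_rows]

    rdr = np.empty((n_groups, m))
    baf = np.empty((n_groups, m))
    rdr[codes, sample_idx] = df["RD"].to_numpy()
    baf[codes, sample_idx] = df["BAF"].to_numpy()
    if np.any(rdr < 0):
        raise BinTableError("RDR values must be nonnegative")
    if np.any((baf < 0) | (baf > 1)):
        raise BinTableError("BAF values must lie in [0, 1]")
    baf = np.minimum(baf, 1.0 - baf)

    if "CLUSTER" in df.columns:
        try:
            clu_rows = pd.to_numeric(df["CLUSTER"], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise BinTableError(f"non-integer CLUSTER value: {exc}") from None
        per_bin = np.full((n_groups, m), 0, dtype=np.int64)
        per_bin[codes, sample_idx] = clu_rows.to_numpy()
        if np.any(per_bin != per_bin[:, :1]):
            bad = int(np.argmax(np.any(per_bin != per_bin[:, :1], axis=1)))
            raise BinTableError(
                f"inconsistent CLUSTER labels across samples for bin index {bad}"
            )
        cluster = per_bin[:, 0]
        if np.any(cluster < ERASED):
            raise BinTableError("cluster IDs must be >= -2")
    else:
        cluster = np.full(n_groups, UNCLUSTERED, dtype=np.int64)

    extra_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    extra = None
    if extra_cols:
        # canonical bin-major, sample-order row layout
        order = np.lexsort((sample_idx, codes))
        extra = df.loc[:, extra_cols].iloc[order].reset_index(drop=True)

    table = BinTable(
        chrom=chrom,
        start=start,
        end=end,
        samples=samples,
        rdr=rdr,
        baf=baf,
        cluster=cluster.astype(np.int64),
        extra=extra,
        columns=list(df.columns),
        had_sample_column=had_sample,
    )
    table.validate()
    return table


def write_bin_table(table: BinTable, path) -> None:
    """Write a bin TSV in the input dialect, omitting erased (cluster -2) bins.

    Extra columns are re-emitted unchanged; CLUSTER is always written so the
    export specifies the clustering.
    """
    table.validate()
    keep = table.cluster != ERASED
    n_keep = int(keep.sum())
    m = table.m
    bin_idx = np.repeat(np.flatnonzero(keep), m)
    sample_idx = np.tile(np.arange(m), n_keep)
    out = pd.DataFrame(
        {
            "CHR": table.chrom[bin_idx],
            "START": table.start[bin_idx],
            "END": table.end[bin_idx],
            "RD": table.rdr[bin_idx, sample_idx],
            "BAF": table.baf[bin_idx, sample_idx],
            "CLUSTER": table.cluster[bin_idx],
        }
    )
    if table.m > 1 or table.had_sample_column:
        out["SAMPLE"] = [table.samples[s] for s in sample_idx]
    if table.extra is not None:
        rows = bin_idx * m + sample_idx
        for col in table.extra.columns:
            out[col] = table.extra[col].to_numpy()[rows]
    # preserve source column order where known
    ordered = [c for c in (table.columns or []) if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    out = out.loc[:, ordered]
    out.to_csv(path, sep="\t", index=False)


_LOCATION_RE = re.compile(r"^\s*([^:\s]+):(\d+)-(\d+)\s*$")


def read_driver_genes(path) -> list[DriverGene]:
    """Parse a driver-gene TSV with columns 'symbol' and 'Genome Location'.

    The location column has the form '{CHR}:{START}-{END}'.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("symbol", "Genome Location"):
        if col not in df.columns:
            raise DriverGeneError(f"missing required column {col!r}")
    genes = []
    for row, (symbol, loc) in enumerate(zip(df["symbol"], df["Genome Location"])):
        match = _LOCATION_RE.match(str(loc))
        if match is None:
            raise DriverGeneError(
                f"malformed Genome Location {loc!r} at row {row} (expected CHR:START-END)"
            )
        chrom, s, e = match.group(1), int(match.group(2)), int(match.group(3))
        if e <= s:
            raise DriverGeneError(f"empty interval {loc!r} at row {row}")
        genes.append(DriverGene(symbol=str(symbol), chrom=chrom, start=s, end=e))
    return genes


def bins_overlapping(table: BinTable, chrom: str, start: int, end: int) -> np.ndarray:
    """Indices of bins intersecting [start, end) on `chrom` (half-open)."""
    if not start < end:
        raise ValueError("query interval must satisfy start < end")
    mask = (table.chrom == chrom) & (table.start < end) & (table.end > start)
    return np.flatnonzero(mask)


def segments_from_clustering(table: BinTable) -> list[SegmentRecord]:
    """Collapse maximal runs of consecutive same-cluster bins into segments.

    Runs never cross chromosome boundaries; concatenating segment bin counts
    recovers n.
    """
    segments: list[SegmentRecord] = []
    n = table.n
    i = 0
    while i < n:
        j = i
        while (
            j + 1 < n
            and table.chrom[j + 1] == table.chrom[i]
            and table.cluster[j + 1] == table.cluster[i]
        ):
            j += 1
        segments.append(
            SegmentRecord(
                chrom=str(table.chrom[i]),
                start=int(table.start[i]),
                end=int(table.end[j]),
                cluster=int(table.cluster[i]),
                n_bins=j - i + 1,
            )
        )
        i = j + 1
    return segments


def write_segments(segments: list[SegmentRecord], path) -> None:
    """Export segments as a BED-like TSV (CHR, START, END, CLUSTER, N_BINS)."""
    pd.DataFrame(
        {
            "CHR": [s.chrom for s in segments],
            "START": [s.start for s in segments],
            "END": [s.end for s in segments],
            "CLUSTER": [s.cluster for s in segments],
            "N_BINS": [s.n_bins for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)
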