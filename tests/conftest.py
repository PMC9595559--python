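import numpy as np
import pytest

from cnaseg import BinTable


def make_table(rdr, baf, cluster=None, chrom=None, samples=None):
    """Build a small valid BinTable from (n, m) arrays with synthetic coords."""
    rdr = np.atleast_2d(np.asarray(rdr, dtype=float))
    baf = np.atleast_2d(np.asarray(baf, dtype=float))
    n, m = rdr.shape
    if chrom is None:
        chrom = np.array(["chr1"] * n)
    else:
        chrom = np.asarray(chrom, dtype=str)
    starts = np.zeros(n, dtype=np.int64)
    pos = {}
    for i, c in enumerate(chrom):
        starts[i] = pos.get(c, 0)
        pos[c] = starts[i] + 100
    table = BinTable(
        chrom=chrom,
        start=starts,
        end=starts + 100,
        samples=samples or [f"sample{p + 1}" for p in range(m)],
        rdr=rdr,
        baf=baf,
        cluster=(
            np.full(n, -1, dtype=np.int64)
            if cluster is None
            else np.asarray(cluster, dtype=np.int64)
        ),
    )
    table.validate()
    return table


@pytest.fixture
def two_sample_tsv(tmp_path):
    """A 3-bin, 2-sample dialect file with CLUSTER and an extra GC column."""
    path = tmp_path / "bins.tsv"
    rows = [
        "CHR\tSTART\tEND\tSAMPLE\tRD\tBAF\tCLUSTER\tGC",
        "chr1\t0\t100\ts1\t1.0\t0.5\t0\t0.41",
        "chr1\t0\t100\ts2\t1.1\t0.48\t0\t0.41",
        "chr1\t100\t200\ts1\t1.5\t0.33\t1\t0.43",
        "chr1\t100\t200\ts2\t1.4\t0.35\t1\t0.43",
        "chr2\t0\t100\ts1\t0.7\t0.2\t0\t0.39",
        "chr2\t0\t100\ts2\t0.8\t0.22\t0\t0.39",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path
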