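import numpy as np
import pandas as pd
import pytest

import chromarch as ca


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One small simulated two-condition genome shared across tests."""
    cfg = ca.SimConfig(n_chroms=1, chrom_length=4_000_000, n_loops=4000,
                       n_genes=400, n_peaks=400, n_diff_loops=20,
                       read_depth=2e5, seed=11)
    outdir = tmp_path_factory.mktemp("simgenome")
    paths, truth = ca.simulate_genome(cfg, outdir)
    return cfg, paths, truth


def make_loopset(rows, condition="a", tvp=None):
    """LoopSet from (chrom1,s1,e1,chrom2,s2,e2,score,q) tuples."""
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                     "chrom2", "start2", "end2", "score", "q"])
    df["name"] = [f"l{i}" for i in range(len(df))]
    df["pets"] = df["score"]
    return ca.LoopSet(df, condition=condition, total_valid_pairs=tvp)


def random_genome_fixture(rng, max_len=10_000, bin_width=1000):
    """A tiny random genome with scored and unscored intervals, for
    cross-checking the binning machinery against per-bp oracles."""
    n_chrom = rng.integers(1, 3)
    sizes = {f"c{i}": int(rng.integers(2 * bin_width, max_len))
             for i in range(n_chrom)}
    intervals = []
    for chrom, size in sizes.items():
        for _ in range(int(rng.integers(0, 8))):
            s = int(rng.integers(0, size - 1))
            e = int(rng.integers(s + 1, size + 1))
            intervals.append((chrom, s, e, float(rng.integers(1, 10))))
    ivals = pd.DataFrame(intervals, columns=["chrom", "start", "end", "score"])
    return sizes, ivals
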