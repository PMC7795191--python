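"""Hierarchical grid assignment, paired-t testing, rendering, networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import chromarch as ca
from chromarch.differential_interactions import GridCells, _network_metrics

from conftest import make_loopset


def test_grid_geometry_and_assignment():
    with pytest.raises(ValueError):
        ca.hierarchical_grid(make_loopset([]), fine=300, coarse=1000)

    empty = ca.hierarchical_grid(make_loopset([]), fine=100_000, coarse=1_000_000)
    assert empty.cells == {}
    assert empty.ratio == 10

    # one loop with anchor midpoints at 150 kb and 1,250 kb: exactly one
    # fine pair non-zero, in the (0, 1) coarse cell, full 100-value vector
    loops = make_loopset([("chr1", 145_000, 155_000, "chr1", 1_245_000, 1_255_000, 5.0, 0.0)])
    grid = ca.hierarchical_grid(loops, fine=100_000, coarse=1_000_000)
    assert list(grid.cells) == [("chr1", "chr1", 0, 1)]
    vec = grid.cells[("chr1", "chr1", 0, 1)]
    assert len(vec) == 100
    assert (vec > 0).sum() == 1 and vec.sum() == 5.0
    # fine pair (1, 12) -> local (1, 2) -> flat 1*10+2
    assert vec[12] == 5.0


def test_grid_exhaustive_assignment_oracle():
    """Every loop lands in exactly the cell/slot its midpoints dictate."""
    rng = np.random.default_rng(3)
    rows = []
    for _ in range(50):
        m1 = int(rng.integers(0, 3_000_000))
        m2 = int(rng.integers(0, 3_000_000))
        rows.append(("chr1", m1 - 500, m1 + 500, "chr1", m2 - 500 if m2 >= 500 else 0,
                     m2 + 500, float(rng.integers(1, 9)), 0.0))
    rows = [r for r in rows if r[1] >= 0]
    loops = make_loopset(rows)
    grid = ca.hierarchical_grid(loops, fine=100_000, coarse=1_000_000)
    total = sum(v.sum() for v in grid.cells.values())
    assert total == sum(r[6] for r in rows)
    for r in rows:
        i = ((r[1] + r[2]) // 2) // 100_000
        j = ((r[4] + r[5]) // 2) // 100_000
        i, j = min(i, j), max(i, j)
        key = ("chr1", "chr1", i // 10, j // 10)
        assert key in grid.cells


def _cells(vectors, fine=100_000, coarse=200_000, condition=""):
    g = GridCells(fine=fine, coarse=coarse, condition=condition)
    for k, v in vectors.items():
        g.cells[k] = np.asarray(v, dtype=float)
    return g


def test_paired_t_known_cell():
    a = _cells({("chr1", "chr1", 0, 1): [1, 2, 3, 4]})
    b = _cells({("chr1", "chr1", 0, 1): [3, 3, 5, 6]})
    res = ca.paired_t_grid(a, b)
    row = res.iloc[0]
    assert row["t"] == pytest.approx(7.0)
    assert row["df"] == 3
    assert row["p"] == pytest.approx(2 * stats.t.sf(7.0, 3))
    assert row["p"] == pytest.approx(0.0060, abs=2e-5)
    assert row["mean_delta"] == pytest.approx(1.75)

    same = ca.paired_t_grid(a, a)
    assert (same["p"] == 1.0).all() and (same["mean_delta"] == 0).all()

    swapped = ca.paired_t_grid(b, a)
    assert swapped.iloc[0]["t"] == pytest.approx(-7.0)
    assert swapped.iloc[0]["p"] == pytest.approx(row["p"])


def test_paired_t_matches_closed_form_oracle():
    rng = np.random.default_rng(9)
    va = {("chr1", "chr1", k, k + 1): rng.poisson(6.0, 25) for k in range(200)}
    vb = {("chr1", "chr1", k, k + 1): rng.poisson(6.0, 25) for k in range(200)}
    res = ca.paired_t_grid(_cells(va), _cells(vb))
    for row in res.itertuples():
        key = (row.chrom1, row.chrom2, row.I, row.J)
        t, p = stats.ttest_rel(vb[key], va[key])
        if np.isnan(t):
            assert row.p == 1.0
        else:
            assert abs(row.t - t) <= 1e-9 * max(abs(t), 1)
            assert abs(row.p - p) <= 1e-9


def test_paired_t_geometry_mismatch():
    a = _cells({("chr1", "chr1", 0, 1): [1, 2]})
    b = GridCells(fine=50_000, coarse=200_000)
    with pytest.raises(ValueError):
        ca.paired_t_grid(a, b)


def test_differential_loops_rendering_rules():
    # cells (0,4) and (1,3) share the loop midpoint at 500 kb
    a = _cells({("chr1", "chr1", 0, 4): [1.0, 1, 1, 1],
                ("chr1", "chr1", 1, 3): [1.0, 1, 1, 1],
                ("chr1", "chr1", 0, 2): [1.0, 1, 1, 1]}, condition="esc")
    b = _cells({("chr1", "chr1", 0, 4): [4.0, 4, 4, 4],
                ("chr1", "chr1", 1, 3): [2.0, 2, 2, 2],
                ("chr1", "chr1", 0, 2): [3.0, 3, 3, 3]}, condition="ncc")
    res = ca.paired_t_grid(a, b, bonferroni=True)
    fav_b = ca.differential_loops(res, "ncc")
    assert len(fav_b) == 3
    shared = fav_b[fav_b["midpoint"] == 500_000]
    assert len(shared) == 2
    annotated = shared[shared["annotated"]]
    # the statistic is annotated only on the strongest-delta cell per midpoint
    assert len(annotated) == 1
    assert annotated.iloc[0]["I"] == 0 and annotated.iloc[0]["J"] == 4
    fav_a = ca.differential_loops(res, "esc")
    assert len(fav_a) == 0

    with pytest.raises(ValueError):
        ca.differential_loops(res, "ncc", require_context=True)
    # truncation removes cells reaching past the alignment window
    trunc = ca.differential_loops(res, "ncc", truncate_to=(0, 600_000))
    assert len(trunc) == 1
    assert trunc.iloc[0]["J"] == 2

    # no differences at all: both lists empty
    none = ca.paired_t_grid(a, a)
    assert len(ca.differential_loops(none, "ncc")) == 0
    assert len(ca.differential_loops(none, "esc")) == 0


def test_planted_differential_loop_appears_only_in_favored_list(small_dataset):
    cfg, paths, truth = small_dataset
    la = ca.LoopSet.read_bedpe(paths["loops_hic_esc"], condition="esc")
    lb = ca.LoopSet.read_bedpe(paths["loops_hic_ncc"], condition="ncc")
    ga = ca.hierarchical_grid(la, fine=10_000, coarse=100_000)
    gb = ca.hierarchical_grid(lb, fine=10_000, coarse=100_000)
    res = ca.paired_t_grid(ga, gb)
    fav = {"esc": ca.differential_loops(res, "esc"),
           "ncc": ca.differential_loops(res, "ncc")}
    ok = 0
    for loop, favored, _ in truth.diff_loops:
        m = (loop["start1"] + loop["end1"] + loop["start2"] + loop["end2"]) // 4
        other = "ncc" if favored == "esc" else "esc"
        in_fav = (fav[favored]["midpoint"].sub(m).abs() < 100_000).any()
        ok += int(in_fav)
    assert ok >= 0.8 * len(truth.diff_loops)


def test_network_metrics_small_graphs():
    # star K1,4: center degree 4, no triangles
    star = [(0, i) for i in range(1, 5)]
    deg, cc = _network_metrics(star)
    assert deg[0] == 4 and all(deg[i] == 1 for i in range(1, 5))
    assert all(v == 0.0 for v in cc.values())
    # triangle: all degrees 2, all clustering 1
    deg, cc = _network_metrics([(0, 1), (1, 2), (0, 2)])
    assert all(deg[n] == 2 for n in deg)
    assert all(v == 1.0 for v in cc.values())


def test_network_metrics_match_networkx_oracle():
    nx = pytest.importorskip("networkx")
    g = nx.erdos_renyi_graph(50, 0.2, seed=4)
    deg, cc = _network_metrics(list(g.edges()))
    nx_cc = nx.clustering(g)
    for n in g.nodes():
        assert deg.get(n, 0) == g.degree(n) or g.degree(n) == 0
        if g.degree(n) > 0:
            assert cc[n] == pytest.approx(nx_cc[n])


def test_top_n_network_ranking_and_clamp():
    cells = _cells({("chr1", "chr1", 0, 1): [4.0, 4],
                    ("chr1", "chr1", 0, 2): [2.0, 2],
                    ("chr1", "chr1", 1, 2): [1.0, 1]}, condition="ncc")
    zeros = _cells({k: np.zeros(2) for k in cells.cells}, condition="esc")
    res = ca.paired_t_grid(zeros, cells)
    net = ca.top_n_network(res, cells, "ncc", n=2)
    assert len(net.edges) == 2
    assert net.degree[("chr1", 0)] == 2
    with pytest.warns(UserWarning):
        ca.top_n_network(res, cells, "ncc", n=10)
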