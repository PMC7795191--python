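"""Hierarchical binned paired-t differential interaction testing and networks.

Loop scores are accumulated onto a fine grid (100 kb genome-wide, 1 kb at
locus scale) by the midpoints of their two anchors; fine pairs are grouped
into coarse cells (1 mb, or 10 kb at locus scale), and each coarse cell is
compared between the two conditions with a paired t-test over its matched
fine-pair value vectors. A full off-diagonal coarse cell holds
(coarse/fine)^2 fine pairs — e.g. 100 values from 100 kb combinations inside
every 1 mb x 1 mb cell; diagonal cells hold the upper-triangle pairs so no
mirrored fine pair is counted twice.

Bonferroni correction is optional: genome-wide scans (millions of cells)
default to uncorrected p with glyph scaling left to the caller, while
locus-scale and border-aligned analyses default to Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_binning import LoopSet


@dataclass
class GridCells:
    """Coarse cells, each holding the accumulated fine-pair value vector.

    Keys are (chrom1, chrom2, I, J) with coarse bin indices I <= J for
    intra-chromosomal cells; values are 1-D float arrays of fixed per-key
    geometry.
    """

    fine: int
    coarse: int
    condition: str = ""
    origin: int = 0
    cells: dict = field(default_factory=dict)

    @property
    def ratio(self) -> int:
        return self.coarse // self.fine

    def vector_length(self, key) -> int:
        c1, c2, i, j = key
        r = self.ratio
        if c1 == c2 and i == j:
            return r * (r + 1) // 2
        return r * r

    def cell_center(self, key) -> tuple:
        """Genomic centers (bp) of the two coarse regions of a cell."""
        _, _, i, j = key
        half = self.coarse // 2
        return (self.origin + i * self.coarse + half,
                self.origin + j * self.coarse + half)


def _flat_index(a: int, b: int, r: int, diagonal: bool) -> int:
    if not diagonal:
        return a * r + b
    # upper triangle (a <= b) packed row-wise
    return a * r - a * (a - 1) // 2 + (b - a)


def hierarchical_grid(loops: LoopSet, fine: int, coarse: int,
                      scope: str = "intra",
                      region: tuple | None = None) -> GridCells:
    """Assign each loop to one fine pair inside one coarse cell.

    A loop lands in the fine bins containing its two anchor midpoints
    (unambiguous single assignment). ``region=(chrom, start, end)`` restricts
    to a locus and makes bin indices relative to ``start``.
    """
    if coarse % fine != 0:
        raise ValueError("coarse must be an integer multiple of fine")
    grid = GridCells(fine=fine, coarse=coarse, condition=loops.condition,
                     origin=region[1] if region else 0)
    r = grid.ratio
    df = loops.df
    if scope == "inter":
        df = df[df["chrom1"] != df["chrom2"]]
    elif scope in ("intra", "region"):
        df = df[df["chrom1"] == df["chrom2"]]
    if region is not None:
        chrom, lo, hi = region
        m1 = (df["start1"] + df["end1"]) // 2
        m2 = (df["start2"] + df["end2"]) // 2
        df = df[(df["chrom1"] == chrom) & (df["chrom2"] == chrom)
                & (m1 >= lo) & (m1 < hi) & (m2 >= lo) & (m2 < hi)]
    origin = grid.origin
    for c1, s1, e1, c2, s2, e2, score in zip(
        df["chrom1"], df["start1"], df["end1"],
        df["chrom2"], df["start2"], df["end2"], df["score"]
    ):
        m1 = (int(s1) + int(e1)) // 2 - origin
        m2 = (int(s2) + int(e2)) // 2 - origin
        i, j = m1 // fine, m2 // fine
        if c1 == c2 and i > j:
            i, j = j, i
        elif (c2, j) < (c1, i):
            (c1, i), (c2, j) = (c2, j), (c1, i)
        I, J = i // r, j // r
        key = (c1, c2, I, J)
        diagonal = c1 == c2 and I == J
        a, b = i - I * r, j - J * r
        if key not in grid.cells:
            grid.cells[key] = np.zeros(grid.vector_length(key))
        grid.cells[key][_flat_index(a, b, r, diagonal)] += score
    return grid


def paired_t_grid(cells_a: GridCells, cells_b: GridCells,
                  bonferroni: bool = False) -> pd.DataFrame:
    """Paired t-test per coarse cell over the matched fine-pair vectors.

    mean_delta is condition B minus condition A; a cell whose differences
    are all zero is reported with p = 1, a cell with identical non-zero
    differences is flagged degenerate with p = 0.
    """
    if (cells_a.fine, cells_a.coarse) != (cells_b.fine, cells_b.coarse):
        raise ValueError("grids have mismatched geometry")
    keys = sorted(set(cells_a.cells) | set(cells_b.cells))
    n_tests = len(keys)
    rows = []
    for key in keys:
        va = cells_a.cells.get(key)
        vb = cells_b.cells.get(key)
        if va is None:
            va = np.zeros(len(vb) if vb is not None else cells_a.vector_length(key))
        if vb is None:
            vb = np.zeros(len(va))
        if len(va) != len(vb):
            raise ValueError("cell vector length mismatch")
        n = len(va)
        d = vb - va
        md = d.mean()
        degenerate = False
        if n < 2:
            t, p = np.nan, 1.0
        else:
            sd = d.std(ddof=1)
            if sd == 0:
                if md == 0:
                    t, p = 0.0, 1.0
                else:
                    t, p = np.sign(md) * np.inf, 0.0
                    degenerate = True
            else:
                t = md / (sd / np.sqrt(n))
                p = 2.0 * stats.t.sf(abs(t), n - 1)
        p_adj = min(1.0, p * n_tests) if bonferroni else p
        ca, cb = cells_a.cell_center(key)
        rows.append({
            "chrom1": key[0], "chrom2": key[1], "I": key[2], "J": key[3],
            "center1": ca, "center2": cb, "n": n, "mean_delta": md,
            "t": t, "df": n - 1, "p": p, "p_adj": p_adj,
            "favored": (cells_b.condition or "B") if md > 0
                       else (cells_a.condition or "A") if md < 0 else "",
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def differential_loops(results: pd.DataFrame, favored: str,
                       truncate_to: tuple | None = None,
                       require_context: bool = False) -> pd.DataFrame:
    """Condition-favored differential loop list with per-midpoint statistics.

    Keeps cells whose delta favors ``favored`` (positive delta for that
    condition). The test statistic is annotated only on the strongest-|delta|
    cell per loop midpoint (``annotated`` column). When ``truncate_to=(lo,
    hi)`` is given (the aligned-border window bounded by the TAD midpoint),
    loops reaching past it are removed.
    """
    if require_context and truncate_to is None:
        raise ValueError("midpoint truncation requested without an alignment context")
    res = results[results["favored"] == favored].copy()
    if truncate_to is not None:
        lo, hi = truncate_to
        res = res[(res["center1"] >= lo) & (res["center1"] < hi)
                  & (res["center2"] >= lo) & (res["center2"] < hi)]
    res["midpoint"] = (res["center1"] + res["center2"]) // 2
    res["delta_mag"] = res["mean_delta"].abs()
    res = res.sort_values(["midpoint", "delta_mag"],
                          ascending=[True, False]).reset_index(drop=True)
    res["annotated"] = ~res.duplicated("midpoint", keep="first")
    return res.drop(columns="delta_mag")


@dataclass
class InteractionNetwork:
    """Undirected simple graph over coarse bins with per-node metrics."""

    edges: pd.DataFrame            # node_a, node_b, weight
    degree: dict
    clustering: dict

    @property
    def mean_clustering(self) -> float:
        return float(np.mean(list(self.clustering.values()))) if self.clustering else 0.0


def _network_metrics(edges: list) -> tuple[dict, dict]:
    nodes = sorted({u for u, v in edges} | {v for u, v in edges})
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    adj = np.zeros((m, m), dtype=bool)
    for u, v in edges:
        if u == v:
            continue
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = True
    k = adj.sum(axis=1)
    a = adj.astype(float)
    triangles = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(k >= 2, 2.0 * triangles / (k * (k - 1.0)), 0.0)
    degree = {n: int(k[idx[n]]) for n in nodes}
    clustering = {n: float(cc[idx[n]]) for n in nodes}
    return degree, clustering


def top_n_network(results: pd.DataFrame, cells: GridCells, favored: str,
                  n: int = 5000, max_mean_strength: float | None = None,
                  percentile: float | None = None) -> InteractionNetwork:
    """Network over the top-n condition-favored coarse cells.

    Cells are ranked by the mean fine-pair strength of the favored condition
    (ties broken by coordinates); optional filters drop cells above a mean
    strength ceiling or below a retention percentile. Degree and local
    clustering coefficient (triangles over possible triangles) are computed
    internally from the adjacency matrix.
    """
    res = results[results["favored"] == favored].copy()
    strengths = []
    for key in zip(res["chrom1"], res["chrom2"], res["I"], res["J"]):
        vec = cells.cells.get(tuple(key))
        strengths.append(float(np.mean(vec)) if vec is not None else 0.0)
    res["strength"] = strengths
    if max_mean_strength is not None:
        res = res[res["strength"] <= max_mean_strength]
    if percentile is not None:
        res = res[res["strength"] >= np.percentile(res["strength"], percentile)]
    if n > len(res):
        warnings.warn(f"requested top {n} cells but only {len(res)} available; clamping")
        n = len(res)
    res = res.sort_values(["strength", "chrom1", "chrom2", "I", "J"],
                          ascending=[False, True, True, True, True]).head(n)
    edge_list = [((r.chrom1, r.I), (r.chrom2, r.J))
                 for r in res.itertuples() if (r.chrom1, r.I) != (r.chrom2, r.J)]
    degree, clustering = _network_metrics(edge_list)
    edges = pd.DataFrame({
        "node_a": [f"{c}:{i}" for (c, i), _ in edge_list],
        "node_b": [f"{c}:{i}" for _, (c, i) in edge_list],
        "weight": res.loc[[i for i, r in zip(res.index, res.itertuples())
                           if (r.chrom1, r.I) != (r.chrom2, r.J)], "strength"].to_numpy(),
    })
    return InteractionNetwork(edges=edges, degree=degree, clustering=clustering)
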