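"""Uniform binned-genome matrix, loop sets, anchor strength and normalization.

The binned-genome matrix tiles every chromosome at a fixed width (1 kb by
default) and overlays two kinds of columns per condition:

* score columns (loop anchor strength, ChIP binding signal, FPKM): the full
  score of every overlapping interval is added to each bin it touches —
  presence-based, no length proration;
* span columns (promoters, UTRs, CpG islands, ...): base pairs of overlap
  summed across intervals, capped at the bin width so features that recur at
  a locus (e.g. shared promoters/enhancers) cannot count more than once per
  base.

Loop records are BEDPE-style with a score and an FDR q; interaction anchor
strength sums a loop's score into every bin overlapped by either of its two
anchors, once per anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io


# ---------------------------------------------------------------------------
# Loop sets


@dataclass
class LoopSet:
    """BEDPE-style chromatin interaction records with score and FDR q.

    ``df`` columns: chrom1,start1,end1,chrom2,start2,end2,name,score,q,pets.
    ``total_valid_pairs`` is the library's valid-pair mass used when
    normalizing between conditions (defaults to the summed scores).
    """

    df: pd.DataFrame
    condition: str = ""
    total_valid_pairs: float | None = None

    def __post_init__(self):
        df = self.df
        for col in ("chrom1", "start1", "end1", "chrom2", "start2", "end2", "score", "q"):
            if col not in df.columns:
                raise ValueError(f"LoopSet missing column {col!r}")
        if (df["start1"] >= df["end1"]).any() or (df["start2"] >= df["end2"]).any():
            raise ValueError("anchor intervals must satisfy start < end")
        if ((df["q"] < 0) | (df["q"] > 1)).any():
            raise ValueError("q values must lie in [0, 1]")

    @property
    def mass(self) -> float:
        if self.total_valid_pairs is not None:
            return float(self.total_valid_pairs)
        return float(self.df["score"].sum())

    def canonical(self) -> "LoopSet":
        """Order intra-chromosomal anchors so anchor1 <= anchor2."""
        df = self.df.copy()
        flip = (df["chrom1"] == df["chrom2"]) & (df["start1"] > df["start2"])
        for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
            df.loc[flip, [a, b]] = df.loc[flip, [b, a]].values
        return replace(self, df=df)

    def filter_q(self, q_max: float) -> "LoopSet":
        return replace(self, df=self.df[self.df["q"] < q_max].reset_index(drop=True))

    def scaled(self, factor: float) -> "LoopSet":
        df = self.df.copy()
        df["score"] = df["score"] * factor
        tvp = None if self.total_valid_pairs is None else self.total_valid_pairs * factor
        return replace(self, df=df, total_valid_pairs=tvp)

    @classmethod
    def read_bedpe(cls, path, condition: str = "", total_valid_pairs=None) -> "LoopSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df.columns = io.BEDPE_COLS[: df.shape[1]]
        return cls(df, condition=condition, total_valid_pairs=total_valid_pairs)

    def write_bedpe(self, path) -> None:
        cols = [c for c in io.BEDPE_COLS if c in self.df.columns]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


def normalize_conditions(loops_a: LoopSet, loops_b: LoopSet) -> tuple[LoopSet, LoopSet]:
    """Scale the larger-mass library down to the smaller one.

    Deterministic linear scaling: the set with the larger valid-pair mass has
    every score multiplied by ``min_mass / its_mass``; the smaller set is
    returned unchanged, so within-set score ratios are preserved.
    """
    ma, mb = loops_a.mass, loops_b.mass
    if ma <= 0 or mb <= 0:
        raise ValueError("both loop sets need positive total mass")
    if ma == mb:
        return loops_a, loops_b
    if ma > mb:
        return loops_a.scaled(mb / ma), loops_b
    return loops_a, loops_b.scaled(ma / mb)


def subsample_loops(loops: LoopSet, target_mass: float, seed: int = 0) -> LoopSet:
    """Binomial subsampling alternative to linear scaling, for sensitivity
    checks; scores are treated as counts."""
    rng = np.random.default_rng(seed)
    p = min(1.0, target_mass / loops.mass)
    df = loops.df.copy()
    df["score"] = rng.binomial(np.round(df["score"]).astype(int), p)
    return replace(loops, df=df, total_valid_pairs=None)


# ---------------------------------------------------------------------------
# Binned genome table


@dataclass
class GenomeBinTable:
    """Fixed-width tiling of the genome with named data columns.

    Bins tile each chromosome without gaps or overlap; the last bin of a
    chromosome is truncated at the chromosome end.
    """

    chrom_sizes: dict
    bin_width: int
    df: pd.DataFrame
    _offsets: dict = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def chrom_n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_width)

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def chrom_values(self, name: str) -> dict:
        """Per-chromosome 1-D arrays of a column, for track-style access."""
        out = {}
        for chrom in self.chrom_sizes:
            off = self._offsets[chrom]
            out[chrom] = self.df[name].to_numpy()[off: off + self.chrom_n_bins(chrom)]
        return out

    def add_column(self, name: str, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_bins,):
            raise ValueError("column length mismatch")
        self.df[name] = values

    def write(self, path) -> None:
        io.write_table(self.df, path)


def bin_genome(chrom_sizes: dict, bin_width: int = 1000) -> GenomeBinTable:
    """Tile each chromosome into fixed-width bins (last bin truncated)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not chrom_sizes:
        raise ValueError("empty chrom_sizes")
    rows = []
    offsets = {}
    offset = 0
    for chrom, size in chrom_sizes.items():
        n = -(-size // bin_width)
        starts = np.arange(n, dtype=np.int64) * bin_width
        ends = np.minimum(starts + bin_width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        offsets[chrom] = offset
        offset += n
    df = pd.concat(rows, ignore_index=True)
    return GenomeBinTable(dict(chrom_sizes), bin_width, df, offsets)


def _iter_intervals(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        return intervals
    return pd.DataFrame(intervals, columns=["chrom", "start", "end", "score"])


def overlay_score(table: GenomeBinTable, intervals, column: str,
                  score_col: str = "score") -> GenomeBinTable:
    """Sum interval scores into every bin each interval overlaps.

    The full score is added per overlapping bin (no proration by overlap
    length): a scored feature is *present* at every bin it touches.
    """
    ivals = _iter_intervals(intervals)
    w = table.bin_width
    acc = np.zeros(table.n_bins)
    if column in table.df.columns:
        acc += table.df[column].to_numpy()
    for chrom, start, end, score in zip(
        ivals["chrom"], ivals["start"], ivals["end"], ivals[score_col]
    ):
        table._check_chrom(chrom)
        off = table._offsets[chrom]
        nbins = table.chrom_n_bins(chrom)
        first = max(0, int(start) // w)
        last = min(nbins - 1, (int(end) - 1) // w)
        if last >= first:
            acc[off + first: off + last + 1] += score
    table.df[column] = acc
    return table


def overlay_span(table: GenomeBinTable, intervals, column: str,
                 cap: int | None = None) -> GenomeBinTable:
    """Sum base pairs of feature overlap per bin, capped at ``cap`` bp.

    The cap (bin width by default) stops features that legitimately recur at
    a locus from counting the same base more than once.
    """
    ivals = _iter_intervals(intervals) if not isinstance(intervals, pd.DataFrame) else intervals
    w = table.bin_width
    if cap is None:
        cap = w
    acc = np.zeros(table.n_bins)
    if column in table.df.columns:
        acc += table.df[column].to_numpy()
    for chrom, start, end in zip(ivals["chrom"], ivals["start"], ivals["end"]):
        table._check_chrom(chrom)
        off = table._offsets[chrom]
        nbins = table.chrom_n_bins(chrom)
        start, end = int(start), int(end)
        first = max(0, start // w)
        last = min(nbins - 1, (end - 1) // w)
        for b in range(first, last + 1):
            lo = max(start, b * w)
            hi = min(end, (b + 1) * w, table.chrom_sizes[chrom])
            if hi > lo:
                acc[off + b] += hi - lo
    np.minimum(acc, cap, out=acc)
    table.df[column] = acc
    return table


def anchor_strength(table: GenomeBinTable, loops: LoopSet, column: str = "anchor_strength",
                    q_max: float | None = None, dedupe_anchors: bool = False) -> GenomeBinTable:
    """Interaction anchor strength per bin.

    Each loop adds its score once per anchor overlapping a bin, regardless of
    which of the two anchors it is; a loop whose anchors both hit the same
    bin contributes twice there unless ``dedupe_anchors`` is set.
    """
    df = loops.df
    if q_max is not None:
        df = df[df["q"] < q_max]
    w = table.bin_width
    acc = np.zeros(table.n_bins)
    if column in table.df.columns:
        acc += table.df[column].to_numpy()
    for c1, s1, e1, c2, s2, e2, score in zip(
        df["chrom1"], df["start1"], df["end1"],
        df["chrom2"], df["start2"], df["end2"], df["score"]
    ):
        hit: set = set()
        for chrom, start, end in ((c1, s1, e1), (c2, s2, e2)):
            table._check_chrom(chrom)
            off = table._offsets[chrom]
            nbins = table.chrom_n_bins(chrom)
            first = max(0, int(start) // w)
            last = min(nbins - 1, (int(end) - 1) // w)
            if last < first:
                continue
            if dedupe_anchors:
                hit.update(range(off + first, off + last + 1))
            else:
                acc[off + first: off + last + 1] += score
        if dedupe_anchors:
            acc[sorted(hit)] += score
    table.df[column] = acc
    return table
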