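"""Border- and midpoint-aligned pile-ups, enrichment statistics, and ranking
of interacting co-regulated gene pairs.

The common currency here is the pile-up: a loci x offset-bin matrix in which
every row is a genomic locus (a loop midpoint or an oriented TAD border) and
every column a fixed-width offset bin around it. A boolean mask marks cells
that must never enter a summary — offsets that run off the chromosome, or
offsets past a TAD's own midpoint (which would mix the two borders of the
domain together). TADs are orientation-corrected before border alignment:
each differential TAD is flipped when the summed strand-directional span of
its significantly regulated genes points backwards, so "left" always means
the 5' border with respect to the regulated transcription.

Per-bin enrichment uses z-scores against the profile's own bins (two-tailed
normal probability from the central area), a paired two-condition ANOVA
helper, zero-centered positional GO profiles, and a resampling-based motif /
k-mer border enrichment scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genome_binning import LoopSet
from .tad_caller import TADSet

_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# Pile-up container


@dataclass
class PileupMatrix:
    """Loci x offset-bin matrix with a validity mask.

    ``values[i, j]`` is the attribute at offset ``offsets[j]`` (bp, the left
    edge of the offset bin) from locus i. ``mask[i, j]`` is True where the
    cell is invalid (off-chromosome or truncated); masked cells are excluded
    from every summary.
    """

    values: np.ndarray
    mask: np.ndarray
    offsets: np.ndarray
    bin_width: int
    loci: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    def column_means(self) -> np.ndarray:
        """Per-offset means over unmasked cells (NaN when all masked)."""
        valid = ~self.mask
        with np.errstate(invalid="ignore"):
            sums = np.where(valid, self.values, 0.0).sum(axis=0)
            counts = valid.sum(axis=0)
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    def row_means(self) -> np.ndarray:
        valid = ~self.mask
        sums = np.where(valid, self.values, 0.0).sum(axis=1)
        counts = valid.sum(axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    def binned_column_means(self, bins_per_point: int = 5) -> np.ndarray:
        return _chunk_means(self.column_means(), bins_per_point)

    def binned_row_means(self, rows_per_point: int = 5) -> np.ndarray:
        return _chunk_means(self.row_means(), rows_per_point)

    def flipped(self) -> "PileupMatrix":
        """Reverse the offset axis of every row; an involution."""
        return replace(self, values=self.values[:, ::-1].copy(),
                       mask=self.mask[:, ::-1].copy(),
                       offsets=(-self.offsets[::-1] - self.bin_width).copy())

    def write(self, path_values, path_meta=None) -> None:
        df = pd.DataFrame(np.where(self.mask, np.nan, self.values),
                          columns=[str(o) for o in self.offsets])
        df.to_csv(path_values, sep="\t", index=False)
        if path_meta is not None:
            self.loci.to_csv(path_meta, sep="\t", index=False)


def _chunk_means(x: np.ndarray, k: int) -> np.ndarray:
    n = len(x) // k * k
    if n == 0:
        return np.array([])
    return np.nanmean(x[:n].reshape(-1, k), axis=1)


def _extract_row(track: np.ndarray, center_bin: int, n_left: int, n_right: int,
                 orient: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """One pile-up row around ``center_bin`` with off-array cells masked.

    ``orient=-1`` mirrors the genome about the center so the oriented offset
    o reads the genomic bin ``center_bin - 1 - o``.
    """
    width = n_left + n_right
    vals = np.zeros(width)
    mask = np.ones(width, dtype=bool)
    offs = np.arange(-n_left, n_right)
    idx = center_bin + offs if orient >= 0 else center_bin - 1 - offs
    ok = (idx >= 0) & (idx < len(track))
    vals[ok] = track[idx[ok]]
    mask[ok] = False
    return vals, mask


# ---------------------------------------------------------------------------
# Midpoint alignment


def align_midpoints(track: dict, midpoints, flank: int = 1_000_000,
                    bin_width: int = 1000) -> PileupMatrix:
    """Stack a binned attribute track around a list of (chrom, bp) midpoints.

    ``track`` maps chromosome to a 1-D array at ``bin_width`` resolution.
    Loci whose flank exits the chromosome keep the row with the out-of-range
    cells masked.
    """
    midpoints = list(midpoints)
    if not midpoints:
        raise ValueError("empty midpoint list")
    f = flank // bin_width
    rows, masks, meta = [], [], []
    for chrom, mid in midpoints:
        arr = track[chrom]
        v, m = _extract_row(arr, int(mid) // bin_width, f, f)
        rows.append(v)
        masks.append(m)
        meta.append({"chrom": chrom, "center": int(mid), "orient": 1})
    offsets = np.arange(-f, f) * bin_width
    return PileupMatrix(np.array(rows), np.array(masks), offsets, bin_width,
                        pd.DataFrame(meta))


def anova_condition_compare(pileup_a: PileupMatrix, pileup_b: PileupMatrix,
                            bins_per_point: int = 5) -> pd.DataFrame:
    """Two-condition comparison of pile-up column means in coarse windows.

    For every group of ``bins_per_point`` adjacent offset bins, the two
    conditions' per-bin column means are compared with a two-way ANOVA
    (condition x offset position, main effects) and the Tukey-style
    condition contrast; with two conditions the Tukey contrast reduces to
    the ANOVA condition effect, whose p is reported.
    """
    ca, cb = pileup_a.column_means(), pileup_b.column_means()
    if len(ca) != len(cb):
        raise ValueError("pile-ups have different offset geometry")
    k = bins_per_point
    rows = []
    for g in range(len(ca) // k):
        xa, xb = ca[g * k:(g + 1) * k], cb[g * k:(g + 1) * k]
        ok = ~(np.isnan(xa) | np.isnan(xb))
        xa, xb = xa[ok], xb[ok]
        n = len(xa)
        if n < 2:
            p = np.nan
        else:
            # two-way main-effects ANOVA without replication: condition
            # effect tested against the residual (interaction) term
            grand = np.concatenate([xa, xb]).mean()
            cond_means = np.array([xa.mean(), xb.mean()])
            pos_means = (xa + xb) / 2.0
            ss_cond = n * ((cond_means - grand) ** 2).sum()
            ss_pos = 2 * ((pos_means - grand) ** 2).sum()
            ss_tot = ((np.concatenate([xa, xb]) - grand) ** 2).sum()
            ss_res = max(ss_tot - ss_cond - ss_pos, 0.0)
            df_res = n - 1
            tiny = 1e-10 * max(ss_tot, 1e-300)
            if ss_res <= tiny:
                p = 1.0 if ss_cond <= tiny else 0.0
            else:
                f = (ss_cond / 1.0) / (ss_res / df_res)
                p = float(stats.f.sf(f, 1, df_res))
        rows.append({"group": g,
                     "offset": int(pileup_a.offsets[g * k]),
                     "mean_a": float(np.nanmean(xa)) if n else np.nan,
                     "mean_b": float(np.nanmean(xb)) if n else np.nan,
                     "p": p})
    return pd.DataFrame(rows)


def tad_overlap_profile(midpoints, tads: TADSet, flank: int = 1_000_000,
                        bin_width: int = 1000) -> np.ndarray:
    """Per offset bin, how many loci are covered by a TAD at that offset."""
    midpoints = list(midpoints)
    f = flank // bin_width
    counts = np.zeros(2 * f, dtype=int)
    by_chrom = {c: g for c, g in tads.df.groupby("chrom", sort=False)}
    for chrom, mid in midpoints:
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        lo = int(mid) - f * bin_width
        edges = lo + np.arange(2 * f + 1) * bin_width
        covered = np.zeros(2 * f, dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            covered |= (edges[:-1] < e) & (edges[1:] > s)
        counts += covered
    return counts


# ---------------------------------------------------------------------------
# DiffGene ranking


def rank_diffgenes(loops: LoopSet, expression: pd.DataFrame, direction: str,
                   q_max: float = 0.001, top_n: int = 200,
                   min_spacing: int = 2_500_000,
                   gene_mode: str = "body") -> pd.DataFrame:
    """Top interacting co-regulated gene pairs.

    High-confidence loops (q < ``q_max``) are scored by the summed log2 fold
    change of the direction-consistent genes contained in anchor 1 plus
    anchor 2 (condition-B-over-A fold for ``direction='up'``, the reciprocal
    — i.e. negated log2 fold — for ``'down'``), ranked from highest to
    lowest, and selected greedily down the list skipping any candidate whose
    anchor midpoint lies within ``min_spacing`` of an already selected one
    on the same chromosome.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    loops = loops.filter_q(q_max)
    if len(loops.df) == 0:
        raise ValueError("no loops pass the q filter")
    sign = 1.0 if direction == "up" else -1.0
    genes = expression[np.sign(expression["log2fc"]) == sign]
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}

    def anchor_sum(chrom, start, end):
        grp = by_chrom.get(chrom)
        if grp is None:
            return 0.0
        if gene_mode == "tss":
            tss = np.where(grp["strand"] == "-", grp["end"], grp["start"])
            hit = (tss >= start) & (tss < end)
        else:
            hit = (grp["start"] < end) & (grp["end"] > start)
        return float((sign * grp.loc[hit, "log2fc"]).sum())

    records = []
    for row in loops.df.itertuples():
        s = (anchor_sum(row.chrom1, row.start1, row.end1)
             + anchor_sum(row.chrom2, row.start2, row.end2))
        m1 = (row.start1 + row.end1) // 2
        m2 = (row.start2 + row.end2) // 2
        records.append({"chrom": row.chrom1, "sum_log2fc": s,
                        "midpoint": (m1 + m2) // 2,
                        "start1": row.start1, "end1": row.end1,
                        "start2": row.start2, "end2": row.end2,
                        "score": row.score, "q": row.q})
    ranked = pd.DataFrame(records).sort_values(
        ["sum_log2fc", "chrom", "midpoint"],
        ascending=[False, True, True]).reset_index(drop=True)
    chosen = []
    taken: dict = {}
    for row in ranked.itertuples():
        near = taken.get(row.chrom, [])
        if any(abs(row.midpoint - m) < min_spacing for m in near):
            continue
        chosen.append(row.Index)
        taken.setdefault(row.chrom, []).append(row.midpoint)
        if len(chosen) >= top_n:
            break
    return ranked.loc[chosen].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Oriented TAD-border alignment


def tad_orientation(tad_row, expression: pd.DataFrame, direction: str,
                    q_max: float = 0.05) -> tuple[int, bool]:
    """Orientation of a differential TAD from its regulated genes.

    Sign of the length-normalized summed strand-directional span (+gene
    length for + strand, -length for - strand) of the significantly
    regulated, direction-consistent genes inside the TAD. Returns
    (orientation, defaulted); TADs with no qualifying genes default to
    forward and are flagged.
    """
    sign = 1.0 if direction == "up" else -1.0
    g = expression[(expression["chrom"] == tad_row["chrom"])
                   & (expression["q"] < q_max)
                   & (np.sign(expression["log2fc"]) == sign)
                   & (expression["start"] < tad_row["end"])
                   & (expression["end"] > tad_row["start"])]
    if len(g) == 0:
        return 1, True
    span = np.where(g["strand"] == "-", -(g["end"] - g["start"]),
                    g["end"] - g["start"]).sum()
    length = tad_row["end"] - tad_row["start"]
    return (1 if span / length >= 0 else -1), False


def align_tad_borders(difftads: TADSet, expression: pd.DataFrame,
                      direction: str, track: dict, flank: int = 500_000,
                      bin_width: int = 1000,
                      q_max: float = 0.05) -> tuple[PileupMatrix, PileupMatrix]:
    """Left/right border-aligned pile-ups of oriented differential TADs.

    Each TAD is flipped when its regulated-gene directionality points
    backwards, rows are sorted by TAD length (smallest first), and cells
    past each TAD's own midpoint are masked so the two borders never average
    into each other.
    """
    if len(difftads.df) == 0:
        raise ValueError("empty TAD list")
    f = flank // bin_width
    tads = difftads.df.copy()
    tads["length"] = tads["end"] - tads["start"]
    tads = tads.sort_values("length", kind="mergesort").reset_index(drop=True)

    left_rows, left_masks, right_rows, right_masks, meta = [], [], [], [], []
    for _, row in tads.iterrows():
        orient, defaulted = tad_orientation(row, expression, direction, q_max)
        arr = track[row["chrom"]]
        if orient == 1:
            left_bp, right_bp = row["start"], row["end"]
        else:
            left_bp, right_bp = row["end"], row["start"]
        half_bins = int(row["length"]) // 2 // bin_width
        lv, lm = _extract_row(arr, int(left_bp) // bin_width, f, f, orient)
        rv, rm = _extract_row(arr, int(right_bp) // bin_width, f, f, orient)
        # interior offsets past the TAD midpoint are masked; on the
        # right-aligned block the interior is the negative-offset side
        offs = np.arange(-f, f)
        lm = lm | (offs >= half_bins)
        rm = rm | (offs < -half_bins)
        left_rows.append(lv); left_masks.append(lm)
        right_rows.append(rv); right_masks.append(rm)
        meta.append({"chrom": row["chrom"], "start": row["start"],
                     "end": row["end"], "length": row["length"],
                     "orient": orient, "orientation_defaulted": defaulted})
    offsets = np.arange(-f, f) * bin_width
    loci = pd.DataFrame(meta)
    left = PileupMatrix(np.array(left_rows), np.array(left_masks), offsets,
                        bin_width, loci)
    right = PileupMatrix(np.array(right_rows), np.array(right_masks),
                         offsets, bin_width, loci)
    return left, right


# ---------------------------------------------------------------------------
# Same-size stacking and split alignment


def stack_same_size(tads: TADSet, tracks: dict, sort_attr: str,
                    size: int = 480_000, n: int = 200, bin_width: int = 1000,
                    tolerance_bins: int = 1,
                    rows_per_point: int = 5) -> dict:
    """Stack ``n`` same-size TADs sorted by one attribute and correlate.

    Rows are TADs of width ``size`` (within +-``tolerance_bins`` bins),
    sorted descending by their mean ``sort_attr``; each attribute's 5-TAD
    binned row means are correlated (Pearson) against the binned sort
    attribute.
    """
    df = tads.df.copy()
    df["length"] = df["end"] - df["start"]
    df = df[(df["length"] - size).abs() <= tolerance_bins * bin_width]
    if len(df) < n:
        raise ValueError(f"only {len(df)} TADs of size {size} available, need {n}")
    df = df.sort_values(["chrom", "start"]).head(n).reset_index(drop=True)
    ncols = size // bin_width

    def tad_matrix(track):
        rows = []
        for _, row in df.iterrows():
            b0 = int(row["start"]) // bin_width
            arr = track[row["chrom"]]
            v = np.zeros(ncols)
            hi = min(b0 + ncols, len(arr))
            v[: hi - b0] = arr[b0:hi]
            rows.append(v)
        return np.array(rows)

    sort_mat = tad_matrix(tracks[sort_attr])
    order = np.argsort(-sort_mat.mean(axis=1), kind="mergesort")
    offsets = np.arange(ncols) * bin_width
    mask = np.zeros((n, ncols), dtype=bool)
    pileups, pearson = {}, {}
    sort_binned = _chunk_means(sort_mat[order].mean(axis=1), rows_per_point)
    for name, track in tracks.items():
        mat = tad_matrix(track)[order]
        pm = PileupMatrix(mat, mask.copy(), offsets, bin_width,
                          df.iloc[order].reset_index(drop=True))
        pileups[name] = pm
        binned = _chunk_means(mat.mean(axis=1), rows_per_point)
        if np.std(binned) == 0 or np.std(sort_binned) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(sort_binned, binned)[0, 1])
        pearson[name] = {"r": r, "r2": None if r is None or np.isnan(r) else r * r}
    return {"pileups": pileups, "pearson": pearson,
            "sorted_tads": df.iloc[order].reset_index(drop=True)}


def split_align_all(tads: TADSet, track: dict, bin_width: int = 1000,
                    max_unsplit: int = 2_000_000) -> tuple[PileupMatrix, PileupMatrix]:
    """Split every TAD in half and align halves at the left/right borders.

    Each TAD contributes its left half to the left block (offset 0 at the
    left border, increasing inward) and its right half to the right block
    (offset 0 at the right border, decreasing inward); TADs longer than
    ``max_unsplit`` contribute only their outer ``max_unsplit/2`` per side,
    dropping the middle. Rows sorted by TAD length, shortest first.
    """
    df = tads.df.copy()
    df["length"] = df["end"] - df["start"]
    df = df.sort_values("length", kind="mergesort").reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty TAD set")
    halves = np.minimum(df["length"], max_unsplit) // 2 // bin_width
    width = int(halves.max())
    lv = np.zeros((len(df), width)); lm = np.ones_like(lv, dtype=bool)
    rv = np.zeros((len(df), width)); rm = np.ones_like(rv, dtype=bool)
    for i, row in df.iterrows():
        h = int(halves[i])
        arr = track[row["chrom"]]
        v, m = _extract_row(arr, int(row["start"]) // bin_width, 0, h)
        lv[i, :h], lm[i, :h] = v, m
        v, m = _extract_row(arr, int(row["end"]) // bin_width, h, 0)
        rv[i, width - h:], rm[i, width - h:] = v, m
    left = PileupMatrix(lv, lm, np.arange(width) * bin_width, bin_width, df)
    right = PileupMatrix(rv, rm, np.arange(-width, 0) * bin_width, bin_width, df)
    return left, right


# ---------------------------------------------------------------------------
# Enrichment statistics


@dataclass
class EnrichmentProfile:
    """Per-bin z scores against the profile's own bins, two-tailed p."""

    values: np.ndarray
    z: np.ndarray
    p: np.ndarray

    def tiers(self) -> np.ndarray:
        tier = np.full(len(self.p), "", dtype=object)
        tier[self.p < 0.05] = "*"
        tier[self.p < 0.01] = "**"
        tier[self.p < 0.005] = "***"
        return tier


def zscore_profile(values) -> EnrichmentProfile:
    """Two-tailed normal probability from the central area, per bin.

    Each bin's z score is taken against the mean and sample (n-1) standard
    deviation of all bins of the profile; a constant profile gets z = 0 and
    p = 1 everywhere.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 bins")
    sd = x.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    return EnrichmentProfile(values=x, z=z, p=p)


def go_positional_profile(genes: pd.DataFrame, go_labels: pd.DataFrame,
                          centers, flank: int = 1_000_000,
                          bin_width: int = 1000,
                          denominator: str = "bin") -> dict:
    """Zero-centered positional GO-category profiles around aligned loci.

    Per offset bin (pooled over all center loci) the category gene count is
    divided by the gene count in that bin (``denominator='bin'``; ``'span'``
    divides by the whole-span gene total instead), and the whole-span mean of
    that ratio is subtracted, so each category profile sums to zero over the
    span. Gene-free bins contribute a ratio of 0.
    """
    if len(go_labels) == 0:
        raise ValueError("empty GO map")
    centers = list(centers)
    f = flank // bin_width
    labeled = genes.merge(go_labels, on="gene")
    tss = np.where(labeled["strand"] == "-", labeled["end"], labeled["start"]) \
        if "strand" in labeled.columns else labeled["start"].to_numpy()
    chroms = labeled["chrom"].to_numpy()
    cats = labeled["category"].to_numpy()
    total = np.zeros(2 * f)
    cat_counts = {c: np.zeros(2 * f) for c in pd.unique(cats)}
    for chrom, mid in centers:
        sel = chroms == chrom
        rel = (tss[sel].astype(np.int64) - (int(mid) - f * bin_width)) // bin_width
        ok = (rel >= 0) & (rel < 2 * f)
        np.add.at(total, rel[ok], 1)
        for cat, r in zip(cats[sel][ok], rel[ok]):
            cat_counts[cat][r] += 1
    profiles = {}
    for cat, counts in cat_counts.items():
        if denominator == "span":
            ratio = counts / max(total.sum(), 1)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        profiles[cat] = ratio - ratio.mean()
    return profiles


def pooled_go_statistics(profiles: dict, bins_per_point: int = 5) -> EnrichmentProfile:
    """Pool category profiles, average in coarse windows, z-score the result."""
    pooled = np.mean(list(profiles.values()), axis=0)
    return zscore_profile(_chunk_means(pooled, bins_per_point))


# ---------------------------------------------------------------------------
# Resampling border enrichment (PWM scan / k-mer modes)


def pwm_from_consensus(consensus: str, p_match: float = 0.94) -> np.ndarray:
    """4 x L probability matrix concentrated on a consensus sequence."""
    L = len(consensus)
    pwm = np.full((4, L), (1.0 - p_match) / 3.0)
    for j, base in enumerate(consensus.upper()):
        pwm[_BASES[base], j] = p_match
    return pwm


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 0, dtype=np.int8)
    for base, code in _BASES.items():
        out[arr == ord(base)] = code
    return out


def scan_pwm(seq_codes: np.ndarray, pwm: np.ndarray,
             threshold_frac: float = 0.8) -> int:
    """Count log-odds PWM hits (>= threshold_frac of the maximum score)."""
    L = pwm.shape[1]
    if len(seq_codes) < L:
        return 0
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    maxscore = logodds.max(axis=0).sum()
    threshold = threshold_frac * maxscore
    n = len(seq_codes) - L + 1
    scores = np.zeros(n)
    for j in range(L):
        scores += logodds[seq_codes[j: j + n], j]
    return int((scores >= threshold).sum())


def border_resampling_enrichment(
    sequences: dict, borders, mode: str = "pwm_scan",
    pwms: dict | None = None, kmers: list | None = None,
    bin_width: int = 10_000, span: int = 195_000,
    n_iterations: int = 50, n_repeats: int = 10, n_samples: int = 1000,
    sample_len: int = 100, kmer_len: int = 20,
    min_total: int = 10, seed: int = 0,
    interior_limits: list | None = None,
    pwm_threshold: float = 0.8,
) -> pd.DataFrame:
    """Random-sampling motif / k-mer enrichment in bins around aligned borders.

    For each offset bin (±``span`` from every border, ``bin_width`` wide),
    ``n_iterations`` iterations of ``n_repeats x n_samples`` random
    ``sample_len`` bp draws are scanned: in ``pwm_scan`` mode against the
    supplied position-weight matrices, in ``kmer`` mode for exact
    ``kmer_len``-mers. Motifs counted ``min_total`` times or fewer over all
    iterations are dropped as noise; per motif, the mean per-bin counts are
    z-scored across bins and the two-tailed p is Bonferroni-adjusted by the
    number of retained motifs. ``interior_limits`` optionally gives, per
    border, the maximum interior offset (the TAD midpoint) beyond which bins
    are not sampled.
    """
    if mode == "pwm_scan":
        if not pwms:
            raise ValueError("pwm_scan mode requires a PWM set")
        motifs = {name: pwm for name, pwm in pwms.items()}
    elif mode == "kmer":
        if kmers:
            motifs = {k: None for k in kmers}
        else:
            motifs = None  # discover sampled k-mers
        sample_len = kmer_len
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    borders = list(borders)
    offsets = np.arange(-span, span, bin_width)
    nbins = len(offsets)
    codes = {c: _encode(s) for c, s in sequences.items()}

    counts: dict = {}

    def tally(name, b, value):
        if name not in counts:
            counts[name] = np.zeros((n_iterations, nbins))
        counts[name][it, b] += value

    for it in range(n_iterations):
        for bi, (chrom, border) in enumerate(
                (b[0], b[1]) for b in borders):
            limit = None
            if interior_limits is not None:
                limit = interior_limits[bi]
            seq = codes[chrom]
            for b, off in enumerate(offsets):
                if limit is not None and off >= limit:
                    continue
                lo = border + off
                hi = lo + bin_width - sample_len
                if lo < 0 or hi <= lo or hi > len(seq) - sample_len:
                    continue
                starts = rng.integers(lo, hi, size=n_repeats * n_samples)
                if mode == "pwm_scan":
                    for name, pwm in motifs.items():
                        hitlen = pwm.shape[1]
                        total = 0
                        for s in starts:
                            total += scan_pwm(seq[s: s + sample_len], pwm,
                                              pwm_threshold)
                        tally(name, b, total)
                else:
                    for s in starts:
                        kseq = seq[s: s + kmer_len]
                        name = "".join("ACGT"[c] for c in kseq)
                        if motifs is not None and name not in motifs:
                            continue
                        tally(name, b, 1)

    rows = []
    names = [n for n, mat in counts.items() if mat.sum() > min_total]
    for name in names:
        mat = counts[name]
        mean_counts = mat.mean(axis=0)
        prof = zscore_profile(mean_counts)
        for b in range(nbins):
            rows.append({"motif": name, "offset": int(offsets[b]),
                         "mean_count": mean_counts[b],
                         "z": prof.z[b], "p": prof.p[b],
                         "p_adj": min(1.0, prof.p[b] * len(names))})
    return pd.DataFrame(rows, columns=["motif", "offset", "mean_count",
                                       "z", "p", "p_adj"])
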