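"""Two-condition synthetic genomes with planted chromatin structure.

The generator emulates the statistical structure of a paired Hi-C/HiChIP +
ChIP-seq + RNA-seq study of two cell states: a distance-decaying
intra-chromosomal contact background (P(contact) ~ d^-alpha), block-enriched
planted TADs whose borders partly move between conditions, planted
condition-favored differential loops, protein binding peaks enriched at TAD
borders, TAD-coupled co-regulated gene expression, and positional clustering
of GO categories. Everything is written in the standard plain-text formats
the analysis pipeline consumes (chrom.sizes, BED, narrowPeak, BEDPE, TSV),
and the ground truth of what was planted is returned alongside.

Scores are drawn as Poisson counts around the decay x enrichment
expectation (count-like valid-pair semantics), and each loop's FDR q is a
Benjamini-Hochberg value over Poisson upper-tail p-values against the
decay-only background. One RNG stream per output artifact is derived from
the master seed by stable labels, so adding an artifact never perturbs the
others. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._util import stream, fmt
from .genome_binning import LoopSet

TAD_BIN = 40_000
GO_CATEGORIES = (
    "proliferation", "metabolism", "rna_processing", "cell_cycle",
    "chromatin", "development", "transcription_regulation", "neuronal",
    "axon_guidance", "signaling",
)
# down-regulated TADs draw from the first half, up-regulated from the second
_GO_DOWN = GO_CATEGORIES[:5]
_GO_UP = GO_CATEGORIES[5:]


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-state genome."""

    n_chroms: int = 2
    chrom_length: int = 20_000_000
    tad_size_range: tuple = (240_000, 960_000)
    decay_exponent: float = 1.0
    intra_tad_enrichment: float = 3.0
    border_loop_enrichment: float = 2.0
    n_diff_loops: int = 50
    diff_loop_fold: float = 4.0
    n_genes: int = 2000
    tad_coregulation_prob: float = 0.8
    border_peak_enrichment: float = 5.0
    fpkm_lognormal_params: tuple = (1.0, 1.0)
    read_depth: float = 1_000_000.0
    seed: int = 0
    # plumbing knobs
    n_loops: int = 20_000
    anchor_width: int = 5_000
    n_peaks: int = 1_000
    border_shift_fraction: float = 0.38
    condition_labels: tuple = ("esc", "ncc")
    proteins: tuple = ("fgfr1", "ctcf")

    def __post_init__(self):
        for name in ("intra_tad_enrichment", "border_loop_enrichment",
                     "diff_loop_fold", "border_peak_enrichment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.tad_coregulation_prob <= 1:
            raise ValueError("tad_coregulation_prob must lie in [0, 1]")
        if self.tad_size_range[0] < 3 * TAD_BIN:
            raise ValueError("minimum TAD size must be at least 3 x 40 kb")
        if self.chrom_length % 1000:
            raise ValueError("chrom_length must be divisible by 1000")

    @property
    def chrom_sizes(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class SyntheticTruth:
    """What was planted: TAD borders, differential loops, co-regulated gene
    groups and border-proximal peak positions."""

    tad_borders_per_condition: dict       # label -> {chrom: sorted borders bp}
    diff_loops: list                      # (loop dict, favored label, fold)
    coregulated_gene_groups: list         # (chrom, [gene ids], sign)
    border_peak_positions: list = field(default_factory=list)  # (protein, chrom, bp)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


# ---------------------------------------------------------------------------
# TAD scaffold


def _draw_tads(config: SimConfig, rng) -> dict:
    """Per-chromosome sorted border arrays for condition 1 (0-based bp)."""
    lo = config.tad_size_range[0] // TAD_BIN
    hi = config.tad_size_range[1] // TAD_BIN
    borders = {}
    for chrom, length in config.chrom_sizes.items():
        pos, cur = [0], 0
        while cur < length:
            size = int(rng.integers(lo, hi + 1)) * TAD_BIN
            cur = min(cur + size, length)
            pos.append(cur)
        borders[chrom] = np.array(pos, dtype=np.int64)
    return borders


def _shift_borders(borders: dict, config: SimConfig, rng) -> dict:
    """Second-condition borders: a fixed fraction of internal borders moved
    by at least one 40 kb bin, preserving order and minimum TAD size."""
    out = {}
    min_bins = 3
    for chrom, b in borders.items():
        b2 = b.copy()
        internal = np.arange(1, len(b) - 1)
        n_shift = int(round(config.border_shift_fraction * len(internal)))
        which = rng.choice(internal, size=n_shift, replace=False) if n_shift else []
        for i in sorted(which):
            step = int(rng.integers(1, 4)) * TAD_BIN * (1 if rng.random() < 0.5 else -1)
            cand = b2[i] + step
            if (cand - b2[i - 1] >= min_bins * TAD_BIN
                    and b2[i + 1] - cand >= min_bins * TAD_BIN):
                b2[i] = cand
        out[chrom] = np.sort(b2)
    return out


def _tad_index(borders: np.ndarray, pos) -> np.ndarray:
    """Index of the TAD interval containing each position."""
    return np.clip(np.searchsorted(borders, pos, side="right") - 1,
                   0, len(borders) - 2)


def _near_border(borders: np.ndarray, pos, window: int = 20_000) -> np.ndarray:
    pos = np.atleast_1d(pos)
    idx = np.searchsorted(borders, pos)
    left = borders[np.clip(idx - 1, 0, len(borders) - 1)]
    right = borders[np.clip(idx, 0, len(borders) - 1)]
    return (np.abs(pos - left) <= window) | (np.abs(pos - right) <= window)


# ---------------------------------------------------------------------------
# Loops


def _sample_distances(rng, n, alpha, dmin, dmax):
    """Power-law distances P(d) ~ d^-alpha on [dmin, dmax] (inverse CDF)."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return dmin * (dmax / dmin) ** u
    a = 1.0 - alpha
    return (dmin ** a + u * (dmax ** a - dmin ** a)) ** (1.0 / a)


def _simulate_loops(config: SimConfig, borders_by_cond: dict) -> tuple:
    """Shared loop positions with per-condition Poisson scores and BH q.

    Returns (positions DataFrame, {label: scores}, {label: q}, diff truth).
    """
    rng = stream(config.seed, "loops")
    labels = list(config.condition_labels)
    per_chrom = config.n_loops // config.n_chroms
    aw = config.anchor_width
    rows = []
    for chrom, length in config.chrom_sizes.items():
        d = _sample_distances(rng, per_chrom, config.decay_exponent,
                              dmin=2 * TAD_BIN, dmax=length / 4)
        start1 = rng.integers(0, length - aw, size=per_chrom).astype(np.int64)
        start2 = np.minimum(start1 + d.astype(np.int64), length - aw)
        for s1, s2 in zip(start1, start2):
            lo, hi = (s1, s2) if s1 <= s2 else (s2, s1)
            rows.append((chrom, int(lo), int(lo + aw), chrom, int(hi), int(hi + aw)))
    pos = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                      "chrom2", "start2", "end2"])
    mid1 = ((pos["start1"] + pos["end1"]) // 2).to_numpy()
    mid2 = ((pos["start2"] + pos["end2"]) // 2).to_numpy()
    dist = np.maximum(np.abs(mid2 - mid1), 1)
    base = dist.astype(float) ** (-config.decay_exponent)

    # enrichment per condition: same-TAD fold and border-proximal fold
    lam = {}
    for label in labels:
        e = np.ones(len(pos))
        for chrom in config.chrom_sizes:
            sel = (pos["chrom1"] == chrom).to_numpy()
            b = borders_by_cond[label][chrom]
            same_tad = _tad_index(b, mid1[sel]) == _tad_index(b, mid2[sel])
            near = _near_border(b, mid1[sel]) | _near_border(b, mid2[sel])
            f = np.ones(sel.sum())
            f[same_tad] *= config.intra_tad_enrichment
            f[near] *= config.border_loop_enrichment
            e[sel] = f
        lam[label] = base * e

    # plant differential loops among mid-distance candidates
    diff_truth = []
    if config.n_diff_loops:
        order = np.argsort(dist)
        cands = order[: max(config.n_diff_loops * 4, config.n_diff_loops)]
        picked = rng.choice(cands, size=config.n_diff_loops, replace=False)
        for k, i in enumerate(picked):
            favored = labels[k % 2]
            lam[favored][i] *= config.diff_loop_fold
            diff_truth.append((int(i), favored, config.diff_loop_fold))

    scores, qvals = {}, {}
    for label in labels:
        scale = config.read_depth / lam[label].sum()
        lam_scaled = lam[label] * scale
        lam_bg = base * (config.read_depth / base.sum())
        s = stream(config.seed, f"loop_scores_{label}").poisson(lam_scaled)
        from scipy import stats as _st
        p = _st.poisson.sf(s - 1, lam_bg)        # P(X >= s) under background
        # Benjamini-Hochberg
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        scores[label] = s
        qvals[label] = np.clip(q, 0.0, 1.0)
    return pos, scores, qvals, diff_truth


def _loopset(pos, scores, qvals, label, subset=None) -> LoopSet:
    df = pos.copy()
    df["name"] = [f"loop{i}" for i in range(len(df))]
    df["score"] = scores[label].astype(float)
    df["q"] = qvals[label]
    df["pets"] = scores[label]
    if subset is not None:
        df = df.loc[subset].reset_index(drop=True)
    return LoopSet(df, condition=label, total_valid_pairs=float(df["score"].sum()))


# ---------------------------------------------------------------------------
# Genes, expression, GO


def _simulate_genes(config: SimConfig, borders: dict) -> tuple:
    rng = stream(config.seed, "genes")
    labels = config.condition_labels
    per_chrom = config.n_genes // config.n_chroms
    mu, sigma = config.fpkm_lognormal_params
    rows, groups = [], []
    gid = 0
    for chrom, length in config.chrom_sizes.items():
        b = borders[chrom]
        tad_dir = np.where(rng.random(len(b) - 1) < 0.5, 1.0, -1.0)
        tad_genes: dict = {}
        tss = np.sort(rng.integers(10_000, length - 30_000, size=per_chrom))
        for t in tss:
            glen = int(rng.integers(2_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = (int(t), int(t) + glen) if strand == "+" else (int(t) - glen, int(t))
            start = max(start, 0)
            tad = int(_tad_index(b, t))
            sign = tad_dir[tad] if rng.random() < config.tad_coregulation_prob \
                else -tad_dir[tad]
            log2fc = float(sign * abs(rng.normal(1.5, 0.5)))
            fpkm_a = float(rng.lognormal(mu, sigma))
            fpkm_b = fpkm_a * 2.0 ** log2fc
            q = float(10 ** -rng.uniform(3, 8)) if abs(log2fc) > 1.0 \
                else float(rng.uniform(0.05, 1.0))
            name = f"g{gid:05d}"
            gid += 1
            rows.append({"gene": name, "chrom": chrom, "start": start,
                         "end": end, "strand": strand,
                         f"fpkm_{labels[0]}": fpkm_a,
                         f"fpkm_{labels[1]}": fpkm_b,
                         "log2fc": log2fc, "q": q})
            tad_genes.setdefault(tad, []).append(name)
        for tad, names in sorted(tad_genes.items()):
            groups.append((chrom, names, int(tad_dir[tad])))
    return pd.DataFrame(rows), groups


def _simulate_go(config: SimConfig, genes: pd.DataFrame, groups) -> pd.DataFrame:
    rng = stream(config.seed, "go")
    tad_cat = {}
    for chrom, names, sign in groups:
        pool = _GO_UP if sign > 0 else _GO_DOWN
        cat = pool[int(rng.integers(len(pool)))]
        for name in names:
            tad_cat[name] = cat
    rows = []
    for gene in genes["gene"]:
        if rng.random() < 0.8 and gene in tad_cat:
            cat = tad_cat[gene]
        else:
            cat = GO_CATEGORIES[int(rng.integers(len(GO_CATEGORIES)))]
        rows.append({"gene": gene, "category": cat})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peaks and annotations


def _simulate_peaks(config: SimConfig, borders: dict, protein: str,
                    label: str) -> tuple:
    """narrowPeak table with the required border enrichment, plus truth."""
    rng = stream(config.seed, f"peaks_{protein}_{label}")
    genome = sum(config.chrom_sizes.values())
    all_borders = {c: b[1:-1] for c, b in borders.items()}
    n_border_bp = sum(len(b) for b in all_borders.values()) * 40_000
    frac = min(0.9, config.border_peak_enrichment * n_border_bp / genome)
    rows, truth = [], []
    per_chrom = config.n_peaks // config.n_chroms
    for chrom, length in config.chrom_sizes.items():
        b = all_borders[chrom]
        for _ in range(per_chrom):
            if len(b) and rng.random() < frac:
                pos = int(b[rng.integers(len(b))] + rng.integers(-20_000, 20_001))
                truth.append((protein, chrom, pos))
            else:
                pos = int(rng.integers(500, length - 500))
            pos = int(np.clip(pos, 500, length - 500))
            signal = float(rng.lognormal(1.0, 0.6))
            rows.append({"chrom": chrom, "start": pos - 250, "end": pos + 250,
                         "name": f"{protein}_{label}_{len(rows)}",
                         "score": int(min(1000, signal * 100)), "strand": ".",
                         "signal": round(signal, 4),
                         "pvalue": round(float(rng.uniform(5, 30)), 4),
                         "qvalue": round(float(rng.uniform(2, 20)), 4),
                         "peak": 250})
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return df, truth


def _complement(intervals: list, length: int) -> list:
    out, cur = [], 0
    for s, e in sorted(intervals):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def _simulate_annotations(config: SimConfig, genes: pd.DataFrame,
                          borders: dict) -> dict:
    """Per-feature-class BED interval tables derived from the gene models."""
    rng = stream(config.seed, "annotations")
    feats: dict = {k: [] for k in
                   ("promoter", "five_utr", "three_utr", "exon", "intron",
                    "first_exon", "cds", "enhancer", "cpg_island",
                    "cpg_shore", "cpg_shelf", "lncrna", "intergenic")}
    genic: dict = {c: [] for c in config.chrom_sizes}
    fpkm_col = f"fpkm_{config.condition_labels[0]}"
    for row in genes.itertuples():
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        fwd = row.strand == "+"
        tss = start if fwd else end
        prom = (tss - 1000, tss) if fwd else (tss, tss + 1000)
        feats["promoter"].append((chrom, max(prom[0], 0), prom[1]))
        genic[chrom].append((max(prom[0], 0), prom[1]))
        genic[chrom].append((start, end))
        glen = end - start
        # three exons: ends plus a middle slice
        e1 = (start, min(start + 200, end)) if fwd else (max(end - 200, start), end)
        feats["first_exon"].append((chrom, *e1))
        feats["five_utr"].append((chrom, *e1))
        far = (max(end - 200, start), end) if fwd else (start, min(start + 200, end))
        feats["three_utr"].append((chrom, *far))
        mid = (start + glen // 2 - 100, start + glen // 2 + 100)
        exons = sorted({e1, far, (max(mid[0], start), min(mid[1], end))})
        for ex in exons:
            feats["exon"].append((chrom, *ex))
            feats["cds"].append((chrom, *ex))
        prev = None
        for ex in exons:
            if prev is not None and ex[0] > prev:
                feats["intron"].append((chrom, prev, ex[0]))
            prev = ex[1]
        # CpG islands preferentially at promoters of highly expressed genes
        if getattr(row, fpkm_col) > np.e:
            ci = (max(prom[0] - 100, 0), prom[0] + 400)
            feats["cpg_island"].append((chrom, *ci))
            feats["cpg_shore"].append((chrom, max(ci[0] - 2000, 0), ci[0]))
            feats["cpg_shore"].append((chrom, ci[1], ci[1] + 2000))
            feats["cpg_shelf"].append((chrom, max(ci[0] - 4000, 0), max(ci[0] - 2000, 0)))
            feats["cpg_shelf"].append((chrom, ci[1] + 2000, ci[1] + 4000))
    for chrom, length in config.chrom_sizes.items():
        b = borders[chrom][1:-1]
        n_enh = config.n_genes // config.n_chroms // 2
        for _ in range(n_enh):
            if len(b) and rng.random() < 0.3:
                pos = int(b[rng.integers(len(b))] + rng.integers(-15_000, 15_001))
            else:
                pos = int(rng.integers(0, length - 500))
            pos = int(np.clip(pos, 0, length - 500))
            feats["enhancer"].append((chrom, pos, pos + 500))
        inter = _complement(genic[chrom], length)
        for s, e in inter:
            feats["intergenic"].append((chrom, s, e))
        big = [iv for iv in inter if iv[1] - iv[0] > 20_000]
        for s, e in big[:: max(1, len(big) // 20)]:
            m = (s + e) // 2
            feats["lncrna"].append((chrom, m - 5_000, m + 5_000))
    out = {}
    for name, rows in feats.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        df["name"] = name
        df["score"] = 0
        df["strand"] = "."
        out[name] = df
    return out


# ---------------------------------------------------------------------------
# Contact matrices


def simulate_contact_matrix(config: SimConfig, truth: SyntheticTruth,
                            condition: str, chrom: str,
                            bin_width: int = TAD_BIN) -> np.ndarray:
    """Symmetric Poisson contact matrix with planted TAD blocks.

    Expected counts follow (|i-j|+1)^-alpha, multiplied by the within-TAD
    enrichment when both bins fall in the same planted TAD, scaled so the
    matrix total matches the configured read depth.
    """
    if config.chrom_length % bin_width:
        raise ValueError("bin width must divide the chromosome length")
    n = config.chrom_length // bin_width
    borders = np.asarray(truth.tad_borders_per_condition[condition][chrom])
    centers = (np.arange(n) + 0.5) * bin_width
    tad_of = _tad_index(borders, centers)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lam = (np.abs(i - j) + 1.0) ** (-config.decay_exponent)
    lam[tad_of[i] == tad_of[j]] *= config.intra_tad_enrichment
    lam *= config.read_depth / lam.sum()
    rng = stream(config.seed, f"matrix_{condition}_{chrom}")
    upper = rng.poisson(np.triu(lam)).astype(float)
    return upper + np.triu(upper, 1).T


# ---------------------------------------------------------------------------
# Top-level generator


def simulate_genome(config: SimConfig, outdir,
                    write_matrices: bool = False) -> tuple[dict, SyntheticTruth]:
    """Write the full synthetic dataset and return (paths, truth).

    Outputs: chrom.sizes; per-feature BED annotations; one narrowPeak per
    protein per condition; BEDPE loop sets per assay (global Hi-C plus one
    protein-associated subset per protein) per condition; the expression
    TSV; the GO label TSV; optionally dense 40 kb contact matrices.
    Identical seeds give byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "annotations").mkdir(exist_ok=True)
        (outdir / "peaks").mkdir(exist_ok=True)
        (outdir / "loops").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    labels = list(config.condition_labels)
    paths: dict = {}

    borders1 = _draw_tads(config, stream(config.seed, "tads"))
    borders2 = _shift_borders(borders1, config, stream(config.seed, "tad_shift"))
    borders_by_cond = {labels[0]: borders1, labels[1]: borders2}

    pos, scores, qvals, diff_idx = _simulate_loops(config, borders_by_cond)
    diff_loops = [
        ({k: (int(v) if isinstance(v, (int, np.integer)) else v)
          for k, v in pos.iloc[i].to_dict().items()} | {"index": int(i)},
         favored, fold)
        for i, favored, fold in diff_idx
    ]
    genes, groups = _simulate_genes(config, borders1)
    go = _simulate_go(config, genes, groups)

    truth = SyntheticTruth(
        tad_borders_per_condition={
            lab: {c: b.tolist() for c, b in bs.items()}
            for lab, bs in borders_by_cond.items()},
        diff_loops=diff_loops,
        coregulated_gene_groups=[(c, names, s) for c, names, s in groups],
    )

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    io.write_chrom_sizes(config.chrom_sizes, paths["chrom_sizes"])

    annots = _simulate_annotations(config, genes, borders1)
    for name, df in annots.items():
        p = outdir / "annotations" / f"{name}.bed"
        io.write_bed(df, p)
        paths[f"annotation_{name}"] = p

    peak_pos: dict = {}
    for protein in config.proteins:
        for label in labels:
            df, truth_peaks = _simulate_peaks(config, borders_by_cond[label],
                                              protein, label)
            truth.border_peak_positions.extend(truth_peaks)
            peak_pos.setdefault((protein, label), df)
            p = outdir / "peaks" / f"{protein}_{label}.narrowPeak"
            io.write_narrowpeak(df, p)
            paths[f"peaks_{protein}_{label}"] = p

    # global loops plus protein-associated subsets (anchors near peaks)
    mid1 = ((pos["start1"] + pos["end1"]) // 2).to_numpy()
    mid2 = ((pos["start2"] + pos["end2"]) // 2).to_numpy()
    for label in labels:
        ls = _loopset(pos, scores, qvals, label)
        p = outdir / "loops" / f"hic_{label}.bedpe"
        ls.write_bedpe(p)
        paths[f"loops_hic_{label}"] = p
        for protein in config.proteins:
            pk = peak_pos[(protein, label)]
            sel = np.zeros(len(pos), dtype=bool)
            for chrom in config.chrom_sizes:
                csel = (pos["chrom1"] == chrom).to_numpy()
                centers = ((pk.loc[pk["chrom"] == chrom, "start"]
                            + pk.loc[pk["chrom"] == chrom, "end"]) // 2).to_numpy()
                if len(centers) == 0:
                    continue
                centers = np.sort(centers)
                for mids in (mid1, mid2):
                    i = np.searchsorted(centers, mids[csel])
                    near = np.minimum(
                        np.abs(mids[csel] - centers[np.clip(i - 1, 0, len(centers) - 1)]),
                        np.abs(mids[csel] - centers[np.clip(i, 0, len(centers) - 1)]),
                    ) <= 10_000
                    tmp = sel[csel]
                    tmp |= near
                    sel[csel] = tmp
            sub = _loopset(pos, scores, qvals, label, subset=np.flatnonzero(sel))
            p = outdir / "loops" / f"{protein}_{label}.bedpe"
            sub.write_bedpe(p)
            paths[f"loops_{protein}_{label}"] = p

    paths["expression"] = outdir / "expression.tsv"
    exp_out = genes.copy()
    for c in exp_out.columns:
        if exp_out[c].dtype == float:
            exp_out[c] = exp_out[c].map(fmt)
    exp_out.to_csv(paths["expression"], sep="\t", index=False)

    paths["go_labels"] = outdir / "go_labels.tsv"
    go.to_csv(paths["go_labels"], sep="\t", index=False)

    if write_matrices:
        (outdir / "matrices").mkdir(exist_ok=True)
        for label in labels:
            for chrom in config.chrom_sizes:
                mat = simulate_contact_matrix(config, truth, label, chrom)
                p = outdir / "matrices" / f"{label}_{chrom}.tsv"
                np.savetxt(p, mat, fmt="%d", delimiter="\t")
                paths[f"matrix_{label}_{chrom}"] = p

    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths, truth


# ---------------------------------------------------------------------------
# Synthetic sequence (for the motif-enrichment scan)


def simulate_sequence(chrom_sizes: dict, borders: dict | None = None,
                      motif: str | None = None, border_density: float = 1e-3,
                      background_density: float = 1e-4,
                      border_window: int = 10_000, seed: int = 0) -> dict:
    """Random genome sequence with a motif planted densely near borders.

    ``border_density`` / ``background_density`` are expected motif copies per
    bp inside the border windows and elsewhere; their ratio is the planted
    enrichment. Returns {chrom: sequence string}.
    """
    rng = stream(seed, "sequence")
    out = {}
    for chrom, length in chrom_sizes.items():
        seq = rng.choice(list("ACGT"), size=length)
        if motif:
            n_bg = rng.poisson(background_density * length)
            for pos in rng.integers(0, length - len(motif), size=n_bg):
                seq[pos: pos + len(motif)] = list(motif)
            for b in (borders or {}).get(chrom, []):
                lo = max(0, int(b) - border_window // 2)
                hi = min(length - len(motif), int(b) + border_window // 2)
                if hi <= lo:
                    continue
                n = rng.poisson(border_density * (hi - lo))
                for pos in rng.integers(lo, hi, size=n):
                    seq[pos: pos + len(motif)] = list(motif)
        out[chrom] = "".join(seq)
    return out
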