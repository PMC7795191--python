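"""End-to-end demonstration pipeline on a synthetic two-condition genome.

Runs every analysis stage in order on one generated dataset: genome binning
with anchor strength and annotation overlays, directionality-index TAD
calling and border comparison per condition, hierarchical paired-t
differential interaction testing with condition-favored loop lists, ranking
of interacting co-regulated gene pairs with midpoint pile-ups, split-TAD
alignment with border enrichment z-statistics, and two-window expression
class prediction. All result files are plain text and byte-identical for a
fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._util import fmt
from .synthetic_data import SimConfig, simulate_genome, simulate_contact_matrix
from .genome_binning import (LoopSet, bin_genome, overlay_score, overlay_span,
                             anchor_strength, normalize_conditions)
from .tad_caller import TADSet, directionality_index, call_tads, compare_tads
from .differential_interactions import (hierarchical_grid, paired_t_grid,
                                        differential_loops)
from .difftad_pileups import (rank_diffgenes, align_midpoints,
                              tad_overlap_profile, split_align_all,
                              zscore_profile)
from .expression_prediction import (two_window_features, label_bins,
                                    train_eval, FPKM_2CLASS)

SPAN_FEATURES = ("promoter", "five_utr", "cpg_island", "enhancer", "intergenic")


def run(config: SimConfig, outdir, fine: int = 100_000,
        coarse: int = 1_000_000) -> dict:
    """Run the full pipeline; returns a dict of computed summaries.

    Writes under ``outdir``: the generated dataset (``data/``), the binned
    genome table, per-condition TAD calls with border-shift statistics,
    differential-interaction tables, the ranked co-regulated interacting
    gene lists with pile-up profiles, and prediction metrics.
    """
    outdir = Path(outdir)
    res_dir = outdir / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    labels = list(config.condition_labels)
    summary: dict = {"seed": config.seed}

    paths, truth = simulate_genome(config, outdir / "data")
    loops = {lab: LoopSet.read_bedpe(paths[f"loops_hic_{lab}"], condition=lab)
             for lab in labels}
    loops[labels[0]], loops[labels[1]] = normalize_conditions(
        loops[labels[0]], loops[labels[1]])

    # --- binned genome table -------------------------------------------------
    sizes = io.read_chrom_sizes(paths["chrom_sizes"])
    table = bin_genome(sizes, 1000)
    expression = io.read_expression(paths["expression"])
    for lab in labels:
        anchor_strength(table, loops[lab], f"anchor_strength_{lab}")
        pk = io.read_narrowpeak(paths[f"peaks_fgfr1_{lab}"])
        overlay_score(table, pk[["chrom", "start", "end", "signal"]],
                      f"fgfr1_binding_{lab}", score_col="signal")
        overlay_score(table, expression[["chrom", "start", "end", f"fpkm_{lab}"]],
                      f"fpkm_{lab}", score_col=f"fpkm_{lab}")
    for feat in SPAN_FEATURES:
        overlay_span(table, io.read_bed(paths[f"annotation_{feat}"]), feat)
    table.write(res_dir / "binned_genome.tsv.gz")

    # --- TAD calling and border comparison -----------------------------------
    tads = {}
    for lab in labels:
        frames = []
        for chrom in sizes:
            mat = simulate_contact_matrix(config, truth, lab, chrom)
            di = directionality_index(mat, chrom=chrom)
            frames.append(call_tads(di).df)
        tads[lab] = TADSet(pd.concat(frames, ignore_index=True), condition=lab)
        tads[lab].write_bed(res_dir / f"tads_{lab}.bed")
    shift = compare_tads(tads[labels[0]], tads[labels[1]])
    summary["tad_counts"] = {lab: int(len(tads[lab].df)) for lab in labels}
    summary["border_shift"] = {
        "pct_changed": shift.pct_changed, "mean_shift_bp": shift.mean_shift,
        "min_shift_bp": shift.min_shift, "max_shift_bp": shift.max_shift}

    # --- differential interactions -------------------------------------------
    grids = {lab: hierarchical_grid(loops[lab], fine=fine, coarse=coarse)
             for lab in labels}
    tests = paired_t_grid(grids[labels[0]], grids[labels[1]])
    io.write_table(tests.round(6), res_dir / "paired_t_grid.tsv")
    for lab in labels:
        fav = differential_loops(tests, lab)
        io.write_table(fav.round(6), res_dir / f"differential_loops_{lab}.tsv")
    summary["n_cells_tested"] = int(len(tests))
    summary["pct_cells_p05"] = float(100.0 * (tests["p"] < 0.05).mean())

    # --- co-regulated interacting genes and pile-ups --------------------------
    delta = (table.column(f"anchor_strength_{labels[1]}")
             - table.column(f"anchor_strength_{labels[0]}"))
    table.add_column("anchor_strength_delta", delta)
    delta_track = table.chrom_values("anchor_strength_delta")
    diffgene = {}
    for direction in ("up", "down"):
        ranked = rank_diffgenes(loops[labels[1]], expression, direction,
                                top_n=20, min_spacing=1_000_000)
        diffgene[direction] = ranked
        io.write_table(ranked.round(6), res_dir / f"diffgenes_{direction}.tsv")
        mids = list(zip(ranked["chrom"], ranked["midpoint"]))
        pm = align_midpoints(delta_track, mids, flank=500_000)
        cm = pd.DataFrame({"offset": pm.offsets,
                           "mean_delta": pm.column_means()})
        io.write_table(cm.round(6), res_dir / f"midpoint_profile_{direction}.tsv")
        counts = tad_overlap_profile(mids, tads[labels[1]], flank=500_000)
        io.write_table(pd.DataFrame({
            "offset": np.arange(-500, 500) * 1000, "n_covered": counts}),
            res_dir / f"tad_overlap_{direction}.tsv")
        tdf = tads[labels[1]].df
        in_tad = [bool(((tdf["chrom"] == c) & (tdf["start"] <= m)
                        & (tdf["end"] > m)).any()) for c, m in mids]
        summary[f"diffgene_{direction}_pct_in_tads"] = float(
            100.0 * np.mean(in_tad))

    # --- split-TAD alignment with border statistics ---------------------------
    strength = table.chrom_values(f"anchor_strength_{labels[0]}")
    left, right = split_align_all(tads[labels[0]], strength)
    cm = left.binned_column_means(5)
    prof = zscore_profile(cm[~np.isnan(cm)])
    io.write_table(pd.DataFrame({
        "bin": np.arange(len(prof.values)),
        "mean": np.round(prof.values, 6), "z": np.round(prof.z, 4),
        "p": np.round(prof.p, 6)}), res_dir / "split_tad_border_profile.tsv")
    interior = prof.values[5:]
    summary["border_vs_interior_strength_ratio"] = float(
        prof.values[0] / interior.mean()) if interior.mean() > 0 else None

    # --- expression prediction -------------------------------------------------
    fpkm_col = f"fpkm_{labels[0]}"
    attrs = ["promoter", "cpg_island", f"fgfr1_binding_{labels[0]}"]
    X, idx = two_window_features(table, attrs, inner=1000, outer=1000)
    y = label_bins(table.column(fpkm_col)[idx], FPKM_2CLASS)
    metrics = train_eval(X, y, seed=config.seed)
    summary["prediction"] = {
        "train_accuracy": metrics["train_accuracy"],
        "test_accuracy": metrics["test_accuracy"],
        "n_bins": int(len(y)),
    }

    (res_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=_num) + "\n")
    return summary


def _num(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(type(x))
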