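"""Hierarchical paired-t differential interaction testing.

Loop scores land on a fine grid by anchor midpoints; fine pairs are grouped
into coarse cells (here 10 kb cells of 1 kb pairs, the locus-scale
geometry) and each cell's matched fine-pair vectors are compared between
conditions with a paired t-test.
"""

import tempfile

import chromarch as ca

cfg = ca.SimConfig(n_chroms=1, chrom_length=8_000_000, n_loops=6000,
                   n_genes=400, n_peaks=300, n_diff_loops=20,
                   diff_loop_fold=4.0, read_depth=5e5, seed=3)
paths, truth = ca.simulate_genome(cfg, tempfile.mkdtemp())

loops = {lab: ca.LoopSet.read_bedpe(paths[f"loops_hic_{lab}"], condition=lab)
         for lab in ("esc", "ncc")}
loops["esc"], loops["ncc"] = ca.normalize_conditions(loops["esc"], loops["ncc"])

grids = {lab: ca.hierarchical_grid(loops[lab], fine=10_000, coarse=100_000)
         for lab in ("esc", "ncc")}
res = ca.paired_t_grid(grids["esc"], grids["ncc"], bonferroni=True)
print(f"{len(res)} coarse cells tested")

for lab in ("esc", "ncc"):
    fav = ca.differential_loops(res, lab)
    strongest = fav.loc[fav["annotated"]].nlargest(1, "mean_delta")
    if len(strongest):
        r = strongest.iloc[0]
        print(f"strongest {lab}-favored cell: {r['chrom1']}:{r['center1']}"
              f" x {r['center2']}, delta {abs(r['mean_delta']):.2f},"
              f" adjusted p {r['p_adj']:.2e}")
print("a single planted loop moves one fine pair, so the per-cell paired t "
      "stays modest here; cells whose whole fine-pair vector shifts (the "
      "calibration setting) reach Bonferroni significance easily.")

net = ca.top_n_network(res, grids["ncc"], "ncc", n=50)
print(f"top-50 ncc-favored network: {len(net.degree)} nodes, "
      f"mean clustering coefficient {net.mean_clustering:.3f}")
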