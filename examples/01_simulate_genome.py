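"""Generate a synthetic two-condition genome and inspect what was planted.

The generator writes the standard formats the pipeline consumes (chrom.sizes,
BED annotations, narrowPeak binding, BEDPE loops, expression and GO TSVs)
and returns the ground truth of the planted structure.
"""

import tempfile

import chromarch as ca

cfg = ca.SimConfig(n_chroms=1, chrom_length=8_000_000, n_loops=5000,
                   n_genes=500, n_peaks=300, n_diff_loops=20,
                   read_depth=3e5, seed=7)
outdir = tempfile.mkdtemp(prefix="chromarch_demo_")
paths, truth = ca.simulate_genome(cfg, outdir)

borders = truth.tad_borders_per_condition["esc"]["chr1"]
print(f"wrote {len(paths)} files under {outdir}")
print(f"planted {len(borders) - 1} TADs in condition 'esc'; "
      f"first three borders at {borders[:3]} bp")
print(f"planted {len(truth.diff_loops)} differential loops "
      f"(fold {cfg.diff_loop_fold}, alternating favored condition)")
print(f"{len(truth.coregulated_gene_groups)} co-regulated gene groups "
      f"(one per TAD, sign agreement ~{cfg.tad_coregulation_prob:.0%})")
# The loop files carry Poisson count-like scores whose total mass per
# condition matches read_depth, with BH q-values against the decay background.
loops = ca.LoopSet.read_bedpe(paths["loops_hic_esc"])
print(f"loop mass: {loops.df['score'].sum():.0f} "
      f"(configured read depth {cfg.read_depth:.0f})")
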