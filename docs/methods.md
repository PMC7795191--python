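# Methods

This note records the models, conventions and design choices behind each
stage of the package, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Coordinates and formats

All coordinates are 0-based half-open, matching BED/BEDPE/narrowPeak
native semantics; 1-based closed coordinates appear nowhere in machine
output. Loop records are a 10-column BEDPE dialect
(`chrom1,start1,end1,chrom2,start2,end2,name,score,q,PETs`) where `score`
is treated as count-like (valid-pair semantics) and `q` is the loop
caller's FDR. Gzipped outputs are written with a fixed gzip mtime so a
fixed seed yields byte-identical files.

## Synthetic two-condition genomes

The generator emulates the statistical structure of a paired chromatin
study, not its sequence content:

- **Contact background.** Intra-chromosomal loop distances follow
  P(d) ∝ d^−α (default α = 1), sampled by inverse CDF on
  [80 kb, L/4]. Loop scores are Poisson draws around the decay ×
  enrichment expectation, scaled so each condition's total score mass
  equals the configured read depth (default 10⁶). Poisson counts keep the
  scores integer-valued like valid-pair counts.
- **Planted TADs.** Domains tile each chromosome with sizes uniform in
  the configured range (240–960 kb by default, multiples of 40 kb).
  Loops with both anchor midpoints in one domain get the within-TAD fold
  (default 3×); anchors within 20 kb of a border get the border fold
  (default 2×). In the second condition a fixed 38% of internal borders
  move by 1–3 bins of 40 kb — the fraction matches the border
  reorganization scale reported for the ESC→NCC transition, so the
  border-comparison stage has realistic work to do.
- **Differential loops.** A configurable number of mid-distance loops
  (default 50) have their expectation multiplied by the differential fold
  (default 4) in alternating favored conditions. Loop q-values are
  Benjamini–Hochberg over Poisson upper-tail p-values against the
  decay-only background — the loop caller whose q the pipeline consumes
  does not publish its definition, so the generator uses this standard
  construction and documents it.
- **Expression.** Genes are placed uniformly and grouped by the TAD
  containing their TSS. Each TAD draws a regulation direction; each gene
  agrees with its TAD's direction with probability
  `tad_coregulation_prob` (default 0.8). |log2FC| ~ |N(1.5, 0.5)|,
  baseline FPKM lognormal(μ=1, σ=1), and strongly regulated genes
  (|log2FC| > 1) receive small per-gene q values.
- **Binding peaks.** Per protein and condition, peaks mix a
  border-proximal component (±20 kb) with a uniform background; the
  mixture weight is solved so border peak density is the configured fold
  (default 5×) of the genome-wide density.
- **GO labels.** Each TAD draws a category from the direction-matched
  half of a 10-category vocabulary (proliferation/metabolic-type for
  down-regulated TADs, developmental/neuronal-type for up-regulated);
  genes inherit their TAD's category with probability 0.8. This plants
  the positional category clustering the GO-profile stage detects.
- **RNG discipline.** Every output artifact draws from its own stream,
  derived from the master seed and a stable label (CRC32), so adding an
  artifact never changes the others; identical seeds give byte-identical
  files.

What the generator does **not** emulate: sequence-dependent mappability
and low-copy-repeat artifacts, restriction-fragment granularity,
inter-chromosomal truth structure beyond background, replicate structure,
or the empirical score/FDR joint distribution of a real loop caller.
Passing tests therefore demonstrate the correctness and calibration of
the machinery on data with known truth, not the pipeline's biological
conclusions on real libraries.

## Genome binning

Score overlays add an interval's **full score** to every bin it touches —
presence-based, no length proration — because anchor-strength semantics
are presence-based; a proration switch is not offered, but the per-bp
span overlay covers the length-weighted case. Span overlays cap at the
bin width (1000 bp per 1 kb bin) so features that legitimately recur at a
locus cannot count a base twice. Anchor strength adds a loop's score once
per anchor overlapping a bin; a loop whose anchors share a bin counts
twice there (`dedupe_anchors=True` collapses this). Between-condition
normalization is deterministic linear scaling of the larger valid-pair
mass to the smaller; a seeded binomial subsampler is available for
sensitivity checks.

## TAD calling

DI uses the Dixon statistic on 40 kb bins with a 2 Mb window; bins near
chromosome edges use the truncated window and keep their DI rather than
being masked, so telomeric domains are not lost. Boundary calling is a
deterministic run-segmentation of sign(DI): values with |DI| below
0.2 × median|DI| are neutral, runs must sustain ≥ 2 bins, a domain opens
at the first bin of a sustained positive run and closes at the last bin
of the last sustained negative run before the next positive run, and
domains shorter than 3 bins (120 kb) are dropped. An HMM could be swapped
in behind the same interface; the run-based caller was chosen because it
is exactly reproducible, property-testable, and recovers ≥ 90% of planted
borders within ±1 bin at 5× enrichment and 10⁶ depth. Border comparison
is directional (each A border to its nearest B border, ties toward the
lower coordinate), with "changed" meaning a distance of at least one bin.

## Differential interactions

Loops are assigned to fine bins by their anchor midpoints (single,
unambiguous assignment). Off-diagonal coarse cells hold the full
(coarse/fine)² fine-pair vector — 100 values for the 100 kb/1 Mb
geometry; diagonal cells hold the upper triangle including the diagonal,
so no mirrored fine pair is counted twice (their paired test runs on that
shorter matched vector). Cells with all-zero differences report p = 1;
zero-variance non-zero differences are flagged degenerate with p = 0.
Genome-wide scans default to uncorrected p (at millions of cells a
Bonferroni threshold is hopeless and display scaling by p is the intended
consumer); locus-scale and border-aligned analyses default to Bonferroni.
Per-cell significance requires a coherent shift of the cell's fine-pair
vector; a single differential loop moves one fine pair and shows up in
the condition-favored delta lists rather than the t-test tail.

Network metrics (degree, local clustering coefficient as triangles over
possible triangles) are computed internally from the adjacency matrix;
ranking for the top-N network uses per-cell mean fine-pair strength in
the favored condition with coordinate tie-breaks.

## Pile-ups and enrichment

All pile-ups are loci × offset-bin matrices with an explicit mask;
masked cells (off-chromosome, or interior offsets past a TAD's own
midpoint) never enter any summary, which is enforced by sentinel tests.
Differential-TAD orientation is the sign of the summed strand-directional
span (gene length, negative on the minus strand) of the TAD's
significantly (q < 0.05) direction-consistent genes, normalized by TAD
length; TADs with no qualifying gene default to forward and are flagged.
Flipping is an exact mirror about the border (an involution). Split-TAD
alignment removes the middle of domains longer than 2 Mb (each side
contributes its outer 1 Mb). Same-size stacking sorts rows by mean sort
attribute and correlates 5-TAD binned row means by default; note that
binning rows in groups of k shrinks the noise variance k-fold and inflates
the Pearson estimate relative to the per-TAD coupling, so the planted-
coupling recovery check runs unbinned (`rows_per_point=1`).

Ranked co-regulated interactions sum per-anchor log2 fold changes of
direction-consistent genes only (condition-B-over-A for "up", negated for
"down"); a gene counts when its body overlaps the anchor (TSS-only mode
available), and a gene in both anchors counts twice, one contribution per
anchor. Greedy selection down the ranking enforces the 2.5 Mb midpoint
spacing per chromosome.

Z-score profiles use the sample (n−1) standard deviation over the
profile's own bins and the two-tailed standard-normal tail; a constant
profile reports z = 0, p = 1. GO positional profiles divide per-bin
category counts by the per-bin gene total (per-span denominator
available), set gene-free bins to 0, and subtract the span mean so every
profile sums to zero. The motif/k-mer border scan samples fixed-length
windows uniformly within each 10 kb bin over ±195 kb, scans supplied
position-weight matrices at a log-odds threshold of 80% of the maximum
score (de novo discovery is out of scope — the scanner is pluggable over
supplied matrices), drops motifs counted ≤ 10 times total, z-scores mean
counts across bins and Bonferroni-adjusts over retained motifs. The
published sampling depths (50 iterations × 10 repeats × 1000 draws;
500 000 k-mer draws) are the defaults; tests and the acceptance script run
reduced depths (e.g. 5 × 2 × 50), which already separate a 10× planted
border motif at adjusted p < 0.05.

## Expression prediction

Two-window features are window-mass concentrations (attribute sum divided
by window width) for an inner and an outer centered window; even window
widths take one extra bin on the right. Centers whose outer window exits
the chromosome are dropped. FPKM class boundaries are [0,1), [1,30],
(30,∞) — the verbal scheme "<1, 1–30, >30" leaves the endpoints open, so
both endpoints of the middle class are closed here and documented.
Interaction classes split at the mean with ties to the lower class.
Features are standardized on the training split before fitting: score and
span concentrations live on scales three orders of magnitude apart and
unscaled ridge penalties would crush one group. The default evaluation
classifier is a deterministic multinomial logistic regression (C = 10⁴,
lbfgs); the 7-layer ReLU network (64, 24, 24, 12, 12, 10, 8 hidden units,
softmax output) is available as `model="mlp"` but its SGD training is
stochastic, so the deterministic fallback is the tested surface. PCA of
the bin × attribute matrix is a thin standardized-PCA utility whose
loadings carry the attribute correlations.

## qPCR quantification

The three printed formulas are implemented verbatim (no additional
control-template normalization is applied beyond the stated reference
CT). Technical replicates are averaged within each biological replicate
before any statistic — the plate structure fixes which CTs are technical,
and averaging first keeps the biological replicate the unit of analysis.
The two-way ANOVA pooled error is the cell-means residual over all
condition × treatment groups; Fisher's LSD contrasts use that MSE and
residual df, which in a two-group design reduces exactly to the pooled-
variance t-test. Fold-change SEMs use the delta method on the ratio of
means.

## Problem sizes and runtime

The test suite and acceptance script run on deliberately scaled-down
genomes — 4–20 Mb chromosomes, 2 000–20 000 loops, read depth 10⁵–2×10⁶,
2 000–2 500 grid cells, reduced motif-sampling depths — chosen so planted
effects sit at the same signal-to-noise regime the methods target while a
full run stays in the minutes range on one CPU. The statistical
guarantees verified (oracle equality, ≥ 90% border recovery, 3–7% null
rates, planted-coupling recovery within ±0.07) are size-stable under
these conditions.

## Known limitations

- The run-segmentation TAD caller has no nesting/hierarchy and no
  compartment (A/B eigenvector) analysis; matrix balancing (ICE/KR) is
  out of scope.
- The paired-t grid treats fine-pair values as exchangeable within a
  cell; strong within-cell distance gradients make the null conservative
  at coarse geometries.
- The motif scan detects enrichment of supplied matrices only; de novo
  discovery is explicitly not reimplemented.
- The synthetic generator's couplings are first-order (block enrichment,
  sign agreement, density mixtures); it does not reproduce higher-order
  features of real chromatin data such as loop extrusion stripes or
  compartment checkerboards.
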