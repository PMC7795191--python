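"""Build the 1 kb binned genome and compute interaction anchor strength.

Score columns sum the full score of every overlapping record per bin;
span columns count overlap base pairs capped at the bin width; anchor
strength adds each loop's score once per anchor overlapping a bin.
"""

import pandas as pd

import chromarch as ca

table = ca.bin_genome({"chr1": 10_000}, bin_width=1000)

promoters = pd.DataFrame({"chrom": ["chr1", "chr1"],
                          "start": [200, 2_900], "end": [700, 3_400]})
ca.overlay_span(table, promoters, "promoter")

loops = ca.LoopSet(pd.DataFrame({
    "chrom1": ["chr1"], "start1": [0], "end1": [1_500],
    "chrom2": ["chr1"], "start2": [1_200], "end2": [2_500],
    "name": ["loopA"], "score": [3.0], "q": [1e-4], "pets": [3]}))
ca.anchor_strength(table, loops, "anchor_strength")

print(table.df[["chrom", "start", "end", "promoter", "anchor_strength"]].head(4))
print("bin 1 holds both anchors' overlap, so it carries 2 x score = 6;")
print("the promoter split 200-700 / 2900-3400 contributes 500 bp to bins 0, 2 and 3.")

# normalizing two libraries scales the larger valid-pair mass down
big = loops.scaled(2.0)
big.total_valid_pairs, loops.total_valid_pairs = 2e6, 1e6
a, b = ca.normalize_conditions(big, loops)
print(f"after normalization both masses equal: {a.mass:.0f} vs {b.mass:.0f}")
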