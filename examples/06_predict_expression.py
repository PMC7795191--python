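"""Predict expression class from two-window genomic features.

Inner/outer window concentrations of promoter span and binding signal are
the features; the label is the 3-class FPKM scheme (<1, 1-30, >30). With a
deterministic class structure the fallback classifier separates almost
perfectly at 1/1 kb windows.
"""

import numpy as np

import chromarch as ca

rng = np.random.default_rng(0)
n = 5000
table = ca.bin_genome({"chr1": n * 1000}, 1000)
promoter = rng.integers(0, 1001, n).astype(float)
binding = rng.lognormal(0, 1, n)
table.add_column("promoter", promoter)
table.add_column("binding", binding)
density = promoter / 1000.0 + binding
table.add_column("fpkm", np.where(density < 1.0, 0.5,
                                  np.where(density < 2.5, 10.0, 50.0)))

X, idx = ca.two_window_features(table, ["promoter", "binding"],
                                inner=1000, outer=1000)
y = ca.label_bins(table.column("fpkm")[idx], ca.FPKM_3CLASS)
out = ca.train_eval(X, y, seed=1)
print(f"1/1 kb combined features: train accuracy "
      f"{out['train_accuracy']:.3f}, test accuracy {out['test_accuracy']:.3f}")
print("confusion matrix (rows true, cols predicted):")
print(out["confusion_matrix"])
print("near-perfect accuracy reflects the planted deterministic link "
      "between class and local feature density.")
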