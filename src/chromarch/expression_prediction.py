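"""Two-window sliding features and class prediction of expression level.

A pair of centered windows (inner <= outer, in kb) slides across the binned
genome; for each attribute the feature is the attribute mass inside the
window divided by the window width — a concentration, which for span
attributes is a coverage fraction in [0, 1]. Labels are FPKM classes
(2-class <1 / >=1 or 3-class <1 / 1-30 / >30) or a 2-class
below/above-average interaction-score scheme. The default classifier is a
feed-forward network (7 hidden layers of 64, 24, 24, 12, 12, 10 and 8 ReLU
units with a softmax output); a deterministic multinomial-logistic fallback
is provided since network training is stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .genome_binning import GenomeBinTable

MLP_LAYERS = (64, 24, 24, 12, 12, 10, 8)


def two_window_features(table: GenomeBinTable, attrs, inner: int,
                        outer: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Inner/outer window concentrations per centered bin.

    ``inner`` and ``outer`` are window widths in bp (multiples of the bin
    width, ``outer >= inner``). Centers whose outer window exits the
    chromosome are dropped; returns (features, retained row indices into the
    table).
    """
    bw = table.bin_width
    if outer < inner:
        raise ValueError("outer window must be at least the inner window")
    if inner % bw or outer % bw or inner <= 0:
        raise ValueError("window widths must be positive multiples of the bin width")

    def window_sums(track, width):
        w = width // bw
        lo, hi = -(w // 2), -(w // 2) + w
        cs = np.concatenate([[0.0], np.cumsum(track)])
        n = len(track)
        idx = np.arange(n)
        valid = (idx + lo >= 0) & (idx + hi <= n)
        sums = np.zeros(n)
        sums[valid] = cs[(idx + hi)[valid]] - cs[(idx + lo)[valid]]
        return sums, valid

    feats = {}
    keep = None
    for attr in attrs:
        for name, width in ((f"{attr}_inner", inner), (f"{attr}_outer", outer)):
            col_parts, valid_parts = [], []
            for chrom in table.chrom_sizes:
                track = table.chrom_values(attr)[chrom]
                s, v = window_sums(track, width)
                col_parts.append(s / width)
                valid_parts.append(v)
            feats[name] = np.concatenate(col_parts)
            v = np.concatenate(valid_parts)
            keep = v if keep is None else (keep & v)
    idx = np.flatnonzero(keep)
    X = pd.DataFrame({k: v[idx] for k, v in feats.items()})
    return X, idx


@dataclass
class ClassScheme:
    """Strictly increasing boundaries splitting a value into classes."""

    boundaries: tuple
    labels: tuple

    def __post_init__(self):
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one more label than boundaries")


FPKM_2CLASS = ClassScheme((1.0,), ("<1", ">=1"))
# 3-class boundaries: [0,1), [1,30], (30, inf)
FPKM_3CLASS = ClassScheme((1.0, 30.0 + 1e-12), ("<1", "1-30", ">30"))


def label_bins(values, scheme: ClassScheme | str = FPKM_3CLASS) -> np.ndarray:
    """Deterministic class label per bin.

    ``scheme='interaction'`` uses the 2-class below-or-equal / above mean
    interaction-score split (ties go to the lower class).
    """
    values = np.asarray(values, dtype=float)
    if isinstance(scheme, str):
        if scheme != "interaction":
            raise ValueError(f"unknown scheme {scheme!r}")
        mean = values.mean()
        return np.where(values <= mean, "below", "above")
    idx = np.searchsorted(scheme.boundaries, values, side="right")
    return np.asarray(scheme.labels, dtype=object)[idx]


def train_eval(X, y, split_fraction: float = 0.5, seed: int = 0,
               model: str = "logistic", max_iter: int = 500) -> dict:
    """Train a classifier on a random split and report both accuracies.

    The split is a seeded permutation, so a fixed seed reproduces identical
    train/test indices. ``model`` is ``'logistic'`` (deterministic
    multinomial fallback) or ``'mlp'`` (the 7-layer ReLU network).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split contains a single class")
    # features are standardized on the training split: window concentrations
    # of score and span attributes live on very different scales
    if model == "mlp":
        clf = make_pipeline(StandardScaler(), MLPClassifier(
            hidden_layer_sizes=MLP_LAYERS, activation="relu",
            random_state=seed, max_iter=max_iter))
    elif model == "logistic":
        # weak regularization: the fallback should drive a separable
        # threshold to near-perfect accuracy
        clf = make_pipeline(StandardScaler(),
                            LogisticRegression(C=1e4, max_iter=max_iter))
    else:
        raise ValueError(f"unknown model {model!r}")
    clf.fit(X[train_idx], y[train_idx])
    labels = np.unique(y)
    return {
        "train_accuracy": float(clf.score(X[train_idx], y[train_idx])),
        "test_accuracy": float(clf.score(X[test_idx], y[test_idx])),
        "confusion_matrix": confusion_matrix(
            y[test_idx], clf.predict(X[test_idx]), labels=labels),
        "labels": labels,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "model": clf,
    }


def pca_attributes(table: GenomeBinTable, attrs, n_components: int | None = None) -> dict:
    """Standard PCA of the bin x attribute matrix; correlations between
    attributes are read from the loadings."""
    X = np.column_stack([table.column(a) for a in attrs])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return {
        "components": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "loadings": pd.DataFrame(pca.components_.T, index=list(attrs)),
        "scores": scores,
    }
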