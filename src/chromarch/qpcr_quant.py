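"""qPCR quantification: 3C and ChIP percent input, RT relative expression,
replicate aggregation and treatment fold changes.

All three quantities are exponential transforms of cycle thresholds (CT):

* 3C percent input (against a non-digested reference locus):
  ``[100 * 2^(reference CT - interaction CT)] * 100``
* ChIP percent 10% input: ``100 * 2^(10% input CT - IP CT)``
* RT relative expression: ``[100 * 2^(-CT)] * 10^6``

Technical replicates (same plate) are averaged within each biological
replicate before any statistics; treatment fold changes (e.g. an FGFR1
kinase inhibitor versus control) are ratios of biological-replicate means,
tested per target with a two-way ANOVA (condition x treatment cell-means
model) and Fisher's LSD contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _check_ct(*cts) -> None:
    for ct in cts:
        if not np.all(np.isfinite(ct)):
            raise ValueError("CT values must be finite")


def percent_input_3c(reference_ct, interaction_ct):
    """3C percent input relative to a non-digested reference locus."""
    reference_ct = np.asarray(reference_ct, dtype=float)
    interaction_ct = np.asarray(interaction_ct, dtype=float)
    _check_ct(reference_ct, interaction_ct)
    return (100.0 * 2.0 ** (reference_ct - interaction_ct)) * 100.0


def percent_input_chip(input10_ct, ip_ct):
    """ChIP percent input relative to the 10% input sample."""
    input10_ct = np.asarray(input10_ct, dtype=float)
    ip_ct = np.asarray(ip_ct, dtype=float)
    _check_ct(input10_ct, ip_ct)
    return 100.0 * 2.0 ** (input10_ct - ip_ct)


def relative_expression(cdna_ct):
    """RT-qPCR relative expression from the cDNA cycle threshold."""
    cdna_ct = np.asarray(cdna_ct, dtype=float)
    _check_ct(cdna_ct)
    return (100.0 * 2.0 ** (-cdna_ct)) * 1e6


_QUANT = {
    "3C": lambda df: percent_input_3c(df["ref_ct"], df["ct"]),
    "ChIP": lambda df: percent_input_chip(df["ref_ct"], df["ct"]),
    "RT": lambda df: relative_expression(df["ct"]),
}


def quantify(samples: pd.DataFrame) -> pd.DataFrame:
    """Apply the per-assay formula, producing a ``quantity`` column."""
    out = samples.copy()
    out["quantity"] = np.nan
    for assay, fn in _QUANT.items():
        sel = out["assay"] == assay
        if sel.any():
            sub = out.loc[sel]
            if assay in ("3C", "ChIP") and ("ref_ct" not in sub or sub["ref_ct"].isna().any()):
                raise ValueError(f"{assay} samples require a reference CT")
            out.loc[sel, "quantity"] = np.asarray(fn(sub), dtype=float)
    unknown = set(out["assay"]) - set(_QUANT)
    if unknown:
        raise ValueError(f"unknown assay types: {sorted(unknown)}")
    return out


def aggregate_and_compare(samples: pd.DataFrame,
                          control_label: str = "control") -> dict:
    """Per-target replicate aggregation, fold changes and LSD p-values.

    ``samples`` is long-format with columns assay, condition, treatment,
    target, bio_rep, tech_rep, ct (and ref_ct for 3C/ChIP). Technical
    replicates are averaged within biological replicates first; per target,
    group means +- SEM per (condition, treatment), treated/control fold
    changes (SEM via the delta method), and Fisher's LSD p per
    treated-vs-control contrast from the two-way ANOVA pooled error.
    """
    q = quantify(samples)
    bio = (q.groupby(["assay", "target", "condition", "treatment", "bio_rep"],
                     sort=False)["quantity"].mean().reset_index())

    summaries, contrasts = [], []
    for (assay, target), grp in bio.groupby(["assay", "target"], sort=False):
        groups = {key: g["quantity"].to_numpy()
                  for key, g in grp.groupby(["condition", "treatment"], sort=False)}
        if any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"target {target!r}: need >=2 biological replicates per cell")
        # cell-means two-way ANOVA pooled error
        n_total = sum(len(v) for v in groups.values())
        df_resid = n_total - len(groups)
        ss_resid = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        mse = ss_resid / df_resid if df_resid > 0 else np.nan
        for (cond, treat), v in groups.items():
            summaries.append({
                "assay": assay, "target": target, "condition": cond,
                "treatment": treat, "n": len(v), "mean": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(len(v)),
            })
        for cond in sorted({c for c, _ in groups}):
            ctrl = groups.get((cond, control_label))
            if ctrl is None:
                continue
            for (c, treat), v in groups.items():
                if c != cond or treat == control_label:
                    continue
                fold = v.mean() / ctrl.mean()
                # delta-method SEM of the ratio of means
                sem = fold * np.sqrt(
                    (v.std(ddof=1) ** 2 / len(v)) / v.mean() ** 2
                    + (ctrl.std(ddof=1) ** 2 / len(ctrl)) / ctrl.mean() ** 2)
                if mse > 0:
                    t = (v.mean() - ctrl.mean()) / np.sqrt(
                        mse * (1.0 / len(v) + 1.0 / len(ctrl)))
                    p = 2.0 * stats.t.sf(abs(t), df_resid)
                else:
                    t, p = 0.0, 1.0
                contrasts.append({
                    "assay": assay, "target": target, "condition": cond,
                    "treatment": treat, "fold_change": fold,
                    "fold_sem": sem, "t": t, "df": df_resid, "p": p,
                })
    return {"summary": pd.DataFrame(summaries),
            "contrasts": pd.DataFrame(contrasts)}
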