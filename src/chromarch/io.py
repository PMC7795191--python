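"""Readers and writers for the plain-text genomics formats the pipeline uses.

All coordinates are 0-based half-open (BED native). Supported formats:
UCSC chrom.sizes, BED6, ENCODE narrowPeak (BED6+4), a 10-column BEDPE
dialect carrying a loop score and FDR q, and TSV expression / GO tables.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLS = BED6_COLS + ["signal", "pvalue", "qvalue", "peak"]
BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "q", "pets",
]
EXPRESSION_COLS = [
    "gene", "chrom", "start", "end", "strand",
    "fpkm_a", "fpkm_b", "log2fc", "q",
]


def read_chrom_sizes(path) -> dict:
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split()[:2]
        sizes[chrom] = int(size)
    if not sizes:
        raise ValueError(f"empty chrom.sizes file: {path}")
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{int(s)}\n" for c, s in sizes.items())
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = NARROWPEAK_COLS
    return df


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    df[NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_expression(path) -> pd.DataFrame:
    """Expression table: gene, coordinates, strand, per-condition FPKM,
    log2 fold change (condition B over A) and per-gene FDR q."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "chrom", "start", "end", "log2fc", "q") if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    return df


def read_go_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "category"} <= set(df.columns):
        raise ValueError("GO table needs 'gene' and 'category' columns")
    return df


def write_table(df: pd.DataFrame, path, **kwargs) -> None:
    """TSV writer, gzip-aware by file extension.

    Gzip members are written with a fixed mtime so identical content gives
    byte-identical files across runs.
    """
    import io as _io
    path = str(path)
    if path.endswith(".gz"):
        with gzip.GzipFile(path, "wb", mtime=0) as gz:
            with _io.TextIOWrapper(gz, encoding="utf8", newline="") as fh:
                df.to_csv(fh, sep="\t", index=False, **kwargs)
    else:
        df.to_csv(path, sep="\t", index=False, **kwargs)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
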