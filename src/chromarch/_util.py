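"""Small shared helpers: seeded RNG streams and formatting."""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from a master seed and a stable label.

    Each output artifact draws from its own stream so that adding a new
    artifact never perturbs the random numbers of the existing ones.
    """
    return np.random.default_rng([int(seed), zlib.crc32(label.encode("utf8"))])


def fmt(x) -> str:
    """Stable text rendering for floats written to TSV outputs."""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"
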