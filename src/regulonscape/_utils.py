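"""Shared helpers: seed derivation and BH adjustment conventions."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests


def child_seed(global_seed: int, stage: str) -> int:
    """Derive a stage-specific seed from a global seed.

    Uses CRC32 of the stage name (stable across processes, unlike ``hash``)
    mixed with the global seed; result is always in [0, 2**31).
    """
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode("utf8"))) % (2**31)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs pass through untouched."""
    p = np.asarray(pvals, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj
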