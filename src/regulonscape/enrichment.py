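"""Preranked gene-set enrichment: weighted KS-style running statistic,
permutation null, NES and BH-FDR, with the significance filter
FDR < 0.05 and |NES| > 1.

The running statistic walks the ranking from top to bottom, adding
|stat|^p / sum(|stat|^p over hits) at gene-set members and subtracting
1/(N - |S|) at misses; the enrichment score (ES) is the signed extremum of
the walk.  The null draws random same-size gene sets from the ranked list
(gene permutation, as is standard for preranked input); NES divides ES by
the mean magnitude of same-sign null scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import bh_adjust


def _sorted_ranking(ranked) -> pd.Series:
    s = pd.Series(ranked, dtype=float) if not isinstance(ranked, pd.Series) else ranked.astype(float)
    if s.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("ranking statistics must be finite")
    order = np.lexsort((s.index.astype(str), -s.to_numpy()))
    return s.iloc[order]


def enrichment_score(ranked, gene_set, weight_p: float = 1.0):
    """ES, the full running profile, and the leading-edge genes.

    ``ranked`` is a gene -> statistic mapping (sorted internally, descending,
    ties broken by gene id for determinism).
    """
    s = _sorted_ranking(ranked)
    genes = s.index.to_numpy()
    hit = np.isin(genes, list(gene_set))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == len(s):
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    w = np.abs(s.to_numpy()) ** weight_p
    wsum = w[hit].sum()
    if wsum == 0:
        # all hit statistics are exactly zero; fall back to unweighted steps
        w = np.ones_like(w)
        wsum = float(n_hits)
    steps = np.where(hit, w / wsum, -1.0 / (len(s) - n_hits))
    running = np.cumsum(steps)
    i_ext = int(np.abs(running).argmax())
    es = float(running[i_ext])
    if es >= 0:
        leading = genes[: i_ext + 1][hit[: i_ext + 1]].tolist()
    else:
        leading = genes[i_ext + 1:][hit[i_ext + 1:]].tolist()
    return es, running, leading


def _es_batch(positions: np.ndarray, w: np.ndarray, N: int) -> np.ndarray:
    """ES for many hit-position sets at once.

    ``positions``: (n_sets, m) 0-based positions in the ranking (any order);
    ``w``: per-position weights |stat|^p.  The extrema of the running walk
    occur immediately after a hit (maxima) or just before one (minima), so
    only those 2m candidate values need evaluating per set.
    """
    pos = np.sort(positions, axis=1)
    m = pos.shape[1]
    pw = w[pos]
    wsum = pw.sum(axis=1, keepdims=True)
    zero = (wsum == 0).ravel()
    if zero.any():
        pw[zero] = 1.0
        wsum = pw.sum(axis=1, keepdims=True)
    cumw = np.cumsum(pw, axis=1) / wsum
    i = np.arange(m)
    miss = (pos - i) / (N - m)         # misses encountered before hit i
    after = cumw - miss                # running value right after hit i
    before = np.concatenate([np.zeros((pos.shape[0], 1)), cumw[:, :-1]], axis=1) - miss
    cand = np.concatenate([after, before], axis=1)
    idx = np.abs(cand).argmax(axis=1)
    return cand[np.arange(cand.shape[0]), idx]


def preranked_gsea(
    ranked,
    sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    fdr_threshold: float = 0.05,
    nes_threshold: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    Null ES per set come from ``n_perm`` random same-size draws from the
    ranked list; NES = ES / mean|same-sign null ES|; the raw p-value is the
    fraction of same-sign null scores at least as extreme; BH correction is
    applied across sets.  ``significant`` flags FDR < 0.05 AND |NES| > 1.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    s = _sorted_ranking(ranked)
    N = len(s)
    genes = s.index.to_numpy()
    w = np.abs(s.to_numpy()) ** weight_p
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in sets.items():
        inter = np.flatnonzero(np.isin(genes, list(members)))
        size = len(inter)
        if size < min_size or size > max_size or size == N:
            continue
        es, _, leading = enrichment_score(s, [genes[i] for i in inter], weight_p=weight_p)
        null_pos = np.stack([rng.choice(N, size=size, replace=False) for _ in range(n_perm)])
        null_es = _es_batch(null_pos, w, N)
        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes, p = np.nan, 1.0
        else:
            mean_mag = np.abs(null_es[same]).mean()
            nes = es / mean_mag if mean_mag > 0 else np.nan
            # add-one (permutation-validity) estimate of the tail fraction
            p = float(((np.abs(null_es[same]) >= abs(es)).sum() + 1) / (n_same + 1))
        rows.append(
            {"name": name, "size": size, "ES": es, "NES": nes, "pvalue": p,
             "leading_edge": ",".join(leading)}
        )
    if not rows:
        raise ValueError("no testable gene sets after size filtering")
    out = pd.DataFrame(rows).set_index("name")
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = (out["fdr"] < fdr_threshold) & (out["NES"].abs() > nes_threshold)
    return out
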