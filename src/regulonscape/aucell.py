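"""Per-cell regulon activity via the area under the gene-ranking recovery curve.

Each cell's genes are ranked by descending expression (rank 1 = highest,
ties — including the dominant zero block — broken by a seeded shuffle).  For
a gene set S and a top fraction of the ranking T = ceil(top_frac * G), the
recovery curve counts the members of S found among the top t genes for
t = 1..T-1; the activity score is the area under this step curve normalized
by its maximum, so scores live in [0, 1] and depend on the expression values
only through the within-cell ranking.  This rank-based construction is
robust to dropout of individual genes and to any monotone transform of a
cell's expression profile.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import bh_adjust


def rank_genes_per_cell(norm: pd.DataFrame, tie_seed: int = 0) -> pd.DataFrame:
    """Within-cell expression ranks (1 = highest), random tie-break.

    Ties are broken by a seeded random shuffle so the rank matrix is a
    proper permutation per cell even for the zero block; deterministic for a
    fixed ``tie_seed``.
    """
    if norm.shape[0] == 0 or norm.shape[1] == 0:
        raise ValueError("empty expression matrix")
    X = norm.to_numpy(dtype=float)
    rng = np.random.default_rng(tie_seed)
    tiebreak = rng.random(X.shape)
    ranks = np.empty(X.shape, dtype=np.int32)
    ar = np.arange(1, X.shape[1] + 1, dtype=np.int32)
    for i in range(X.shape[0]):
        order = np.lexsort((tiebreak[i], -X[i]))
        ranks[i, order] = ar
    out = pd.DataFrame(ranks, index=norm.index, columns=norm.columns)
    out.attrs["tie_seed"] = int(tie_seed)
    return out


def aucell_score(ranks: pd.DataFrame, gene_set: list[str], top_frac: float = 0.05) -> np.ndarray:
    """Per-cell AUC of the recovery curve of ``gene_set`` over the top
    ``top_frac`` of each cell's ranking.

    With G genes, T = ceil(top_frac*G) and usable set S:
    raw = sum_{t=1}^{T-1} |{g in S : rank_g <= t}|, normalized by
    max = sum_{t=1}^{T-1} min(t, |S|).
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    G = ranks.shape[1]
    T = math.ceil(top_frac * G)
    if T < 2:
        raise ValueError(f"top fraction {top_frac} of {G} genes gives T={T} < 2 ranks")
    usable = [g for g in gene_set if g in ranks.columns]
    dropped = len(gene_set) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} gene(s) of the set absent from the matrix; dropped")
    if not usable:
        raise ValueError("gene set has no overlap with the gene universe")
    R = ranks[usable].to_numpy()
    # sum over t of hits(t) telescopes to sum over hit genes of (T - rank)
    raw = np.where(R <= T - 1, T - R, 0).sum(axis=1)
    m = len(usable)
    t = np.arange(1, T)
    max_raw = np.minimum(t, m).sum()
    return raw / max_raw


def score_all(ranks: pd.DataFrame, regulons: dict[str, list[str]], top_frac: float = 0.05) -> pd.DataFrame:
    """AUC scores for every regulon; columns follow the input order.

    A regulon with no usable genes yields a NaN column plus a warning.
    """
    cols = {}
    for name, genes in regulons.items():
        try:
            cols[name] = aucell_score(ranks, genes, top_frac)
        except ValueError as err:
            if "no overlap" in str(err):
                warnings.warn(f"regulon {name!r} has no usable genes; column set to NaN")
                cols[name] = np.full(ranks.shape[0], np.nan)
            else:
                raise
    auc = pd.DataFrame(cols, index=ranks.index)
    auc.attrs["top_frac"] = float(top_frac)
    return auc


class AUCellScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a cells x genes matrix to cells x regulons AUCs.

    Parameters
    ----------
    regulons : mapping of regulon name -> target gene list.
    top_frac : fraction of the ranking integrated (default 0.05).
    tie_seed : seed for the rank tie-break shuffle.
    """

    def __init__(self, regulons: dict[str, list[str]], top_frac: float = 0.05, tie_seed: int = 0):
        self.regulons = regulons
        self.top_frac = top_frac
        self.tie_seed = tie_seed

    def fit(self, X: pd.DataFrame, y=None) -> "AUCellScorer":
        X = self._as_frame(X)
        universe = set(X.columns)
        self.genes_ = list(X.columns)
        self.usable_regulons_ = {
            name: [g for g in genes if g in universe] for name, genes in self.regulons.items()
        }
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "usable_regulons_"):
            raise RuntimeError("AUCellScorer is not fitted")
        X = self._as_frame(X)
        ranks = rank_genes_per_cell(X, tie_seed=self.tie_seed)
        return score_all(ranks, self.regulons, top_frac=self.top_frac)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X))


def differential_activity(values: pd.DataFrame, labels) -> pd.DataFrame:
    """Kruskal-Wallis test of each feature across >= 2 groups with BH
    correction across features; all-identical features come back NaN."""
    labels = np.asarray(labels)
    if len(labels) != values.shape[0]:
        raise ValueError("labels must match cell count")
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
    if values.shape[1] == 0:
        raise ValueError("empty feature set")
    stats_out, pvals, medians = [], [], []
    for feat in values.columns:
        x = values[feat].to_numpy()
        samples = [x[labels == g] for g in groups]
        if np.all(x == x[0]) or np.isnan(x).any():
            stats_out.append(np.nan)
            pvals.append(np.nan)
        else:
            h, p = stats.kruskal(*samples)
            stats_out.append(h)
            pvals.append(p)
        medians.append([float(np.median(s)) for s in samples])
    out = pd.DataFrame(
        {"statistic": stats_out, "pvalue": pvals, "padj": bh_adjust(np.array(pvals))},
        index=values.columns,
    )
    med = pd.DataFrame(medians, index=values.columns, columns=[f"median_{g}" for g in groups])
    return pd.concat([out, med], axis=1)


def summarize_by_cluster(
    values: pd.DataFrame,
    labels,
    stat: str = "mean",
    row_scale: str | None = "z",
) -> pd.DataFrame:
    """Per-cluster mean/median of each feature, optionally z-scaled across
    clusters for display (0 where the across-cluster stdev is 0)."""
    labels = np.asarray(labels)
    if len(labels) != values.shape[0]:
        raise ValueError("labels must match cell count")
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    agg = values.groupby(labels).agg(stat)
    agg = agg.sort_index()
    if row_scale == "z":
        mu = agg.mean(axis=0)
        sd = agg.std(axis=0, ddof=0)
        agg = (agg - mu).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    elif row_scale is not None:
        raise ValueError("row_scale must be 'z' or None")
    return agg
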