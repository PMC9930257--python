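"""Cell-specific networks (CSN): per-cell gene-gene association statistics,
edge significance, the network degree matrix (NDM), and differential
connectivity between cell clusters.

For a pair of genes (x, y) and a focal cell k, marginal neighborhoods
("boxes") around cell k are drawn in each gene's expression dimension so
that each contains about box_frac * n cells; with n_x, n_y cells in the two
marginal boxes and n_xy in their intersection, the statistic

    rho_xy(k) = sqrt(n-1) * (n * n_xy - n_x * n_y)
                / sqrt(n_x * n_y * (n - n_x) * (n - n_y))

is asymptotically standard normal when x and y are independent.  For the
per-edge decision the focal cell (which always sits inside both of its own
boxes) is removed from the counts; conditional on the box sizes the
remaining overlap n_xy - 1 is then exactly Hypergeometric(n-1, n_x-1,
n_y-1) under independence, and an edge is declared in cell k by the exact
upper-tail test at the chosen significance level (the normal-quantile rule
applied to the raw statistic is biased upward by about 0.4 standard
deviations, because the focal cell always contributes to the overlap).
The NDM entry for (gene, cell) is the gene's
number of significant edges in that cell — a per-cell connectivity profile
that can be compared between clusters with rank tests.

Box construction works in rank space: ties (in particular the dominant
zero block of scRNA-seq data) are broken by a per-gene seeded shuffle, and
the box around cell k is the smallest symmetric-in-rank window centred on
k's rank holding at least ceil(box_frac * n) cells.  Breaking ties rather
than including whole tie blocks keeps every box at its nominal size: a tie
block admitted wholesale would turn the shared dropout mass of two sparse
genes into an enormous always-overlapping neighborhood, flooding inactive
cells with "coordinated silence" edges and drowning the expression-level
associations the method is after.  The shuffle is independent across genes
(so subsampled tie blocks do not artificially co-occupy) and deterministic
under ``tie_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import bh_adjust


@dataclass
class CsnParams:
    box_frac: float = 0.1
    alpha: float = 0.01
    gene_subset: list[str] | None = None
    tie_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.box_frac <= 1:
            raise ValueError("box_frac must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class CsnResult:
    edges: pd.DataFrame            # columns: cell_id, gene_a, gene_b, rho (a < b)
    ndm: pd.DataFrame              # genes x cells significant-edge degree counts
    params: CsnParams
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)


def box_membership(values, k: int, box_frac: float = 0.1, tie_seed: int = 0) -> np.ndarray:
    """Indices of the cells in the rank-window box around cell ``k`` for one
    gene; ties broken by a seeded shuffle, ``k`` always a member."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty expression vector")
    rng = np.random.default_rng(tie_seed)
    return np.flatnonzero(_box_masks(values, box_frac, rng)[k])


def _box_masks(values: np.ndarray, box_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean n x n matrix; row k marks the members of cell k's box."""
    n = len(values)
    m = min(math.ceil(box_frac * n), n)
    # strict ranks, ties broken by a seeded shuffle so boxes keep nominal size
    order = np.lexsort((rng.random(n), values))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    dist = np.abs(ranks[:, None] - ranks[None, :])
    # half-width per focal cell: the m-th smallest rank distance in its row
    h = np.partition(dist, m - 1, axis=1)[:, m - 1]
    return dist <= h[:, None]


def csn_statistic(n, n_x, n_y, n_xy):
    """The per-cell association statistic; standard normal under independence.

    Accepts scalars or aligned arrays.  Undefined when a marginal box is
    empty or covers all cells (n_x or n_y in {0, n}); those entries come
    back NaN and must be treated as untestable.
    """
    n = np.asarray(n, dtype=float)
    n_x = np.asarray(n_x, dtype=float)
    n_y = np.asarray(n_y, dtype=float)
    n_xy = np.asarray(n_xy, dtype=float)
    denom_sq = n_x * n_y * (n - n_x) * (n - n_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.sqrt(n - 1) * (n * n_xy - n_x * n_y) / np.sqrt(denom_sq)
        rho = np.where(denom_sq > 0, rho, np.nan)
    return rho if rho.ndim else float(rho)


def build_csn(norm: pd.DataFrame, params: CsnParams | None = None) -> CsnResult:
    """Compute boxes, counts and the statistic for every unordered gene pair
    (within ``params.gene_subset`` if given) in every cell; collect the
    significant edges and the NDM.

    An edge is significant in cell k iff rho > z_(1-alpha) (upper tail).
    Untestable pairs (degenerate boxes) are never significant.
    """
    params = params or CsnParams()
    genes = list(params.gene_subset) if params.gene_subset is not None else [str(g) for g in norm.columns]
    missing = [g for g in genes if g not in norm.columns]
    if missing:
        raise ValueError(f"subset genes missing from matrix: {missing[:5]}")
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    n = norm.shape[0]
    if n < math.ceil(1 / params.box_frac):
        raise ValueError(f"need at least {math.ceil(1 / params.box_frac)} cells for box_frac={params.box_frac}")

    X = norm[genes].to_numpy(dtype=float)
    rng = np.random.default_rng(params.tie_seed)
    masks = np.stack([_box_masks(X[:, j], params.box_frac, rng) for j in range(len(genes))])
    counts = masks.sum(axis=2).astype(np.int64)  # genes x cells marginal box sizes

    # exact conditional test: critical overlap per (n_x, n_y) box-size pair
    crit_cache: dict[tuple[int, int], int] = {}

    def critical(nx: int, ny: int) -> int:
        key = (nx, ny) if nx <= ny else (ny, nx)
        if key not in crit_cache:
            # smallest c with P(Hypergeom(n-1, nx-1, ny-1) >= c) <= alpha
            crit_cache[key] = int(
                stats.hypergeom.isf(params.alpha, n - 1, key[0] - 1, key[1] - 1) + 1
            )
        return crit_cache[key]

    G = len(genes)
    ndm = np.zeros((G, n), dtype=np.int64)
    rows_cell, rows_a, rows_b, rows_rho = [], [], [], []
    cells = np.arange(n)
    for a in range(G):
        Ma = masks[a]
        na = counts[a]
        for b in range(a + 1, G):
            nb = counts[b]
            nab = (Ma & masks[b]).sum(axis=1)
            # leave the focal cell out of all counts; it is always in both boxes
            rho = csn_statistic(n - 1, na - 1, nb - 1, nab - 1)
            testable = (na > 1) & (na < n) & (nb > 1) & (nb < n)
            keys = na * (n + 1) + nb
            crits = np.full(n, n, dtype=np.int64)
            for key in np.unique(keys[testable]):
                kx, ky = divmod(int(key), n + 1)
                crits[keys == key] = critical(kx, ky)
            sig = testable & (nab - 1 >= crits)
            if sig.any():
                ndm[a, sig] += 1
                ndm[b, sig] += 1
                idx = cells[sig]
                rows_cell.append(idx)
                rows_a.append(np.full(len(idx), a))
                rows_b.append(np.full(len(idx), b))
                rows_rho.append(np.asarray(rho)[sig])

    cell_ids = [str(c) for c in norm.index]
    if rows_cell:
        cat = np.concatenate
        edges = pd.DataFrame(
            {
                "cell_id": np.asarray(cell_ids, dtype=object)[cat(rows_cell)],
                "gene_a": np.asarray(genes, dtype=object)[cat(rows_a)],
                "gene_b": np.asarray(genes, dtype=object)[cat(rows_b)],
                "rho": cat(rows_rho),
            }
        )
    else:
        edges = pd.DataFrame(columns=["cell_id", "gene_a", "gene_b", "rho"])
    ndm_df = pd.DataFrame(ndm, index=genes, columns=cell_ids)
    return CsnResult(edges=edges, ndm=ndm_df, params=params, gene_ids=genes, cell_ids=cell_ids)


class CellSpecificNetwork(BaseEstimator, TransformerMixin):
    """Transformer mapping a cells x genes matrix to its cells x genes NDM.

    ``fit`` runs the full per-cell network construction and stores the
    result (``result_``); ``transform`` returns the NDM transposed to
    cells x genes so it composes with sklearn pipelines.
    """

    def __init__(self, box_frac: float = 0.1, alpha: float = 0.01,
                 gene_subset: list[str] | None = None):
        self.box_frac = box_frac
        self.alpha = alpha
        self.gene_subset = gene_subset

    def fit(self, X: pd.DataFrame, y=None) -> "CellSpecificNetwork":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        self.result_ = build_csn(
            X, CsnParams(box_frac=self.box_frac, alpha=self.alpha, gene_subset=self.gene_subset)
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("CellSpecificNetwork is not fitted")
        return self.result_.ndm.T

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def ndm(result: CsnResult) -> pd.DataFrame:
    """Recompute the genes x cells NDM from the stored significant edges.

    Satisfies the handshake identity: each cell's NDM column sums to twice
    its significant-edge count.
    """
    out = pd.DataFrame(
        np.zeros((len(result.gene_ids), len(result.cell_ids)), dtype=np.int64),
        index=result.gene_ids, columns=result.cell_ids,
    )
    for col in ("gene_a", "gene_b"):
        tab = result.edges.groupby([col, "cell_id"]).size()
        for (g, c), cnt in tab.items():
            out.loc[g, c] += cnt
    return out


def differential_ndm(ndm_mat: pd.DataFrame, labels, target_cluster) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of each gene's NDM values, target cluster
    vs all other cells, BH-corrected across genes.

    Exact null distribution for small tie-free groups, midrank/normal
    approximation otherwise (scipy's Mann-Whitney U).  Genes whose NDM is
    identical in every cell are reported with p = 1 (no evidence of a
    connectivity shift).
    """
    labels = np.asarray(labels)
    if ndm_mat.shape[1] != len(labels):
        raise ValueError("labels must match NDM cell count")
    in_cluster = labels == target_cluster
    if in_cluster.sum() < 2 or (~in_cluster).sum() < 2:
        raise ValueError("target cluster and complement each need >= 2 cells")
    X = ndm_mat.to_numpy()
    stats_out, pvals, mean_in, mean_out = [], [], [], []
    for i in range(X.shape[0]):
        x, y = X[i, in_cluster], X[i, ~in_cluster]
        mean_in.append(float(x.mean()))
        mean_out.append(float(y.mean()))
        if np.all(X[i] == X[i, 0]):
            stats_out.append(np.nan)
            pvals.append(1.0)
            continue
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        stats_out.append(float(u))
        pvals.append(float(p))
    return pd.DataFrame(
        {
            "statistic": stats_out,
            "pvalue": pvals,
            "padj": bh_adjust(np.array(pvals)),
            "mean_ndm_cluster": mean_in,
            "mean_ndm_rest": mean_out,
        },
        index=ndm_mat.index,
    )


def connectivity_by_cluster(result: CsnResult, labels) -> dict:
    """Per cluster, the fraction of member cells in which each gene pair is
    significant (input to arc diagrams); pairs never significant in a
    cluster report 0."""
    labels = np.asarray(labels)
    if len(labels) != len(result.cell_ids):
        raise ValueError("labels must cover all cells")
    lab_of = dict(zip(result.cell_ids, labels))
    clusters = pd.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in clusters}
    pairs = sorted(
        set(zip(result.edges["gene_a"], result.edges["gene_b"]))
    ) if len(result.edges) else []
    out = {c: {p: 0.0 for p in pairs} for c in clusters}
    if len(result.edges):
        edge_lab = result.edges["cell_id"].map(lab_of)
        grouped = result.edges.groupby([edge_lab, result.edges["gene_a"], result.edges["gene_b"]]).size()
        for (c, a, b), cnt in grouped.items():
            out[c][(a, b)] = cnt / sizes[c]
    return out
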