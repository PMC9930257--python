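"""Quality control, normalization, HVG selection, PCA and baseline clustering.

QC keeps cells whose detected-gene count lies within [min_genes, max_genes],
whose mitochondrial count fraction is at most max_mito_frac, that express
every required lineage marker (raw count > 0), and that express none of the
excluded genes (raw count == 0 for all of them).  Defaults follow standard
droplet scRNA-seq practice for an osteoblast-lineage sort: 200-5000 genes,
15% mitochondrial reads, RUNX2 required, hemoglobin genes excluded.

Normalization scales each cell to ``scale_total`` molecules and applies
log1p, so per-cell expm1 sums reproduce ``scale_total`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

#: attribution order when a cell fails several QC rules at once
QC_RULE_ORDER = ("low_genes", "high_genes", "mito", "no_marker", "hemoglobin")


@dataclass
class QCParams:
    min_genes: int = 200
    max_genes: int = 5000
    max_mito_frac: float = 0.15
    required_positive_genes: list[str] = field(default_factory=lambda: ["RUNX2"])
    excluded_if_expressed: list[str] = field(default_factory=lambda: ["HBM", "HBA1", "HBA2", "HBB"])
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_by_rule: dict[str, int]
    warnings: list[str] = field(default_factory=list)


def qc_filter(counts: pd.DataFrame, params: QCParams | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Apply the four QC rules; attribute each removed cell to its first
    failing rule (order: low, high, mito, marker, excluded)."""
    params = params or QCParams()
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty count matrix")
    notes: list[str] = []
    X = counts.to_numpy()
    detected = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    mito_cols = [i for i, g in enumerate(counts.columns) if str(g).startswith(params.mito_prefix)]
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito_cols].sum(axis=1) / np.maximum(total, 1), 0.0)

    required = [g for g in params.required_positive_genes if g in counts.columns]
    for g in set(params.required_positive_genes) - set(required):
        notes.append(f"required gene {g!r} absent from matrix; rule skipped for it")
    excluded = [g for g in params.excluded_if_expressed if g in counts.columns]
    for g in set(params.excluded_if_expressed) - set(excluded):
        notes.append(f"excluded gene {g!r} absent from matrix; rule skipped for it")

    fails = {
        "low_genes": detected < params.min_genes,
        "high_genes": detected > params.max_genes,
        "mito": mito_frac > params.max_mito_frac,
        "no_marker": ~(counts[required].to_numpy() > 0).all(axis=1)
        if required else np.zeros(len(counts), dtype=bool),
        "hemoglobin": (counts[excluded].to_numpy() > 0).any(axis=1)
        if excluded else np.zeros(len(counts), dtype=bool),
    }
    removed_by_rule = {}
    attributed = np.zeros(len(counts), dtype=bool)
    keep = np.ones(len(counts), dtype=bool)
    for rule in QC_RULE_ORDER:
        hit = fails[rule] & ~attributed
        removed_by_rule[rule] = int(hit.sum())
        attributed |= fails[rule]
        keep &= ~fails[rule]
    if not keep.any():
        raise ValueError("QC removed every cell; check thresholds against the data")
    report = QCReport(
        n_input=len(counts), n_kept=int(keep.sum()),
        removed_by_rule=removed_by_rule, warnings=notes,
    )
    return counts.loc[keep], report


def normalize_log(counts: pd.DataFrame, scale_total: float = 10_000.0) -> pd.DataFrame:
    """log1p of per-cell counts rescaled to ``scale_total`` molecules."""
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = counts.index[totals == 0].tolist()
        raise ValueError(f"all-zero cells cannot be normalized: {bad[:5]}")
    norm = pd.DataFrame(
        np.log1p(X / totals[:, None] * scale_total),
        index=counts.index, columns=counts.columns,
    )
    norm.attrs["scale_total"] = float(scale_total)
    norm.attrs["log_applied"] = True
    return norm


def select_hvg(norm: pd.DataFrame, n_top: int = 2000) -> list[str]:
    """Top ``n_top`` genes by dispersion (variance/mean), computed on the
    normalized-count scale (expm1 of the log-normalized values, the scale on
    which overdispersion is meaningful); deterministic tie-break by gene id."""
    if n_top > norm.shape[1]:
        raise ValueError(f"n_top={n_top} exceeds gene count {norm.shape[1]}")
    X = norm.to_numpy()
    if norm.attrs.get("log_applied", True):
        X = np.expm1(X)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    if np.all(var == 0):
        raise ValueError("degenerate matrix: every gene is constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    order = sorted(range(norm.shape[1]), key=lambda i: (-disp[i], str(norm.columns[i])))
    return [str(norm.columns[i]) for i in order[:n_top]]


@dataclass
class PCResult:
    embedding: pd.DataFrame      # cells x PCs
    stdevs: np.ndarray           # per-PC standard deviation, non-increasing
    variance_pct: np.ndarray     # stdev^2 / sum(stdev^2) * 100 over computed PCs
    loadings: pd.DataFrame       # genes x PCs


def run_pca(
    norm: pd.DataFrame,
    genes: list[str] | None = None,
    n_pcs: int = 18,
    center: bool = True,
    unit_scale: bool = True,
) -> PCResult:
    """PCA on the (centered, optionally unit-scaled) gene submatrix.

    Constant genes are dropped with a warning; component signs are fixed by
    making each PC's largest-magnitude loading positive, so results are
    deterministic.
    """
    sub = norm[list(genes)] if genes is not None else norm
    X = sub.to_numpy(dtype=float)
    kept = np.ones(X.shape[1], dtype=bool)
    if unit_scale or center:
        sd = X.std(axis=0, ddof=1)
        kept = sd > 0
        if not kept.all():
            warnings.warn(f"dropping {int((~kept).sum())} constant gene(s) before PCA")
        X = X[:, kept]
        if center:
            X = X - X.mean(axis=0)
        if unit_scale:
            X = X / X.std(axis=0, ddof=1)
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(X.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    emb = pca.fit_transform(X)
    comp = pca.components_  # n_pcs x genes
    signs = np.sign(comp[np.arange(n_pcs), np.abs(comp).argmax(axis=1)])
    signs[signs == 0] = 1
    emb *= signs
    comp = comp * signs[:, None]
    stdevs = np.sqrt(pca.explained_variance_)
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return PCResult(
        embedding=pd.DataFrame(emb, index=sub.index, columns=cols),
        stdevs=stdevs,
        variance_pct=variance_explained(stdevs),
        loadings=pd.DataFrame(comp.T, index=sub.columns[kept], columns=cols),
    )


def variance_explained(stdevs: np.ndarray) -> np.ndarray:
    """Percentage of variance per PC: stdev**2 / sum(stdev**2) * 100."""
    s = np.asarray(stdevs, dtype=float)
    if (s < 0).any():
        raise ValueError("standard deviations must be non-negative")
    ss = (s**2).sum()
    if ss == 0:
        raise ValueError("all standard deviations are zero")
    return s**2 / ss * 100.0


def cluster_cells(embedding: pd.DataFrame | np.ndarray, k: int, seed: int, n_init: int = 10) -> np.ndarray:
    """K-means labels on an embedding; deterministic under a fixed seed."""
    X = embedding.to_numpy() if isinstance(embedding, pd.DataFrame) else np.asarray(embedding)
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} cells")
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=n_init)
    return km.fit_predict(X)
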