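"""Diffusion maps, diffusion pseudotime and cluster-level transition summaries.

A Gaussian kernel with per-cell adaptive bandwidth (the distance to the
ceil(k_neighbors/2)-th nearest neighbour) is built on Euclidean distances in
the supplied feature space — log-normalized expression PCs or the regulon
activity matrix.  Optional density normalization (dividing the kernel by the
product of its row sums) removes sampling-density effects before
row-normalizing to a Markov transition matrix.  Diffusion components are the
non-trivial right eigenvectors of this matrix scaled by their eigenvalues;
diffusion pseudotime is the Euclidean distance to a root cell in the
lambda/(1-lambda)-weighted eigenspace, rescaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class DiffusionResult:
    components: pd.DataFrame        # cells x n_comps, eigenvalue-scaled
    eigenvalues: np.ndarray         # non-trivial, descending, in (0, 1]
    eigenvectors: np.ndarray        # cells x n_comps right eigenvectors of T
    transition: pd.DataFrame        # cells x cells row-stochastic matrix
    pseudotime: pd.Series | None = None
    root_cell: str | None = None


def diffusion_map(
    X: pd.DataFrame | np.ndarray,
    n_comps: int = 10,
    k_neighbors: int = 30,
    density_norm: bool = True,
) -> DiffusionResult:
    """Diffusion-map embedding of a cells x features matrix."""
    idx = list(X.index) if isinstance(X, pd.DataFrame) else [str(i) for i in range(len(X))]
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    n = A.shape[0]
    if n < n_comps + 1:
        raise ValueError(f"need at least n_comps+1={n_comps + 1} cells, got {n}")
    kk = min(max(int(np.ceil(k_neighbors / 2)), 1), n - 1)

    D = squareform(pdist(A))
    sigma = np.sort(D, axis=1)[:, kk]  # column 0 is the self-distance 0
    if (sigma == 0).any():
        # duplicate cells (e.g. quantized activity scores): give them the
        # typical bandwidth so they stay coupled to the rest of the graph
        pos = sigma[sigma > 0]
        floor = np.median(pos) if pos.size else 1.0
        warnings.warn(f"{int((sigma == 0).sum())} zero bandwidth(s); floored at {floor:.3g}")
        sigma = np.maximum(sigma, floor)

    W = np.exp(-(D**2) / (2.0 * np.outer(sigma, sigma)))
    np.fill_diagonal(W, 0.0)
    if density_norm:
        q = W.sum(axis=1)
        q[q == 0] = 1.0
        W = W / np.outer(q, q)
    d = W.sum(axis=1)
    if (d == 0).any():
        raise ValueError("isolated cell(s): kernel row sums to zero")

    # symmetric conjugate of the transition matrix -> real spectrum
    inv_sqrt_d = 1.0 / np.sqrt(d)
    S = W * np.outer(inv_sqrt_d, inv_sqrt_d)
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1][: n_comps + 1]
    evals = evals[order]
    psi = evecs[:, order] * inv_sqrt_d[:, None]   # right eigenvectors of T
    # drop the trivial constant eigenvector (eigenvalue 1)
    lam = evals[1:]
    psi = psi[:, 1:]
    # normalize and fix signs: largest-magnitude entry positive
    psi = psi / np.linalg.norm(psi, axis=0)
    signs = np.sign(psi[np.abs(psi).argmax(axis=0), np.arange(psi.shape[1])])
    signs[signs == 0] = 1
    psi = psi * signs

    T = W / d[:, None]
    comps = psi * lam
    cols = [f"DC{i + 1}" for i in range(comps.shape[1])]
    return DiffusionResult(
        components=pd.DataFrame(comps, index=idx, columns=cols),
        eigenvalues=lam,
        eigenvectors=psi,
        transition=pd.DataFrame(T, index=idx, columns=idx),
    )


def diffusion_pseudotime(res: DiffusionResult, root_cell) -> pd.Series:
    """Diffusion pseudotime anchored at ``root_cell``.

    Distance between cells in the eigenspace with coordinates
    psi_i * lambda_i / (1 - lambda_i) over the non-trivial components,
    rescaled so the farthest cell sits at 1; the root sits at 0.
    """
    idx = list(res.components.index)
    if root_cell not in idx:
        raise KeyError(f"root cell {root_cell!r} not found")
    if np.any(res.eigenvalues >= 1 - 1e-10):
        bad = (np.flatnonzero(res.eigenvalues >= 1 - 1e-10) + 1).tolist()
        raise ValueError(
            f"disconnected kernel graph: non-trivial component(s) {bad} have "
            "eigenvalue numerically 1; pseudotime is undefined across components"
        )
    weights = res.eigenvalues / (1.0 - res.eigenvalues)
    M = res.eigenvectors * weights
    r = idx.index(root_cell)
    dist = np.linalg.norm(M - M[r], axis=1)
    if dist.max() > 0:
        dist = dist / dist.max()
    pt = pd.Series(dist, index=idx, name="pseudotime")
    res.pseudotime = pt
    res.root_cell = str(root_cell)
    return pt


def select_root_cell(res: DiffusionResult, labels, root_cluster) -> str:
    """Pick the root for pseudotime: the cell of ``root_cluster`` farthest
    (in diffusion-component space) from the centroid of all other clusters.

    Anchoring at the extreme of the early cluster is robust to individual
    noisy cells; anchoring at an arbitrary early cell is not, since a cell
    whose profile happens to resemble a later state drags the whole
    ordering with it.
    """
    labels = np.asarray(labels)
    comps = res.components.to_numpy()
    if len(labels) != comps.shape[0]:
        raise ValueError("labels must cover all cells")
    in_root = labels == root_cluster
    if not in_root.any():
        raise ValueError(f"root cluster {root_cluster!r} matches no cells")
    if in_root.all():
        idx = int(np.argmax(np.abs(comps[:, 0])))
        return str(res.components.index[idx])
    centroid = comps[~in_root].mean(axis=0)
    dist = np.linalg.norm(comps[in_root] - centroid, axis=1)
    return str(res.components.index[in_root][int(np.argmax(dist))])


def cluster_transitions(res: DiffusionResult, labels) -> pd.DataFrame:
    """Mean cell-to-cell transition probability between every pair of
    clusters (diagonal included)."""
    labels = np.asarray(labels)
    T = res.transition.to_numpy()
    if len(labels) != T.shape[0]:
        raise ValueError("labels must cover all cells")
    clusters = sorted(pd.unique(labels).tolist())
    out = np.zeros((len(clusters), len(clusters)))
    masks = {c: labels == c for c in clusters}
    for i, a in enumerate(clusters):
        for j, b in enumerate(clusters):
            out[i, j] = T[np.ix_(masks[a], masks[b])].mean()
    return pd.DataFrame(out, index=clusters, columns=clusters)


class DiffusionMap(BaseEstimator, TransformerMixin):
    """Transformer yielding eigenvalue-scaled diffusion components.

    After ``fit``, ``result_`` carries the full decomposition, and
    ``pseudotime(root_cell)`` computes diffusion pseudotime from it.
    """

    def __init__(self, n_comps: int = 10, k_neighbors: int = 30, density_norm: bool = True):
        self.n_comps = n_comps
        self.k_neighbors = k_neighbors
        self.density_norm = density_norm

    def fit(self, X, y=None) -> "DiffusionMap":
        self.result_ = diffusion_map(
            X, n_comps=self.n_comps, k_neighbors=self.k_neighbors, density_norm=self.density_norm
        )
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X=None) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise RuntimeError("DiffusionMap is not fitted")
        return self.result_.components

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def pseudotime(self, root_cell) -> pd.Series:
        if not hasattr(self, "result_"):
            raise RuntimeError("DiffusionMap is not fitted")
        return diffusion_pseudotime(self.result_, root_cell)
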