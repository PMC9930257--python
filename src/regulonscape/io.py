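"""Readers and writers for the standard interchange formats.

Count matrices travel as the 10x-style Matrix Market triple
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, genes stored as rows
in the mtx as 10x does) or as dense CSV/TSV with a declared orientation.
Regulons and gene sets travel as GMT; weighted interaction graphs as
three-column TSV edge lists.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def read_10x(directory: str | os.PathLike) -> pd.DataFrame:
    """Read a matrix.mtx + features.tsv + barcodes.tsv triple.

    Returns a cells x genes integer DataFrame (cells as index). The mtx is
    stored genes x cells, following the 10x convention.
    """
    directory = str(directory)
    mtx_path = _first_existing(directory, ["matrix.mtx", "matrix.mtx.gz"])
    feat_path = _first_existing(directory, ["features.tsv", "genes.tsv"])
    bc_path = _first_existing(directory, ["barcodes.tsv"])
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    features = pd.read_csv(feat_path, sep="\t", header=None)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None)[0].tolist()
    gene_ids = features[0].tolist()
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but features/barcodes imply "
            f"({len(gene_ids)}, {len(barcodes)})"
        )
    dense = np.asarray(mat.todense()).T  # -> cells x genes
    return pd.DataFrame(dense, index=barcodes, columns=gene_ids, dtype=np.int64)


def write_10x(counts: pd.DataFrame, directory: str | os.PathLike) -> None:
    """Write a cells x genes DataFrame as a 10x triple (genes as mtx rows)."""
    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    mat = sp.coo_matrix(counts.to_numpy().T)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame({"id": counts.columns, "symbol": counts.columns})
    feats.to_csv(os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(counts.index).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_dense(path: str | os.PathLike, cells_in: str = "rows", sep: str | None = None) -> pd.DataFrame:
    """Read a dense CSV/TSV count matrix; ``cells_in`` declares orientation."""
    if cells_in not in ("rows", "cols"):
        raise ValueError("cells_in must be 'rows' or 'cols'")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df if cells_in == "rows" else df.T


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets from GMT: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"empty gene set {name!r} in GMT")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read a weighted edge list TSV with columns node_a, node_b, combined_score."""
    df = pd.read_csv(path, sep="\t")
    expected = {"node_a", "node_b", "combined_score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(expected)}")
    return df


def write_edge_list(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_labels(path: str | os.PathLike) -> pd.Series:
    """Read a two-column (cell_id, label) TSV into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("label TSV needs at least two columns: cell_id, label")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, header_meta: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with optional '# key=value' comment header."""
    with open(path, "w") as fh:
        for key, val in (header_meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t")


def _first_existing(directory: str, names: list[str]) -> str:
    for name in names:
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")
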