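"""Synthetic single-cell datasets with planted ground truth.

The generator emulates the structure the downstream analyses are designed to
detect: K cell clusters ordered along a (optionally branching) pseudotime,
planted regulons (a TF plus co-regulated targets) elevated in designated
clusters, negative-binomial counts with logistic dropout, marker genes with
monotone pseudotime trends, and QC decoys (mitochondrial and hemoglobin
genes, a required lineage marker, and deliberately broken cells that each
violate exactly one QC rule).

Counts for gene g in cell c are NegativeBinomial(mean mu, size = dispersion)
with mu = baseline_mean, multiplied by active_fold_change when g belongs to a
regulon active in c's cluster, and by (1 + marker_strength * t) /
(1 + marker_strength * (1 - t)) for up-/down-trending markers at pseudotime
t.  Each count is then independently zeroed with probability
sigmoid(-dropout_slope * (log mu - dropout_midpoint)); dropout_slope = 0
disables dropout entirely.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as rio
from .preprocess import QCParams

MITO_DECOYS = ["MT-ND1", "MT-CO1", "MT-CO2", "MT-CYB", "MT-ATP6"]
HB_DECOYS = ["HBM", "HBA1", "HBA2", "HBB"]
LINEAGE_MARKER = "RUNX2"

_QC_RULES = ("low_genes", "high_genes", "mito", "no_marker", "hemoglobin")


@dataclass
class PlantedRegulon:
    """A ground-truth regulon: TF gene id, its targets, and where it is on."""

    name: str
    targets: list[str]
    active_clusters: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.name in self.targets:
            raise ValueError(f"TF {self.name!r} must not appear in its own target list")
        if not self.active_clusters:
            raise ValueError(f"regulon {self.name!r} has no active clusters")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.name!r} has duplicate targets")

    @property
    def genes(self) -> list[str]:
        return [self.name, *self.targets]


def default_regulons() -> list[PlantedRegulon]:
    """Two non-overlapping regulons of 10 targets, active in the first and
    last of three clusters (the study-condition default)."""
    return [
        PlantedRegulon("G0000", [f"G{i:04d}" for i in range(1, 11)], {0}),
        PlantedRegulon("G0020", [f"G{i:04d}" for i in range(21, 31)], {2}),
    ]


@dataclass
class SimConfig:
    n_clusters: int = 3
    cells_per_cluster: int = 200
    n_genes: int = 100
    regulons: list[PlantedRegulon] = field(default_factory=default_regulons)
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    active_fold_change: float = 8.0
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    marker_strength: float = 6.0
    n_marker_up: int = 20
    n_marker_down: int = 20
    n_qc_bad_cells: int = 5
    include_decoy_genes: bool = True
    branch: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_clusters, self.cells_per_cluster, self.n_genes) <= 0:
            raise ValueError("n_clusters, cells_per_cluster and n_genes must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.regulons and self.active_fold_change <= 1:
            raise ValueError("active_fold_change must exceed 1 when regulons are planted")
        if min(self.n_marker_up, self.n_marker_down, self.n_qc_bad_cells) < 0:
            raise ValueError("gene/cell counts must be non-negative")
        universe = set(generic_gene_ids(self.n_genes))
        for reg in self.regulons:
            missing = set(reg.genes) - universe
            if missing:
                raise ValueError(f"regulon {reg.name!r} references unknown genes {sorted(missing)}")
            if reg.active_clusters - set(range(self.n_clusters)):
                raise ValueError(f"regulon {reg.name!r} references unknown clusters")


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame            # cells x genes, integer
    true_labels: pd.Series          # cluster index per cell
    true_pseudotime: pd.Series      # in [0, 1]
    true_branch: pd.Series          # 0/1 branch flag (all 0 for linear lineage)
    regulon_truth: dict[str, list[str]]       # regulon name -> target list
    activity_design: pd.DataFrame   # regulons x clusters binary design
    qc_truth: pd.Series             # True = should survive QC
    qc_fail_rule: pd.Series         # rule name for planted bad cells, '' otherwise
    qc_params: QCParams             # QC thresholds matched to this universe
    config: SimConfig

    def __post_init__(self) -> None:
        n = self.counts.shape[0]
        if not (len(self.true_labels) == len(self.true_pseudotime) == len(self.qc_truth) == n):
            raise ValueError("truth vectors must match the cell count")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def generic_gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def simulate_counts(config: SimConfig) -> SyntheticDataset:
    """Draw a SyntheticDataset under ``config``; fully reproducible per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, n_good = config.n_clusters, config.n_clusters * config.cells_per_cluster
    n_bad = config.n_qc_bad_cells if config.include_decoy_genes else 0
    n_cells = n_good + n_bad

    genes = generic_gene_ids(config.n_genes)
    markers_up = [f"MUP{i:02d}" for i in range(config.n_marker_up)]
    markers_dn = [f"MDN{i:02d}" for i in range(config.n_marker_down)]
    decoys = (MITO_DECOYS + HB_DECOYS + [LINEAGE_MARKER]) if config.include_decoy_genes else []
    all_genes = genes + markers_up + markers_dn + decoys
    G = len(all_genes)

    # stratified pseudotime: cluster j covers quantile bin [j/K, (j+1)/K)
    t_good = np.concatenate(
        [rng.uniform(j / K, (j + 1) / K, size=config.cells_per_cluster) for j in range(K)]
    )
    t_bad = rng.uniform(0, 1, size=n_bad)
    t = np.concatenate([t_good, t_bad])
    labels = np.minimum((t * K).astype(int), K - 1)
    branch = np.zeros(n_cells, dtype=int)
    if config.branch:
        # duplicate the upper half of pseudotime into a side branch
        upper = np.flatnonzero(t >= 0.5)
        branch[rng.choice(upper, size=len(upper) // 2, replace=False)] = 1

    mu = np.full((n_cells, G), config.baseline_mean)
    col = {g: i for i, g in enumerate(all_genes)}
    for reg in config.regulons:
        active = np.isin(labels, sorted(reg.active_clusters))
        # co-regulation: TF and targets share a per-cell latent activity.
        # The latent ramps along pseudotime within the active window (early
        # programs decay from the lineage start, late programs rise towards
        # its end) with multiplicative cell-to-cell jitter, so member genes
        # co-vary within the active cluster AND activity tracks the lineage,
        # instead of being conditionally independent given the cluster.
        lo = min(reg.active_clusters) / K
        hi = (max(reg.active_clusters) + 1) / K
        u = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
        ramp = u if (lo + hi) / 2 >= 0.5 else 1.0 - u
        latent = np.where(active, ramp, 0.0) * rng.uniform(0.5, 1.0, size=n_cells)
        boost = 1 + (config.active_fold_change - 1) * latent
        for g in reg.genes:
            mu[:, col[g]] *= boost
    for g in markers_up:
        mu[:, col[g]] *= 1 + config.marker_strength * t
    for g in markers_dn:
        mu[:, col[g]] *= 1 + config.marker_strength * (1 - t)
    if config.include_decoy_genes:
        for g in HB_DECOYS:
            mu[:, col[g]] = 0.0
        # healthy cells carry a low mitochondrial load (a few percent of reads)
        for g in MITO_DECOYS:
            mu[:, col[g]] = 0.2 * config.baseline_mean

    counts = _nb_draw(rng, mu, config.dispersion)
    if config.dropout_slope != 0:
        with np.errstate(divide="ignore"):
            logmu = np.where(mu > 0, np.log(np.maximum(mu, 1e-300)), -np.inf)
        p_drop = _sigmoid(-config.dropout_slope * (logmu - config.dropout_midpoint))
        p_drop[~np.isfinite(logmu)] = 1.0
        counts[rng.random(counts.shape) < p_drop] = 0

    qc_rule = np.array([""] * n_cells, dtype=object)
    if config.include_decoy_genes:
        # the lineage marker is expressed in every intact lineage cell
        marker_extra = _nb_draw(rng, np.full(n_cells, 3 * config.baseline_mean), config.dispersion)
        counts[:, col[LINEAGE_MARKER]] = 1 + marker_extra
        for g in HB_DECOYS:
            counts[:, col[g]] = 0
        for i in range(n_bad):
            c = n_good + i
            rule = _QC_RULES[i % len(_QC_RULES)]
            qc_rule[c] = rule
            _break_cell(counts, c, rule, col, genes + markers_up + markers_dn, rng)

    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    counts_df = pd.DataFrame(counts, index=cell_ids, columns=all_genes, dtype=np.int64)
    design = pd.DataFrame(
        [[int(j in r.active_clusters) for j in range(K)] for r in config.regulons],
        index=[r.name for r in config.regulons],
        columns=list(range(K)),
        dtype=int,
    )
    qc_params = QCParams(
        min_genes=10,
        max_genes=int(0.9 * G),
        max_mito_frac=0.15,
        required_positive_genes=[LINEAGE_MARKER] if config.include_decoy_genes else [],
        excluded_if_expressed=list(HB_DECOYS) if config.include_decoy_genes else [],
    )
    return SyntheticDataset(
        counts=counts_df,
        true_labels=pd.Series(labels, index=cell_ids, name="cluster"),
        true_pseudotime=pd.Series(t, index=cell_ids, name="pseudotime"),
        true_branch=pd.Series(branch, index=cell_ids, name="branch"),
        regulon_truth={r.name: list(r.targets) for r in config.regulons},
        activity_design=design,
        qc_truth=pd.Series(qc_rule == "", index=cell_ids, name="qc_ok"),
        qc_fail_rule=pd.Series(qc_rule, index=cell_ids, name="qc_fail_rule"),
        qc_params=qc_params,
        config=config,
    )


def _break_cell(counts: np.ndarray, c: int, rule: str, col: dict[str, int],
                expressable: list[str], rng: np.random.Generator) -> None:
    """Make cell ``c`` violate exactly the named QC rule and no other."""
    mito = [col[g] for g in MITO_DECOYS]
    if rule == "low_genes":
        keep = rng.choice([col[g] for g in expressable], size=5, replace=False)
        mask = np.zeros(counts.shape[1], dtype=bool)
        mask[keep] = True
        mask[col[LINEAGE_MARKER]] = True
        counts[c, ~mask] = 0
        counts[c, keep] = np.maximum(counts[c, keep], 1)
    elif rule == "high_genes":
        counts[c, :] = np.maximum(counts[c, :], 1)
        counts[c, [col[g] for g in HB_DECOYS]] = 0
        counts[c, mito] = 1
    elif rule == "mito":
        other = counts[c].sum() - counts[c, mito].sum()
        per_gene = int(np.ceil(0.7 * max(other, 5) / len(mito)))  # ~40% mito fraction
        counts[c, mito] = per_gene
    elif rule == "no_marker":
        counts[c, col[LINEAGE_MARKER]] = 0
    elif rule == "hemoglobin":
        counts[c, col["HBB"]] = 3


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size: float) -> np.ndarray:
    """Negative binomial with mean mu and size (dispersion) parameter."""
    p = size / (size + np.asarray(mu, dtype=float))
    return rng.negative_binomial(size, p).astype(np.int64)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def simulate_ppi_graph(
    n_background: int,
    planted_cliques: list[int],
    p_background: float,
    seed: int,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Erdos-Renyi background plus fully connected planted cliques.

    Background edges carry combined scores uniform in [0.4, 1.0]; clique
    edges uniform in [0.9, 1.0].  Returns (edge list, clique memberships).
    """
    if any(s < 3 for s in planted_cliques):
        raise ValueError("planted clique sizes must be >= 3")
    if not (0 <= p_background < 1):
        raise ValueError("p_background must be in [0, 1)")
    rng = np.random.default_rng(seed)
    background = [f"B{i:04d}" for i in range(n_background)]
    truth: list[list[str]] = []
    clique_nodes: list[str] = []
    for m, size in enumerate(planted_cliques):
        members = [f"M{m}_{j}" for j in range(size)]
        truth.append(members)
        clique_nodes.extend(members)
    if len(set(clique_nodes)) != len(clique_nodes) or set(clique_nodes) & set(background):
        raise ValueError("node id collision between cliques/background")

    edges: dict[tuple[str, str], float] = {}
    nodes = background + clique_nodes
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < p_background:
                edges[(nodes[i], nodes[j])] = rng.uniform(0.4, 1.0)
    for members in truth:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges[(members[i], members[j])] = rng.uniform(0.9, 1.0)
    df = pd.DataFrame(
        [(a, b, round(w, 4)) for (a, b), w in edges.items()],
        columns=["node_a", "node_b", "combined_score"],
    )
    return df, truth


def write_dataset(ds: SyntheticDataset, out_dir: str | os.PathLike) -> None:
    """Write the 10x triple, truth tables (TSV) and a JSON config echo."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rio.write_10x(ds.counts, out_dir)
    truth = pd.DataFrame(
        {
            "cluster": ds.true_labels,
            "pseudotime": ds.true_pseudotime,
            "branch": ds.true_branch,
            "qc_ok": ds.qc_truth.astype(int),
            "qc_fail_rule": ds.qc_fail_rule,
        }
    )
    truth.index.name = "cell_id"
    truth.to_csv(os.path.join(out_dir, "cell_truth.tsv"), sep="\t")
    labels = ds.true_labels.to_frame()
    labels.index.name = "cell_id"
    labels.to_csv(os.path.join(out_dir, "truth_labels.tsv"), sep="\t")
    ds.activity_design.rename_axis("regulon").to_csv(
        os.path.join(out_dir, "activity_design.tsv"), sep="\t"
    )
    rio.write_gmt(ds.regulon_truth, os.path.join(out_dir, "regulons.gmt"))
    cfg = dataclasses.asdict(ds.config)
    cfg["regulons"] = [
        {"name": r.name, "targets": r.targets, "active_clusters": sorted(r.active_clusters)}
        for r in ds.config.regulons
    ]
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
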