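# regulonscape

Regulon-activity landscapes for single-cell RNA-seq: per-cell scoring of
transcription-factor programs, cell-specific association networks, and
activity-based trajectory inference — with a synthetic-data generator that
plants ground truth for every stage.

## The problem

In a differentiating lineage (the motivating system is the human osteoblast
lineage, from preosteoblasts through intermediate to mature osteoblasts),
cell states are often better separated by *which regulatory programs are
on* than by raw expression. A **regulon** is a transcription factor together
with its target genes, regulated as a unit. This package takes a counts
matrix plus regulon definitions (GMT) and asks, per cell:

- **How active is each regulon?** The activity score is the area under the
  gene-set recovery curve over the top fraction of the cell's
  expression-ranked genes (AUCell-style): with `T = ceil(top_frac·G)` ranks
  and gene set S, `AUC = Σ_{t<T} |{g∈S : rank_g ≤ t}| / Σ_{t<T} min(t,|S|)`
  — rank-based, in [0, 1], robust to dropout.
- **Which gene pairs associate in *this* cell?** The cell-specific network
  (CSN) statistic counts cells in expression-neighborhood boxes around the
  focal cell k:
  `ρ̂_xy(k) = √(n−1)·(n·n_xy − n_x·n_y) / √(n_x n_y (n−n_x)(n−n_y))`,
  asymptotically N(0,1) under independence; edges are called by an exact
  conditional (hypergeometric) upper-tail test. A gene's number of
  significant edges per cell forms the **network degree matrix (NDM)**,
  compared across clusters by Wilcoxon rank-sum with BH correction.
- **Where does each cell sit on the lineage?** Diffusion maps with adaptive
  Gaussian kernels yield diffusion components, cluster-to-cluster mean
  transition probabilities, and diffusion pseudotime (distance to a root
  cell in λ/(1−λ)-weighted eigenspace) — computable from expression PCs or
  directly from the regulon activity matrix.

Around this core: the standard QC/normalization/HVG/PCA preprocessing,
preranked GSEA (significance = BH-FDR < 0.05 and |NES| > 1), and MCODE
dense-module detection on weighted interaction graphs (defaults 2 / 0.2 /
2 / 3.0). Every stage is seeded and deterministic.

## Worked example

```python
import regulonscape as rs
from scipy.stats import spearmanr

ds = rs.simulate_counts(rs.SimConfig(seed=1))      # 3 clusters x 200 cells,
kept, report = rs.qc_filter(ds.counts, ds.qc_params)  # 2 planted regulons
print(f"QC kept {report.n_kept}/{report.n_input} cells")
norm = rs.normalize_log(kept)
labels = ds.true_labels.loc[norm.index].to_numpy()

ranks = rs.rank_genes_per_cell(norm, tie_seed=0)
activity = rs.score_all(ranks, ds.regulon_truth, top_frac=0.2)
print(activity.groupby(labels).mean().round(3))

genes = sorted({g for tf, ts in ds.regulon_truth.items() for g in [tf] + ts})
csn = rs.build_csn(norm, rs.CsnParams(box_frac=0.1, alpha=0.01, gene_subset=genes))
print(csn.ndm.loc["G0000"].groupby(labels).mean().round(2).to_dict())

pcs = rs.run_pca(norm, rs.select_hvg(norm, n_top=50), n_pcs=10)
dm = rs.diffusion_map(pcs.embedding, n_comps=10, k_neighbors=30)
pt = rs.diffusion_pseudotime(dm, rs.select_root_cell(dm, labels, 0))
t = ds.true_pseudotime.loc[norm.index]
print(f"Spearman rho = {spearmanr(pt, t).statistic:.3f}")
```

prints

```
QC kept 600/605 cells
   G0000  G0020
0  0.257  0.022
1  0.036  0.032
2  0.022  0.279
{0: 1.21, 1: 0.12, 2: 0.18}
Spearman rho = 0.946
```

Reading it: the five planted low-quality cells are removed (one per QC
rule); each regulon's activity peaks in its planted cluster (regulon
`G0000` in cluster 0, `G0020` in cluster 2); the TF `G0000` carries ~10×
more significant network edges per cell in its active cluster than
elsewhere; and diffusion pseudotime reorders the 600 cells to within
Spearman 0.95 of the planted ordering.

The same run is available end-to-end from a shell:

```sh
regulonscape simulate --out sim/ --seed 1
regulonscape run --config config.yaml       # QC → activity → CSN → trajectory → GSEA
regulonscape mcode --edges graph.tsv --out modules/
```

(`regulonscape --help` lists all subcommands; every tabular output is TSV
with a `# key=value` header recording parameters and seeds.)

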