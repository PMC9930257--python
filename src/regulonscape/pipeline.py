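"""End-to-end pipeline: simulate/ingest -> QC -> normalize -> score regulons
-> cluster -> CSN/NDM -> trajectory -> GSEA -> report.

A single YAML config drives the run.  Every stochastic stage consumes a
stage-specific child seed derived from the global seed and the stage name,
so a rerun with the same config is byte-identical.  Each stage appends a
record (parameters, outputs, counts) to the RunReport, which is written as
JSON next to the tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from ._utils import child_seed
from .aucell import differential_activity, rank_genes_per_cell, score_all, summarize_by_cluster
from .csn import CsnParams, build_csn, differential_ndm
from .enrichment import preranked_gsea
from .preprocess import QCParams, cluster_cells, normalize_log, qc_filter, run_pca, select_hvg
from .simdata import PlantedRegulon, SimConfig, simulate_counts
from .trajectory import cluster_transitions, diffusion_map, diffusion_pseudotime, select_root_cell

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "simulate", "input", "qc", "normalize", "hvg", "pca",
         "cluster", "aucell", "csn", "trajectory", "gsea"},
    "simulate": {f.name for f in dataclasses.fields(SimConfig)},
    "input": {"tenx_dir", "dense", "cells_in", "regulons_gmt", "labels"},
    "qc": {f.name for f in dataclasses.fields(QCParams)} | {"use_dataset_defaults"},
    "normalize": {"scale_total"},
    "hvg": {"n_top"},
    "pca": {"n_pcs", "unit_scale", "center"},
    "cluster": {"k", "source", "labels_file"},
    "aucell": {"top_frac", "gmt"},
    "csn": {"box_frac", "alpha", "genes", "n_background"},
    "trajectory": {"input", "n_comps", "k_neighbors", "density_norm", "root_cluster"},
    "gsea": {"enabled", "gmt", "n_perm", "weight_p", "cluster", "min_size", "max_size"},
}

_DEFAULTS: dict[str, dict] = {
    "qc": {"use_dataset_defaults": True},
    "normalize": {"scale_total": 10000.0},
    "hvg": {"n_top": 50},
    "pca": {"n_pcs": 10, "unit_scale": True, "center": True},
    "cluster": {"k": 3, "source": "expression", "labels_file": None},
    "aucell": {"top_frac": 0.05, "gmt": None},
    "csn": {"box_frac": 0.1, "alpha": 0.01, "genes": "regulons", "n_background": 20},
    "trajectory": {"input": "expression", "n_comps": 10, "k_neighbors": 30,
                   "density_norm": True, "root_cluster": 0},
    "gsea": {"enabled": True, "gmt": None, "n_perm": 1000, "weight_p": 1.0,
             "cluster": 0, "min_size": 5, "max_size": 500},
}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    simulate: dict | None
    input: dict | None
    qc: dict
    normalize: dict
    hvg: dict
    pca: dict
    cluster: dict
    aucell: dict
    csn: dict
    trajectory: dict
    gsea: dict


@dataclass
class StageRecord:
    stage: str
    params: dict
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)


@dataclass
class RunReport:
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "stages": [dataclasses.asdict(s) for s in self.stages]},
            indent=2, default=str,
        )


def validate_config(path: str) -> PipelineConfig:
    """Parse and strictly validate a YAML pipeline config.

    Unknown keys are errors (named in the message); ranges are checked; file
    paths referenced by the config must exist.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config_dict(raw, base_dir=os.path.dirname(os.path.abspath(path)))


def validate_config_dict(raw: dict, base_dir: str = ".") -> PipelineConfig:
    _check_keys(raw, "", _SCHEMA[""])
    if ("simulate" in raw) == ("input" in raw):
        raise ValueError("config needs exactly one of 'simulate' or 'input'")
    blocks = {}
    for name in ("qc", "normalize", "hvg", "pca", "cluster", "aucell", "csn", "trajectory", "gsea"):
        block = dict(_DEFAULTS.get(name, {}))
        user = raw.get(name) or {}
        _check_keys(user, name, _SCHEMA[name])
        block.update(user)
        blocks[name] = block
    if not 0 < blocks["csn"]["box_frac"] <= 1:
        raise ValueError(f"csn.box_frac={blocks['csn']['box_frac']} out of range (0, 1]")
    if not 0 < blocks["csn"]["alpha"] < 1:
        raise ValueError(f"csn.alpha={blocks['csn']['alpha']} out of range (0, 1)")
    if not 0 < blocks["aucell"]["top_frac"] <= 1:
        raise ValueError(f"aucell.top_frac={blocks['aucell']['top_frac']} out of range (0, 1]")
    sim = raw.get("simulate")
    if sim is not None:
        _check_keys(sim, "simulate", _SCHEMA["simulate"])
    inp = raw.get("input")
    if inp is not None:
        _check_keys(inp, "input", _SCHEMA["input"])
        for key in ("tenx_dir", "dense", "regulons_gmt", "labels"):
            if inp.get(key):
                p = os.path.join(base_dir, inp[key]) if not os.path.isabs(inp[key]) else inp[key]
                if not os.path.exists(p):
                    raise ValueError(f"input.{key} path does not exist: {inp[key]}")
                inp[key] = p
        if inp.get("regulons_gmt") is None:
            raise ValueError("input.regulons_gmt is required when not simulating")
    return PipelineConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir", "regulonscape_out"),
        simulate=sim, input=inp, **blocks,
    )


def _check_keys(d: dict, block: str, allowed: set[str]) -> None:
    if not isinstance(d, dict):
        raise ValueError(f"config block {block or '<root>'} must be a mapping")
    unknown = set(d) - allowed
    if unknown:
        where = f"in block '{block}'" if block else "at top level"
        raise ValueError(f"unknown config key(s) {sorted(unknown)} {where}")


def _build_sim_config(block: dict, seed: int) -> SimConfig:
    block = dict(block)
    regs = block.pop("regulons", None)
    kwargs = dict(block)
    kwargs.setdefault("seed", seed)
    if regs is not None:
        kwargs["regulons"] = [
            PlantedRegulon(r["name"], list(r["targets"]), set(r["active_clusters"]))
            for r in regs
        ]
    return SimConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order; deterministic under the config seed."""
    os.makedirs(config.out_dir, exist_ok=True)
    report = RunReport(seed=config.seed)
    out = config.out_dir

    def record(stage: str, params: dict, outputs: list[str] | None = None, **counts) -> None:
        report.stages.append(StageRecord(stage, params, outputs or [], counts))

    # --- ingest -----------------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim_cfg = _build_sim_config(config.simulate, child_seed(config.seed, "simulate"))
        ds = simulate_counts(sim_cfg)
        counts, regulons = ds.counts, ds.regulon_truth
        truth = ds
        qc_params = ds.qc_params if config.qc.get("use_dataset_defaults") else _qc_from_block(config.qc)
        record("simulate", {"seed": sim_cfg.seed, "n_clusters": sim_cfg.n_clusters,
                            "cells_per_cluster": sim_cfg.cells_per_cluster},
               n_cells=counts.shape[0], n_genes=counts.shape[1])
    else:
        inp = config.input
        if inp.get("tenx_dir"):
            counts = rio.read_10x(inp["tenx_dir"])
        elif inp.get("dense"):
            counts = rio.read_dense(inp["dense"], cells_in=inp.get("cells_in", "rows"))
        else:
            raise ValueError("input block needs tenx_dir or dense")
        regulons = rio.read_gmt(inp["regulons_gmt"])
        qc_params = _qc_from_block(config.qc)
        record("ingest", {k: v for k, v in inp.items() if v},
               n_cells=counts.shape[0], n_genes=counts.shape[1])

    # --- QC ---------------------------------------------------------------
    filtered, qc_report = qc_filter(counts, qc_params)
    rio.write_tsv(pd.DataFrame(qc_report.removed_by_rule, index=["removed"]).T,
                  os.path.join(out, "qc_report.tsv"), {"seed": config.seed})
    record("qc", dataclasses.asdict(qc_params), [os.path.join(out, "qc_report.tsv")],
           n_input=qc_report.n_input, n_kept=qc_report.n_kept)

    # --- normalize --------------------------------------------------------
    norm = normalize_log(filtered, scale_total=config.normalize["scale_total"])
    record("normalize", dict(config.normalize), n_cells=norm.shape[0])

    # --- HVG + PCA --------------------------------------------------------
    n_top = min(config.hvg["n_top"], norm.shape[1])
    hvg = select_hvg(norm, n_top=n_top)
    pcs = run_pca(norm, hvg, n_pcs=config.pca["n_pcs"],
                  center=config.pca["center"], unit_scale=config.pca["unit_scale"])
    rio.write_tsv(pcs.embedding, os.path.join(out, "pca_embedding.tsv"), {"seed": config.seed})
    record("pca", {"n_top_hvg": n_top, **{k: config.pca[k] for k in ("n_pcs",)}},
           [os.path.join(out, "pca_embedding.tsv")],
           variance_pct_sum=float(pcs.variance_pct.sum()))

    # --- regulon activity -------------------------------------------------
    if config.aucell.get("gmt"):
        regulons = rio.read_gmt(config.aucell["gmt"])
    ranks = rank_genes_per_cell(norm, tie_seed=child_seed(config.seed, "aucell"))
    activity = score_all(ranks, regulons, top_frac=config.aucell["top_frac"])
    rio.write_tsv(activity, os.path.join(out, "activity.tsv"), {"seed": config.seed})
    record("aucell", dict(config.aucell), [os.path.join(out, "activity.tsv")],
           n_regulons=activity.shape[1])

    # --- cluster labels ---------------------------------------------------
    src = config.cluster["source"]
    if src == "truth":
        if truth is None:
            raise ValueError("cluster.source=truth requires a simulate block")
        labels = truth.true_labels.loc[norm.index].to_numpy()
    elif src == "file":
        labels = rio.read_labels(config.cluster["labels_file"]).loc[norm.index].to_numpy()
    elif src == "expression":
        labels = cluster_cells(pcs.embedding, config.cluster["k"], child_seed(config.seed, "cluster"))
    elif src == "activity":
        labels = cluster_cells(activity.fillna(0.0), config.cluster["k"], child_seed(config.seed, "cluster"))
    else:
        raise ValueError(f"unknown cluster.source {src!r}")
    pd.DataFrame({"cell_id": norm.index, "label": labels}).to_csv(
        os.path.join(out, "labels.tsv"), sep="\t", index=False)
    record("cluster", dict(config.cluster), [os.path.join(out, "labels.tsv")],
           n_clusters=int(len(np.unique(labels))))

    # --- differential activity + summary ---------------------------------
    diff_act = differential_activity(activity.dropna(axis=1), labels)
    rio.write_tsv(diff_act, os.path.join(out, "differential_activity.tsv"), {"seed": config.seed})
    summary = summarize_by_cluster(activity.dropna(axis=1), labels, row_scale=None)
    rio.write_tsv(summary, os.path.join(out, "activity_by_cluster.tsv"), {"seed": config.seed})
    record("differential_activity", {}, [os.path.join(out, "differential_activity.tsv"),
                                         os.path.join(out, "activity_by_cluster.tsv")])

    # --- CSN / NDM --------------------------------------------------------
    gene_choice = config.csn["genes"]
    if gene_choice == "regulons":
        reg_genes = sorted({g for gs in regulons.values() for g in gs} | set(regulons))
        reg_genes = [g for g in reg_genes if g in norm.columns]
        background = [g for g in norm.columns if g not in set(reg_genes)][: config.csn["n_background"]]
        subset = reg_genes + background
    elif gene_choice == "all":
        subset = None
    else:
        subset = [g for g in gene_choice if g in norm.columns]
    csn_res = build_csn(norm, CsnParams(box_frac=config.csn["box_frac"],
                                        alpha=config.csn["alpha"], gene_subset=subset))
    rio.write_tsv(csn_res.ndm, os.path.join(out, "ndm.tsv"), {"seed": config.seed})
    csn_res.edges.to_csv(os.path.join(out, "csn_edges.tsv"), sep="\t", index=False)
    ndm_tests = {}
    for cl in np.unique(labels):
        ndm_tests[str(cl)] = differential_ndm(csn_res.ndm, labels, cl)
    ndm_long = pd.concat(ndm_tests, names=["cluster", "gene"])
    rio.write_tsv(ndm_long, os.path.join(out, "ndm_differential.tsv"), {"seed": config.seed})
    record("csn", {"box_frac": config.csn["box_frac"], "alpha": config.csn["alpha"],
                   "n_genes": csn_res.ndm.shape[0]},
           [os.path.join(out, "ndm.tsv"), os.path.join(out, "csn_edges.tsv"),
            os.path.join(out, "ndm_differential.tsv")],
           n_edges=int(len(csn_res.edges)))

    # --- trajectory -------------------------------------------------------
    traj_input = pcs.embedding if config.trajectory["input"] == "expression" else activity.dropna(axis=1)
    dm = diffusion_map(traj_input, n_comps=min(config.trajectory["n_comps"], traj_input.shape[0] - 2),
                       k_neighbors=config.trajectory["k_neighbors"],
                       density_norm=config.trajectory["density_norm"])
    root_cell = select_root_cell(dm, labels, config.trajectory["root_cluster"])
    pt = diffusion_pseudotime(dm, root_cell)
    trans = cluster_transitions(dm, labels)
    pt.to_frame().to_csv(os.path.join(out, "pseudotime.tsv"), sep="\t")
    rio.write_tsv(trans, os.path.join(out, "cluster_transitions.tsv"), {"seed": config.seed})
    record("trajectory", {**{k: config.trajectory[k] for k in ("input", "k_neighbors")},
                          "root_cell": str(root_cell)},
           [os.path.join(out, "pseudotime.tsv"), os.path.join(out, "cluster_transitions.tsv")])

    # --- GSEA -------------------------------------------------------------
    if config.gsea["enabled"]:
        sets = rio.read_gmt(config.gsea["gmt"]) if config.gsea.get("gmt") else regulons
        target = config.gsea["cluster"]
        in_c = np.asarray(labels) == target
        ranking = pd.Series(
            norm.to_numpy()[in_c].mean(axis=0) - norm.to_numpy()[~in_c].mean(axis=0),
            index=norm.columns,
        )
        gsea_res = preranked_gsea(
            ranking, sets, n_perm=config.gsea["n_perm"],
            seed=child_seed(config.seed, "gsea"), weight_p=config.gsea["weight_p"],
            min_size=config.gsea["min_size"], max_size=config.gsea["max_size"],
        )
        rio.write_tsv(gsea_res, os.path.join(out, "gsea.tsv"), {"seed": config.seed})
        record("gsea", {k: config.gsea[k] for k in ("n_perm", "weight_p", "cluster")},
               [os.path.join(out, "gsea.tsv")],
               n_significant=int(gsea_res["significant"].sum()))

    with open(os.path.join(out, "run_report.json"), "w") as fh:
        fh.write(report.to_json())
    _assert_consistency(report)
    return report


def _qc_from_block(block: dict) -> QCParams:
    kwargs = {k: v for k, v in block.items() if k != "use_dataset_defaults"}
    return QCParams(**kwargs) if kwargs else QCParams()


def _assert_consistency(report: RunReport) -> None:
    """Every recorded output file must exist on disk."""
    for st in report.stages:
        for f in st.outputs:
            if not os.path.exists(f):
                raise RuntimeError(f"stage {st.stage} recorded missing output {f}")
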