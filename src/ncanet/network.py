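"""Stage-wise regulatory network assembly, trajectory comparison, graph
export, and the end-to-end pipeline driver.

A per-stage network has the ten-ish TFs in the middle, their target genes
around them, and one signed edge per nonzero control strength; TF nodes
carry the stage-mean activity, target nodes the stage-mean expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .connectivity import (
    ConnectivityPattern,
    build_initial_connectivity,
    bundled_interaction_table,
    check_nca_identifiability,
    match_tfs_to_genes,
    read_interaction_table,
    select_top_tfs,
)
from .ica import consensus_significant_genes
from .nca import NCAConfig, NCAResult, estimate_stage_tfas
from .preprocess import normalize_samples, sam_select
from .synthetic import STAGES, generate_regulatory_dataset

__all__ = [
    "RegulatoryNetwork",
    "build_stage_network",
    "compare_tfa_vs_expression",
    "export_network",
    "read_network_tsv",
    "default_pipeline_config",
    "run_pipeline",
]


@dataclass
class RegulatoryNetwork:
    """Signed, weighted TF -> target network for one disease stage."""

    stage: str
    edges: list[tuple[str, str, float]]
    node_attrs: dict[str, dict]

    def __eq__(self, other):
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.stage == other.stage
            and sorted(self.edges) == sorted(other.edges)
            and self.node_attrs == other.node_attrs
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(stage=self.stage)
        for node, attrs in self.node_attrs.items():
            g.add_node(node, **attrs)
        for tf, tg, w in self.edges:
            g.add_edge(tf, tg, control_strength=float(w))
        return g


def build_stage_network(
    result: NCAResult,
    pattern: ConnectivityPattern,
    stage_expr: pd.DataFrame,
    stage: str,
    min_abs_cs: float | None = None,
) -> RegulatoryNetwork:
    """One edge per nonzero control strength; node values are stage means.

    ``min_abs_cs`` optionally drops edges with |control strength| below
    the cutoff (no cutoff by default).
    """
    cs = result.cs
    edges = []
    for tf in cs.columns:
        col = cs[tf]
        for gene, w in col[col != 0].items():
            if min_abs_cs is not None and abs(w) < min_abs_cs:
                continue
            edges.append((str(tf), str(gene), float(w)))
    tfa_means = result.tfa.mean(axis=1)
    expr_means = stage_expr.mean(axis=1)
    node_attrs: dict[str, dict] = {}
    for tf in cs.columns:
        node_attrs[str(tf)] = {"role": "TF", "value": float(tfa_means[tf])}
    for gene in cs.index:
        if (cs.loc[gene] != 0).any():
            node_attrs[str(gene)] = {
                "role": "TG",
                "value": float(expr_means.get(gene, np.nan)),
            }
    return RegulatoryNetwork(stage=str(stage), edges=edges, node_attrs=node_attrs)


def compare_tfa_vs_expression(
    trajectories: pd.DataFrame,
    expr_by_stage: Mapping[str, pd.DataFrame],
    tf_gene_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long table contrasting TF activity with the TF's own expression.

    ``trajectories`` is TF x stage (stage-mean activities). For each TF the
    stage-mean expression of its own gene (via ``tf_gene_map``, identity by
    default) is looked up per stage; both columns are z-scored across
    stages per TF so shapes are comparable. A TF whose gene is missing from
    the expression data gets NaN expression and a warning.
    """
    tf_gene_map = dict(tf_gene_map or {})
    rows = []
    stages = list(trajectories.columns)
    for tf in trajectories.index:
        gene = tf_gene_map.get(tf, tf)
        tfa = trajectories.loc[tf, stages].values.astype(float)
        expr = np.full(len(stages), np.nan)
        for k, stage in enumerate(stages):
            mat = expr_by_stage[stage]
            if gene in mat.index:
                expr[k] = mat.loc[gene].mean()
        if np.isnan(expr).all():
            warnings.warn(f"TF {tf}: gene {gene} absent from expression data")

        def _z(v):
            sd = np.nanstd(v)
            if not np.isfinite(sd) or sd < 1e-12:
                return np.zeros_like(v) if np.isfinite(v).any() else v
            return (v - np.nanmean(v)) / sd

        tfa_z, expr_z = _z(tfa), _z(expr)
        for k, stage in enumerate(stages):
            rows.append(
                {
                    "tf": str(tf),
                    "stage": str(stage),
                    "tfa": float(tfa_z[k]),
                    "tf_gene_expression": float(expr_z[k]),
                }
            )
    return pd.DataFrame(rows)


def export_network(
    network: RegulatoryNetwork, format: str, path: str | Path
) -> None:
    """Write a network as SIF, GraphML or a TSV edge list.

    SIF lines read ``tf activates|represses target`` by the sign of the
    control strength; TSV round-trips losslessly at 12 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "sif":
        with path.open("w") as fh:
            for tf, tg, w in network.edges:
                rel = "activates" if w >= 0 else "represses"
                fh.write(f"{tf}\t{rel}\t{tg}\n")
    elif format == "tsv":
        with path.open("w") as fh:
            fh.write(f"# stage: {network.stage}\n")
            fh.write("tf\ttarget\tcontrol_strength\ttf_value\ttarget_value\n")
            for tf, tg, w in network.edges:
                fh.write(
                    f"{tf}\t{tg}\t{w:.12g}"
                    f"\t{network.node_attrs[tf]['value']:.12g}"
                    f"\t{network.node_attrs[tg]['value']:.12g}\n"
                )
    elif format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_tsv(path: str | Path) -> RegulatoryNetwork:
    """Read back a TSV edge list written by :func:`export_network`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    stage = "unknown"
    if lines and lines[0].startswith("# stage:"):
        stage = lines[0].split(":", 1)[1].strip()
        lines = lines[1:]
    df = pd.DataFrame(
        [ln.split("\t") for ln in lines[1:] if ln.strip()],
        columns=lines[0].split("\t"),
    )
    edges = []
    node_attrs: dict[str, dict] = {}
    for _, row in df.iterrows():
        w = float(row["control_strength"])
        edges.append((row["tf"], row["target"], w))
        node_attrs[row["tf"]] = {"role": "TF", "value": float(row["tf_value"])}
        node_attrs[row["target"]] = {
            "role": "TG",
            "value": float(row["target_value"]),
        }
    return RegulatoryNetwork(stage=stage, edges=edges, node_attrs=node_attrs)


def default_pipeline_config() -> dict:
    """Desk-scale defaults for the end-to-end synthetic study."""
    return {
        "seed": 0,
        "interactions": None,  # None -> packaged curated table
        "stages": list(STAGES),
        "simulate": {
            "samples_per_stage": [9, 7, 8, 7],
            "n_filler_genes": 300,
            "noise_sd": 0.1,
            "base_sd": 0.5,
            "tfa_scale": 1.0,
            "tfa_shift": 2.0,
        },
        "sam": {"target_n": 200, "n_perms": 50},
        "ica": {"n_runs": 10, "top_k": 60, "min_frequency": 0.5, "a1": 1.0},
        "connect": {"min_targets": 5, "strict": False},
        "nca": {"n_restarts": 3, "tol": 1e-6, "max_iter": 500},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None, out_dir: str | Path, seed: int | None = None):
    """End-to-end run on a seeded synthetic study.

    Chains simulate -> SAM filter (per control-vs-stage group) -> consensus
    ICA selection -> connectivity assembly -> per-stage NCA -> network and
    trajectory export. Ground-truth regulation follows the packaged curated
    TF->target topology; unregulated filler genes emulate the bulk of the
    array. All outputs are TSV/YAML under ``out_dir``; a fixed seed makes
    every byte reproducible.
    """
    cfg = _merge(default_pipeline_config(), config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    sim = cfg["simulate"]
    samples_per_stage = list(sim["samples_per_stage"])
    if len(samples_per_stage) != len(stages):
        raise ValueError("samples_per_stage must align with stages")

    # --- ground truth topology from the curated interaction table
    table = cfg["interactions"] or bundled_interaction_table()
    interactions = read_interaction_table(table)
    true_pattern = build_initial_connectivity(interactions)
    L = true_pattern.n_tfs

    # --- simulate: per-stage bilinear expression + null filler genes
    rng = np.random.default_rng(seed)
    # stage-dependent TF activity means: control at 0, later stages shifted
    shift = float(sim["tfa_shift"])
    stage_means = np.zeros((L, len(stages)))
    stage_means[:, 1:] = rng.uniform(-shift, shift, size=(L, len(stages) - 1))
    n_filler = int(sim["n_filler_genes"])
    filler_genes = [f"NULL{i + 1:04d}" for i in range(n_filler)]
    filler_baseline = rng.normal(0.0, 1.0, size=n_filler)
    # TF transcripts: flat baseline + noise, deliberately NOT tracking the
    # TF's activity (activity is set post-translationally in the model);
    # TFs that are themselves targets already have an expression row
    tf_only = [t for t in true_pattern.tfs if t not in set(true_pattern.genes)]
    tf_baseline = rng.normal(0.0, 1.0, size=len(tf_only))

    # control strengths are a stage-invariant property of the network:
    # draw them once and share across stages
    true_cs = generate_regulatory_dataset(
        true_pattern, n_samples=1, seed=seed
    ).true_cs

    stage_exprs: dict[str, pd.DataFrame] = {}
    labels_all, cols_all = [], []
    for si, (stage, m) in enumerate(zip(stages, samples_per_stage)):
        srng = np.random.default_rng((seed * 1009 + 17 + si) % (2**31 - 1))
        tfa = stage_means[:, si][:, None] + srng.normal(
            0.0, float(sim["tfa_scale"]), size=(L, m)
        )
        expr_t = true_cs @ tfa + srng.normal(
            0.0, float(sim["noise_sd"]), size=(true_pattern.n_genes, m)
        )
        filler = filler_baseline[:, None] + srng.normal(
            0.0, float(sim["base_sd"]), size=(n_filler, m)
        )
        tf_expr = tf_baseline[:, None] + srng.normal(
            0.0, float(sim["base_sd"]), size=(len(tf_only), m)
        )
        cols = [f"{stage}_{k + 1:02d}" for k in range(m)]
        full = pd.DataFrame(
            np.vstack([expr_t, tf_expr, filler]),
            index=list(true_pattern.genes) + tf_only + filler_genes,
            columns=cols,
        )
        stage_exprs[stage] = full
        labels_all.extend([stage] * m)
        cols_all.extend(cols)

    combined = pd.concat([stage_exprs[s] for s in stages], axis=1)
    nio.write_expression(combined, out_dir / "expression.tsv")
    nio.write_labels(
        pd.Series(labels_all, index=cols_all, name="stage"),
        out_dir / "labels.tsv",
    )

    # --- SAM + consensus ICA per control-vs-stage group
    control = stages[0]
    selections: dict[str, list[str]] = {}
    for stage in stages[1:]:
        pair = pd.concat([stage_exprs[control], stage_exprs[stage]], axis=1)
        pair_labels = [control] * samples_per_stage[0] + [stage] * (
            samples_per_stage[stages.index(stage)]
        )
        sam = sam_select(
            pair,
            pair_labels,
            target_n=int(cfg["sam"]["target_n"]),
            n_perms=int(cfg["sam"]["n_perms"]),
            seed=seed + 101,
        )
        filtered = normalize_samples(pair.loc[sam.selected])
        sel = consensus_significant_genes(
            filtered,
            n_runs=int(cfg["ica"]["n_runs"]),
            top_k=int(cfg["ica"]["top_k"]),
            min_frequency=float(cfg["ica"]["min_frequency"]),
            a1=float(cfg["ica"]["a1"]),
            seed=seed + 211,
        )
        selections[stage] = sel.selected
    union: list[str] = []
    seen: set[str] = set()
    for stage in stages[1:]:
        for g in selections[stage]:
            if g not in seen:
                seen.add(g)
                union.append(g)
    pd.DataFrame({"gene": union}).to_csv(
        out_dir / "selected_genes.tsv", sep="\t", index=False
    )

    # --- connectivity on the selected genes
    matched = match_tfs_to_genes(interactions, union)
    top = select_top_tfs(
        matched,
        min_targets=int(cfg["connect"]["min_targets"]),
        strict=bool(cfg["connect"]["strict"]),
    )
    if not top:
        raise RuntimeError("no TFs survive connectivity filtering")
    pattern = build_initial_connectivity(top)
    pattern.write(out_dir / "connectivity.tsv")
    report = check_nca_identifiability(pattern, n_samples=min(samples_per_stage))

    # --- per-stage NCA
    ncfg = NCAConfig(
        max_iter=int(cfg["nca"]["max_iter"]),
        tol=float(cfg["nca"]["tol"]),
        n_restarts=int(cfg["nca"]["n_restarts"]),
        seed=seed + 307,
    )
    stage_E = {s: stage_exprs[s].loc[pattern.genes] for s in stages}
    results, trajectories = estimate_stage_tfas(stage_E, pattern, ncfg, stages=stages)
    trajectories.to_csv(out_dir / "tfa_trajectories.tsv", sep="\t",
                        float_format="%.12g")

    # --- networks and comparison table
    networks = {}
    for stage in stages:
        net = build_stage_network(results[stage], pattern, stage_exprs[stage], stage)
        networks[stage] = net
        export_network(net, "tsv", out_dir / f"network_{stage}.tsv")
        export_network(net, "sif", out_dir / f"network_{stage}.sif")
    comparison = compare_tfa_vs_expression(trajectories, stage_exprs)
    comparison.to_csv(out_dir / "tfa_vs_expression.tsv", sep="\t", index=False,
                      float_format="%.12g")

    summary = {
        "seed": seed,
        "stages": stages,
        "n_genes_simulated": int(combined.shape[0]),
        "n_samples": int(combined.shape[1]),
        "selected_per_group": {s: len(selections[s]) for s in stages[1:]},
        "n_selected_union": len(union),
        "n_tfs": pattern.n_tfs,
        "n_targets": pattern.n_genes,
        "n_interactions": int(pattern.support.sum()),
        "identifiability": report.to_dict(),
        "per_stage": {
            s: {
                "final_residual": results[s].final_residual,
                "converged": bool(results[s].converged),
                "n_iter": int(results[s].n_iter),
            }
            for s in stages
        },
    }
    with (out_dir / "summary.yaml").open("w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return {
        "config": cfg,
        "pattern": pattern,
        "true_cs": true_cs,
        "results": results,
        "trajectories": trajectories,
        "networks": networks,
        "summary": summary,
    }
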