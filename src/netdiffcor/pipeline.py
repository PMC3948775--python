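"""End-to-end pipeline: counts + network in, results bundle out.

Stages run in a fixed order — read, trim, normalize, edge statistics,
permutation null, two-criterion filter, classification, enrichment, network
statistics, export — and every run writes a manifest recording the resolved
configuration, the seed, package versions, and the summary counts
(significant edges, per-type counts, largest-component size, enriched
pathways) for the run's own data.  Identical configuration and seed produce
a byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx
import numpy
import pandas
import scipy
import yaml

from . import __version__
from .classify import classify_significant, type_counts
from .edge_stats import edge_statistics, write_edge_statistics
from .enrichment import enrich_pathways, write_enrichment
from .expression import normalize_log_cpm, read_counts
from .network import (
    InteractionNetwork,
    edge_key,
    largest_connected_component,
    node_degrees,
    read_network,
    trim_to_genes,
    write_annotated_graph,
)
from .permutation import PermutationConfig, build_null, significant_interactions

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts: str = ""
    groups: str = ""
    network: str = ""
    pathway_names: str | None = None
    output_dir: str = "results"
    permutations: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    p_mode: str = "count_over_N"
    enrich_tail: str = "standard"
    export_formats: tuple[str, ...] = ("graphml", "xgmml")
    n_workers: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "export_formats" in data:
            data["export_formats"] = tuple(data["export_formats"])
        return cls(**data)


def _edge_attr_table(rows, group_order, cm):
    """Per-edge export attributes: correlations, p-values, type/style,
    pathway ids, and the two genes' raw read counts."""
    first, second = group_order
    raw = cm.counts
    attrs = {}
    for _, row in rows.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        attrs[edge_key(a, b)] = {
            f"r_{first}": float(row[f"r_{first}"]),
            f"r_{second}": float(row[f"r_{second}"]),
            "z_diff": float(row["z_diff"]),
            "p_zdiff": float(row["p_zdiff"]),
            "corr_type": row["corr_type"],
            "color": row["color"],
            "line_style": row["line_style"],
            "pathways": row["pathways"],
            f"counts_{a}": ";".join(str(c) for c in raw.loc[a]),
            f"counts_{b}": ";".join(str(c) for c in raw.loc[b]),
        }
    return attrs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis; returns the manifest dict.

    On any stage failure the partially written output directory is removed
    and a PipelineError naming the stage is raised.
    """
    outdir = Path(cfg.output_dir)
    for name in ("counts", "groups", "network"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise PipelineError(f"stage read: {name} path does not exist: {p}")
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        cm = read_counts(cfg.counts, cfg.groups)
        net = read_network(cfg.network, cfg.pathway_names)
        group_order = cm.group_labels

        stage = "trim"
        trimmed = trim_to_genes(net, set(cm.genes))

        stage = "normalize"
        em = normalize_log_cpm(cm)

        stage = "edge_stats"
        stats = edge_statistics(em, cm, trimmed)

        stage = "build_null"
        pcfg = PermutationConfig(
            n_perm=cfg.permutations,
            seed=cfg.seed,
            alpha=cfg.alpha,
            p_mode=cfg.p_mode,
            n_workers=cfg.n_workers,
        )
        null = build_null(em, cm, trimmed, pcfg)

        stage = "significant_interactions"
        sig_table = significant_interactions(stats, null, pcfg)

        stage = "classify"
        classified = classify_significant(sig_table, group_order, alpha=cfg.alpha)
        classified["pathways"] = [
            ";".join(sorted(trimmed.edge_pathways[edge_key(a, b)]))
            for a, b in zip(classified["gene_a"], classified["gene_b"])
        ]

        stage = "enrich"
        enr = enrich_pathways(
            classified, trimmed, mode=cfg.enrich_tail, alpha=cfg.alpha,
            group_order=group_order,
        )

        stage = "netstats"
        sig_edges = {
            edge_key(a, b) for a, b in zip(classified["gene_a"], classified["gene_b"])
        }
        sig_net = InteractionNetwork(
            edge_pathways={e: trimmed.edge_pathways[e] for e in sig_edges},
            pathway_names=dict(trimmed.pathway_names),
        )
        if sig_net.n_edges:
            lcc = largest_connected_component(sig_net)
            lcc_edges, lcc_nodes = lcc.n_edges, lcc.n_nodes
        else:
            lcc_edges = lcc_nodes = 0
        enriched_ids = set(enr.loc[enr["enriched"], "pathway_id"])
        enr_edges = {
            e for e in sig_edges if trimmed.edge_pathways[e] & enriched_ids
        }
        enr_net = InteractionNetwork(
            edge_pathways={e: trimmed.edge_pathways[e] for e in enr_edges},
            pathway_names=dict(trimmed.pathway_names),
        )

        stage = "export"
        write_edge_statistics(sig_table, outdir / "edge_statistics.tsv")
        classified.to_csv(
            outdir / "significant_edges.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        write_enrichment(enr, outdir / "enrichment.tsv")
        node_degrees(sig_net).to_csv(outdir / "node_degrees.tsv", sep="\t", index=False)
        attrs = _edge_attr_table(classified, group_order, cm)
        for fmt in cfg.export_formats:
            write_annotated_graph(
                sig_net, attrs, outdir / f"significant_network.{fmt}", format=fmt
            )
            enr_attrs = {e: attrs[e] for e in enr_net.edges}
            write_annotated_graph(
                enr_net, enr_attrs, outdir / f"enriched_subnetwork.{fmt}", format=fmt
            )

        per_type = type_counts(classified, group_order)
        manifest = {
            "config": {
                **{k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()}
            },
            "versions": {
                "netdiffcor": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
                "networkx": networkx.__version__,
            },
            "counts": {
                "genes": len(cm.genes),
                "samples": len(cm.samples),
                "group_sizes": {
                    lab: len(cm.samples_in_group(lab)) for lab in group_order
                },
                "network_edges_raw_rows": net.meta.get("raw_row_count"),
                "network_edges_deduplicated": net.n_edges,
                "trimmed_nodes": trimmed.n_nodes,
                "trimmed_edges": trimmed.n_edges,
                "invalid_edges": int((~stats["valid"]).sum()),
                "significant_edges": int(len(classified)),
                "significant_nodes": int(sig_net.n_nodes),
                "lcc_edges": lcc_edges,
                "lcc_nodes": lcc_nodes,
                "per_type": per_type,
                "enriched_pathways": int(enr["enriched"].sum()),
                "edges_in_enriched_pathways": int(enr_net.n_edges),
                "nodes_in_enriched_pathways": int(enr_net.n_nodes),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for f in outdir.glob("*"):
                if f.is_file():
                    f.unlink()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
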