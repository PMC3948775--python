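"""Pathway-annotated gene–gene interaction networks.

The interaction network is an undirected simple graph over gene identifiers.
Each edge carries a (possibly empty) set of pathway identifiers — the KEGG
pathways in which the interaction occurs — and the network carries a mapping
from pathway id to display name.  Edges are unordered pairs; directionality
of the underlying database relations is deliberately discarded because every
downstream statistic (Pearson correlation of the two genes' expression) is
symmetric in the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

Edge = tuple[str, str]

XGMML_NS = "http://www.cs.rpi.edu/XGMML"


class NetworkFormatError(ValueError):
    """Raised when a network file does not match the expected format."""


def edge_key(a: str, b: str) -> Edge:
    """Canonical (sorted) orientation of an undirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionNetwork:
    """Undirected gene interaction network with per-edge pathway annotations.

    Invariants: no self-loops, each unordered pair at most once, every edge
    endpoint is a node, and every pathway id on an edge has a display name
    (defaulting to the id itself).
    """

    edge_pathways: dict[Edge, frozenset[str]] = field(default_factory=dict)
    pathway_names: dict[str, str] = field(default_factory=dict)
    _extra_nodes: set[str] = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[Edge, frozenset[str]] = {}
        for (a, b), pws in self.edge_pathways.items():
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            key = edge_key(a, b)
            normalized[key] = normalized.get(key, frozenset()) | frozenset(pws)
        self.edge_pathways = normalized
        for pws in self.edge_pathways.values():
            for pw in pws:
                self.pathway_names.setdefault(pw, pw)

    # -- basic views ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        out = set(self._extra_nodes)
        for a, b in self.edge_pathways:
            out.add(a)
            out.add(b)
        return out

    @property
    def edges(self) -> set[Edge]:
        return set(self.edge_pathways)

    @property
    def n_edges(self) -> int:
        return len(self.edge_pathways)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def pathways(self) -> set[str]:
        """All pathway ids referenced by at least one edge."""
        out: set[str] = set()
        for pws in self.edge_pathways.values():
            out |= pws
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), pws in self.edge_pathways.items():
            g.add_edge(a, b, pathways=";".join(sorted(pws)))
        return g


def read_network(path: str | Path, names_path: str | Path | None = None) -> InteractionNetwork:
    """Read an interaction network from a tab-separated edge list.

    Expected header: ``gene_a  gene_b  pathways`` with semicolon-separated
    pathway ids (empty allowed).  Duplicate rows — including reversed
    duplicates — are merged with pathway-set union; self-loop rows are
    dropped with a warning.  A companion two-column TSV
    (``pathway_id  name``) may supply display names.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        raise NetworkFormatError(f"empty network file: {path}")
    for col in ("gene_a", "gene_b", "pathways"):
        if col not in df.columns:
            raise NetworkFormatError(f"network file {path} is missing required column {col!r}")
    if df.empty:
        raise NetworkFormatError(f"network file {path} contains no edges")

    edge_pathways: dict[Edge, frozenset[str]] = {}
    self_loops = 0
    raw_rows = len(df)
    for a, b, pw in zip(df["gene_a"], df["gene_b"], df["pathways"]):
        if a == b:
            self_loops += 1
            continue
        pws = frozenset(p for p in pw.split(";") if p)
        key = edge_key(a, b)
        edge_pathways[key] = edge_pathways.get(key, frozenset()) | pws
    if self_loops:
        logger.warning("dropped %d self-loop row(s) while reading %s", self_loops, path)

    names: dict[str, str] = {}
    if names_path is not None:
        ndf = pd.read_csv(names_path, sep="\t", comment="#", dtype=str, keep_default_na=False)
        for col in ("pathway_id", "name"):
            if col not in ndf.columns:
                raise NetworkFormatError(
                    f"pathway-name file {names_path} is missing required column {col!r}"
                )
        names = dict(zip(ndf["pathway_id"], ndf["name"]))

    net = InteractionNetwork(edge_pathways=edge_pathways, pathway_names=names)
    net.meta.update(
        raw_row_count=raw_rows,
        self_loop_rows=self_loops,
        deduplicated_edge_count=net.n_edges,
    )
    return net


def write_network_tsv(net: InteractionNetwork, path: str | Path) -> None:
    """Write the edge list back out in the same TSV format read_network reads."""
    rows = [
        {"gene_a": a, "gene_b": b, "pathways": ";".join(sorted(pws))}
        for (a, b), pws in sorted(net.edge_pathways.items())
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "pathways"]).to_csv(
        path, sep="\t", index=False
    )


def trim_to_genes(net: InteractionNetwork, genes: Iterable[str]) -> InteractionNetwork:
    """Induced subnetwork on the genes present in both the network and `genes`.

    Nodes in the intersection are kept even if they lose all their edges; the
    count of such newly isolated nodes is recorded in ``meta['isolated_nodes']``
    (downstream edge statistics never see them, as they are edge-driven).
    """
    genes = set(genes)
    if not genes:
        raise ValueError("gene set is empty")
    common = net.nodes & genes
    if not common:
        raise ValueError("no genes in common between network and expression data")
    kept = {
        e: pws for e, pws in net.edge_pathways.items() if e[0] in common and e[1] in common
    }
    with_edges = {n for e in kept for n in e}
    trimmed = InteractionNetwork(
        edge_pathways=kept,
        pathway_names=dict(net.pathway_names),
        _extra_nodes=common - with_edges,
    )
    trimmed.meta["isolated_nodes"] = len(common - with_edges)
    return trimmed


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subnetwork of the component with the most nodes.

    Ties are broken by the lexicographically smallest member node id, so the
    result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    g = net.to_networkx()
    components = [set(c) for c in nx.connected_components(g)]
    max_size = max(len(c) for c in components)
    candidates = [c for c in components if len(c) == max_size]
    best = min(candidates, key=min)
    kept = {e: pws for e, pws in net.edge_pathways.items() if e[0] in best}
    lcc = InteractionNetwork(
        edge_pathways=kept,
        pathway_names=dict(net.pathway_names),
        _extra_nodes=best - {n for e in kept for n in e},
    )
    return lcc


def node_degrees(net: InteractionNetwork) -> pd.DataFrame:
    """Per-gene interaction counts, sorted by degree descending then gene id."""
    deg = {n: 0 for n in net.nodes}
    for a, b in net.edge_pathways:
        deg[a] += 1
        deg[b] += 1
    df = pd.DataFrame({"gene": list(deg), "degree": list(deg.values())})
    df = df.sort_values(["degree", "gene"], ascending=[False, True], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Annotated graph export (GraphML / XGMML)
# ---------------------------------------------------------------------------

def format_attr(value) -> str:
    """Render an attribute value as a string (numbers at 15 significant digits)."""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.15g}"
    if isinstance(value, (list, tuple, set, frozenset)):
        return ";".join(sorted(str(v) for v in value))
    return str(value)


def _stringify_attrs(net: InteractionNetwork, attrs: Mapping[Edge, Mapping[str, object]]):
    edges = net.edges
    out: dict[Edge, dict[str, str]] = {}
    for e, mapping in attrs.items():
        key = edge_key(*e)
        if key not in edges:
            raise ValueError(f"attribute table references edge {key} absent from network")
        out[key] = {k: format_attr(v) for k, v in mapping.items()}
    return out


def write_annotated_graph(
    net: InteractionNetwork,
    attrs: Mapping[Edge, Mapping[str, object]],
    path: str | Path,
    format: str = "graphml",
) -> None:
    """Export the network with per-edge attributes as GraphML or XGMML.

    All attribute values are serialized as strings so the files round-trip
    bit-for-bit; Cytoscape reads both formats.  Visual attributes (``color``,
    ``line_style``) are ordinary edge attributes here.
    """
    str_attrs = _stringify_attrs(net, attrs)
    if format == "graphml":
        _write_graphml(net, str_attrs, path)
    elif format == "xgmml":
        _write_xgmml(net, str_attrs, path)
    else:
        raise ValueError(f"unknown export format: {format!r} (expected 'graphml' or 'xgmml')")


def _write_graphml(net, str_attrs, path):
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    for a, b in sorted(net.edge_pathways):
        g.add_edge(a, b, **str_attrs.get((a, b), {}))
    nx.write_graphml(g, path)


def _write_xgmml(net, str_attrs, path):
    root = etree.Element(
        "graph",
        nsmap={None: XGMML_NS},
        label="netdiffcor",
        directed="0",
    )
    node_ids = {n: str(i) for i, n in enumerate(sorted(net.nodes))}
    for name, nid in node_ids.items():
        etree.SubElement(root, "node", id=nid, label=name)
    for a, b in sorted(net.edge_pathways):
        el = etree.SubElement(
            root,
            "edge",
            source=node_ids[a],
            target=node_ids[b],
            label=f"{a} (pp) {b}",
        )
        for k, v in sorted(str_attrs.get((a, b), {}).items()):
            etree.SubElement(el, "att", type="string", name=k, value=v)
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_annotated_graph(path: str | Path, format: str = "graphml"):
    """Read back a file written by :func:`write_annotated_graph`.

    Returns ``(nodes, edge_attrs)`` where ``edge_attrs`` maps canonical edge
    keys to their string attribute dicts.  Used for round-trip verification.
    """
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = set(g.nodes)
        edge_attrs = {edge_key(a, b): dict(d) for a, b, d in g.edges(data=True)}
        return nodes, edge_attrs
    if format == "xgmml":
        tree = etree.parse(str(path))
        root = tree.getroot()
        ns = {"x": XGMML_NS}
        id_to_label = {
            el.get("id"): el.get("label") for el in root.findall("x:node", ns)
        }
        nodes = set(id_to_label.values())
        edge_attrs = {}
        for el in root.findall("x:edge", ns):
            a = id_to_label[el.get("source")]
            b = id_to_label[el.get("target")]
            attrs = {
                att.get("name"): att.get("value") for att in el.findall("x:att", ns)
            }
            edge_attrs[edge_key(a, b)] = attrs
        return nodes, edge_attrs
    raise ValueError(f"unknown export format: {format!r}")
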