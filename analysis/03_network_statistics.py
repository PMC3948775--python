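#!/usr/bin/env python
"""Network statistics of the significant-interaction network.

Reads the significant edges from results/run/, rebuilds the network, and
tabulates node degrees (hub genes), the largest connected component, and
the per-pathway split of significant interactions between the two groups.
Writes results/tables/{node_degrees,pathway_split}.tsv.
"""

from pathlib import Path

import pandas as pd

import netdiffcor as nd
from netdiffcor.network import InteractionNetwork, largest_connected_component, node_degrees

run = Path("results/run")
tables = Path("results/tables")
tables.mkdir(parents=True, exist_ok=True)

sig = pd.read_csv(run / "significant_edges.tsv", sep="\t")
edge_pathways = {
    (row.gene_a, row.gene_b): frozenset(
        p for p in str(row.pathways).split(";") if p and p != "nan"
    )
    for row in sig.itertuples()
}
net = InteractionNetwork(edge_pathways=edge_pathways)

deg = node_degrees(net)
deg.to_csv(tables / "node_degrees.tsv", sep="\t", index=False)
print("top hub genes of the significant network:")
print(deg.head(5).to_string(index=False))

lcc = largest_connected_component(net)
print(f"\nlargest connected component: {lcc.n_edges} edges, {lcc.n_nodes} nodes "
      f"of {net.n_edges} edges / {net.n_nodes} nodes total")

enr = pd.read_csv(run / "enrichment.tsv", sep="\t")
split = enr[["pathway_id", "name", "p_adj", "k", "n_LA", "n_HA", "enriched"]]
split.to_csv(tables / "pathway_split.tsv", sep="\t", index=False)
print(f"\nper-pathway LA/HA interaction splits written "
      f"({int(enr['enriched'].sum())} pathways enriched):")
print(split.head(5).to_string(index=False))
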