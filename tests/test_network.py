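"""Interaction-network reading, trimming, components, degrees, export."""

import numpy as np
import pytest

from netdiffcor.network import (
    InteractionNetwork,
    NetworkFormatError,
    edge_key,
    largest_connected_component,
    node_degrees,
    read_annotated_graph,
    read_network,
    trim_to_genes,
    write_annotated_graph,
    write_network_tsv,
)


def write_edges(path, rows, header="gene_a\tgene_b\tpathways"):
    lines = [header] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadNetwork:
    def test_reversed_duplicates_merge_pathways_by_union(self, tmp_path):
        p = write_edges(tmp_path / "net.tsv", [("g1", "g2", "ssc00480"), ("g2", "g1", "ssc00600")])
        net = read_network(p)
        assert net.edges == {("g1", "g2")}
        assert net.edge_pathways[("g1", "g2")] == {"ssc00480", "ssc00600"}

    def test_self_loops_dropped_and_counted(self, tmp_path, caplog):
        p = write_edges(tmp_path / "net.tsv", [("g1", "g1", "ssc00480"), ("g1", "g2", "")])
        with caplog.at_level("WARNING"):
            net = read_network(p)
        assert net.n_edges == 1
        assert net.meta["self_loop_rows"] == 1
        assert any("self-loop" in r.message for r in caplog.records)

    def test_empty_pathway_sets_allowed(self, tmp_path):
        p = write_edges(tmp_path / "net.tsv", [("a", "b", ""), ("b", "c", "ssc00230")])
        net = read_network(p)
        assert net.n_edges == 2
        assert net.nodes == {"a", "b", "c"}
        assert net.edge_pathways[("a", "b")] == frozenset()

    def test_missing_column_named_in_error(self, tmp_path):
        p = (tmp_path / "bad.tsv")
        p.write_text("gene_a\tgene_b\na\tb\n")
        with pytest.raises(NetworkFormatError, match="pathways"):
            read_network(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_a\tgene_b\tpathways\n")
        with pytest.raises(NetworkFormatError):
            read_network(p)

    def test_pathway_names_companion_file(self, tmp_path):
        p = write_edges(tmp_path / "net.tsv", [("a", "b", "ssc00480")])
        names = tmp_path / "names.tsv"
        names.write_text("pathway_id\tname\nssc00480\tGlutathione metabolism\n")
        net = read_network(p, names)
        assert net.pathway_names["ssc00480"] == "Glutathione metabolism"

    def test_tsv_round_trip_is_identity(self, tmp_path):
        p = write_edges(
            tmp_path / "net.tsv",
            [("b", "a", "p1;p2"), ("a", "c", ""), ("c", "d", "p2")],
        )
        net = read_network(p)
        out = tmp_path / "out.tsv"
        write_network_tsv(net, out)
        again = read_network(out)
        assert again.edges == net.edges
        assert again.edge_pathways == net.edge_pathways


class TestTrim:
    @staticmethod
    def chain_net():
        return InteractionNetwork(
            edge_pathways={
                ("a", "b"): frozenset({"p1"}),
                ("b", "c"): frozenset({"p2"}),
                ("c", "d"): frozenset(),
            }
        )

    def test_induced_subgraph(self):
        t = trim_to_genes(self.chain_net(), {"a", "b", "c"})
        assert t.edges == {("a", "b"), ("b", "c")}
        assert t.nodes == {"a", "b", "c"}
        assert t.edge_pathways[("a", "b")] == {"p1"}

    def test_superset_leaves_network_unchanged(self):
        net = self.chain_net()
        t = trim_to_genes(net, set("abcdxyz"))
        assert t.edges == net.edges and t.nodes == net.nodes

    def test_isolated_intersection_nodes_kept_and_counted(self):
        t = trim_to_genes(InteractionNetwork(edge_pathways={("a", "b"): frozenset()}), {"a"})
        assert t.n_edges == 0
        assert t.nodes == {"a"}
        assert t.meta["isolated_nodes"] == 1

    def test_no_common_genes_is_an_error(self):
        with pytest.raises(ValueError, match="no genes in common"):
            trim_to_genes(self.chain_net(), {"zz"})

    def test_idempotent(self):
        net = self.chain_net()
        once = trim_to_genes(net, {"a", "b", "c"})
        twice = trim_to_genes(once, {"a", "b", "c"})
        assert twice.edges == once.edges and twice.nodes == once.nodes


class TestLargestComponent:
    def test_picks_biggest_component(self):
        net = InteractionNetwork(
            edge_pathways={("a", "b"): frozenset(), ("b", "c"): frozenset(), ("d", "e"): frozenset()}
        )
        lcc = largest_connected_component(net)
        assert lcc.nodes == {"a", "b", "c"} and lcc.n_edges == 2

    def test_connected_network_is_its_own_lcc(self):
        net = InteractionNetwork(edge_pathways={("a", "b"): frozenset(), ("b", "c"): frozenset()})
        lcc = largest_connected_component(net)
        assert lcc.nodes == net.nodes and lcc.edges == net.edges

    def test_tie_broken_by_smallest_member(self):
        net = InteractionNetwork(edge_pathways={("c", "d"): frozenset(), ("a", "b"): frozenset()})
        assert largest_connected_component(net).nodes == {"a", "b"}

    def test_empty_network_error(self):
        with pytest.raises(ValueError):
            largest_connected_component(InteractionNetwork())

    def test_matches_flood_fill_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            m = int(rng.integers(1, min(3 * n, n * (n - 1) // 2)))
            names = [f"n{i:03d}" for i in range(n)]
            edges = set()
            while len(edges) < m:
                i, j = rng.integers(0, n, size=2)
                if i != j:
                    edges.add(edge_key(names[i], names[j]))
            net = InteractionNetwork(edge_pathways={e: frozenset() for e in edges})

            # flood-fill oracle
            adj = {x: set() for x in net.nodes}
            for a, b in edges:
                adj[a].add(b)
                adj[b].add(a)
            seen, comps = set(), []
            for start in sorted(adj):
                if start in seen:
                    continue
                stack, comp = [start], set()
                while stack:
                    v = stack.pop()
                    if v in comp:
                        continue
                    comp.add(v)
                    stack.extend(adj[v] - comp)
                seen |= comp
                comps.append(comp)
            best = min(
                (c for c in comps if len(c) == max(map(len, comps))), key=min
            )
            assert largest_connected_component(net).nodes == best


class TestDegrees:
    def test_counts_and_ordering(self):
        net = InteractionNetwork(
            edge_pathways={("a", "b"): frozenset(), ("a", "c"): frozenset()}
        )
        df = node_degrees(net)
        assert dict(zip(df["gene"], df["degree"])) == {"a": 2, "b": 1, "c": 1}
        assert list(df["gene"]) == ["a", "b", "c"]  # degree desc, then gene id

    def test_isolated_node_has_degree_zero(self):
        net = InteractionNetwork(
            edge_pathways={("a", "b"): frozenset()}, _extra_nodes={"z"}
        )
        df = node_degrees(net)
        assert df.set_index("gene").loc["z", "degree"] == 0

    def test_handshake_lemma(self, null_dataset):
        net = null_dataset["net"]
        assert node_degrees(net)["degree"].sum() == 2 * net.n_edges


class TestGraphExport:
    @staticmethod
    def demo():
        net = InteractionNetwork(
            edge_pathways={
                ("g1", "g2"): frozenset({"p1"}),
                ("g2", "g3"): frozenset({"p1", "p2"}),
                ("g1", "g3"): frozenset(),
            }
        )
        attrs = {
            ("g1", "g2"): {"r_LA": 0.123456789012345, "r_HA": -0.5, "color": "red"},
            ("g2", "g3"): {"r_LA": -1.0 / 3.0, "r_HA": 0.9, "line_style": "dashed"},
        }
        return net, attrs

    @pytest.mark.parametrize("fmt", ["graphml", "xgmml"])
    def test_round_trip_topology_and_attributes(self, tmp_path, fmt):
        net, attrs = self.demo()
        path = tmp_path / f"net.{fmt}"
        write_annotated_graph(net, attrs, path, format=fmt)
        nodes, edge_attrs = read_annotated_graph(path, format=fmt)
        assert nodes == net.nodes
        assert set(edge_attrs) == net.edges
        from netdiffcor.network import format_attr

        for e, mapping in attrs.items():
            assert edge_attrs[e] == {k: format_attr(v) for k, v in mapping.items()}

    @pytest.mark.parametrize("fmt", ["graphml", "xgmml"])
    def test_empty_attribute_table_gives_topology_only(self, tmp_path, fmt):
        net, _ = self.demo()
        path = tmp_path / f"bare.{fmt}"
        write_annotated_graph(net, {}, path, format=fmt)
        nodes, edge_attrs = read_annotated_graph(path, format=fmt)
        assert nodes == net.nodes and set(edge_attrs) == net.edges
        assert all(v == {} for v in edge_attrs.values())

    def test_attribute_on_absent_edge_is_an_error(self, tmp_path):
        net, _ = self.demo()
        with pytest.raises(ValueError, match="absent"):
            write_annotated_graph(net, {("g1", "zz"): {"x": 1}}, tmp_path / "x.graphml")

    def test_unknown_format_is_an_error(self, tmp_path):
        net, attrs = self.demo()
        with pytest.raises(ValueError, match="format"):
            write_annotated_graph(net, attrs, tmp_path / "x.gml", format="gml")
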