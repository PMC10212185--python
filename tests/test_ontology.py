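"""Ontology construction: parsing, propagation, size filter, collapse, permutation."""

import numpy as np
import pytest

from hiergwas.ontology import (
    ROOT_ID,
    OntologyGraph,
    SystemNode,
    collapse_similar,
    filter_by_size,
    parse_ontology,
    permute_gene_labels,
    propagate_annotations,
    unify_roots,
)

OBO_3TERM = """\
format-version: 1.2
ontology: toy

[Term]
id: T:B
name: parent B
namespace: biological_process

[Term]
id: T:C
name: parent C
namespace: biological_process

[Term]
id: T:A
name: child A
namespace: biological_process
is_a: T:B
relationship: part_of T:C
"""


def make_graph(spec: dict[str, tuple[set, set]]) -> OntologyGraph:
    """Build a graph from {id: (parents, direct_genes)} by hand."""
    g = OntologyGraph()
    for nid, (parents, genes) in spec.items():
        g.nodes[nid] = SystemNode(id=nid, name=nid, direct_genes=set(genes))
    for nid, (parents, _) in spec.items():
        for p in parents:
            g.nodes[nid].parents.add(p)
            g.nodes[p].children.add(nid)
    return g


class TestParse:
    def test_empty_streams_give_empty_graph(self):
        g = parse_ontology("", "")
        assert g.nodes == {}

    def test_is_a_and_part_of_both_become_parent_links(self):
        g = parse_ontology(OBO_3TERM, "")
        assert g.nodes["T:A"].parents == {"T:B", "T:C"}
        assert g.nodes["T:B"].children == {"T:A"}

    def test_excluded_evidence_codes_are_dropped(self):
        annot = "g1\tT:A\tIEA\ng2\tT:A\tEXP\n"
        g = parse_ontology(OBO_3TERM, annot, excluded_evidence={"IEA"})
        assert g.nodes["T:A"].direct_genes == {"g2"}

    def test_gaf_rows_use_symbol_term_and_evidence_columns(self):
        gaf = (
            "!gaf-version: 2.2\n"
            "DB\tID1\tGENE1\t\tT:A\tREF\tEXP\t\tP\t\t\t\t\t\t\t\t\n"
            "DB\tID2\tGENE2\t\tT:B\tREF\tIEA\t\tP\t\t\t\t\t\t\t\t\n"
        )
        g = parse_ontology(OBO_3TERM, gaf)
        assert g.nodes["T:A"].direct_genes == {"GENE1"}
        assert g.nodes["T:B"].direct_genes == set()

    def test_unknown_term_annotation_warns_and_skips(self):
        with pytest.warns(UserWarning, match="unknown term"):
            g = parse_ontology(OBO_3TERM, "g1\tT:MISSING\tEXP\n")
        assert all(not n.direct_genes for n in g.nodes.values())


class TestUnifyRoots:
    def test_three_namespace_roots_get_common_root(self):
        g = make_graph({"R1": (set(), set()), "R2": (set(), set()), "R3": (set(), set())})
        u = unify_roots(g)
        assert u.root == ROOT_ID
        assert u.nodes[ROOT_ID].children == {"R1", "R2", "R3"}

    def test_idempotent_on_reapplication(self):
        g = make_graph({"R1": (set(), set())})
        once = unify_roots(g)
        twice = unify_roots(once)
        assert set(twice.nodes) == set(once.nodes)
        assert twice.nodes[ROOT_ID].children == {"R1"}

    def test_empty_graph_becomes_root_only(self):
        u = unify_roots(OntologyGraph())
        assert set(u.nodes) == {ROOT_ID}


class TestPropagate:
    def test_parent_inherits_child_genes(self):
        g = make_graph({"P": (set(), {"g2"}), "C": ({"P"}, {"g1"})})
        p = propagate_annotations(g)
        assert p.nodes["P"].genes == {"g1", "g2"}
        assert p.nodes["C"].genes == {"g1"}

    def test_diamond_counts_shared_gene_once(self):
        g = make_graph(
            {
                "TOP": (set(), set()),
                "L": ({"TOP"}, set()),
                "R": ({"TOP"}, set()),
                "BOT": ({"L", "R"}, {"g"}),
            }
        )
        p = propagate_annotations(g)

        # independent oracle: brute-force DFS union of descendant direct sets
        def dfs_union(nid):
            out = set(g.nodes[nid].direct_genes)
            for c in g.nodes[nid].children:
                out |= dfs_union(c)
            return out

        for nid in g.nodes:
            assert p.nodes[nid].genes == dfs_union(nid)
        assert p.nodes["TOP"].genes == {"g"}

    def test_propagation_is_monotone_in_descendant_genes(self, rng):
        g = make_graph(
            {"A": (set(), {"x"}), "B": ({"A"}, {"y"}), "C": ({"B"}, {"z"})}
        )
        before = propagate_annotations(g).nodes["A"].genes
        g.nodes["C"].direct_genes.add("extra")
        after = propagate_annotations(g).nodes["A"].genes
        assert before < after


def _sized_graph(sizes: dict[str, int]) -> OntologyGraph:
    spec = {"R": (set(), set())}
    for name, size in sizes.items():
        spec[name] = ({"R"}, {f"{name}_g{i}" for i in range(size)})
    g = make_graph(spec)
    return propagate_annotations(unify_roots(g))


class TestFilterBySize:
    @pytest.mark.parametrize("size,kept", [(2, False), (3, True), (75, True), (76, False)])
    def test_size_boundaries(self, size, kept):
        g = _sized_graph({"S": size})
        f = filter_by_size(g)
        assert ("S" in f.nodes) is kept

    def test_children_reconnect_to_surviving_ancestors(self):
        # A(ok) -> B(2 genes, removed) -> C(2 genes, removed); D survives under A
        spec2 = {
            "A": (set(), {f"a{i}" for i in range(10)}),
            "B": ({"A"}, set()),
            "C": ({"B"}, {"c0", "c1"}),
            "D": ({"A"}, {f"d{i}" for i in range(4)}),
        }
        g2 = propagate_annotations(unify_roots(make_graph(spec2)))
        f = filter_by_size(g2)  # B (2 genes) and C (2 genes) both go
        assert "B" not in f.nodes and "C" not in f.nodes
        assert "D" in f.nodes and f.nodes["D"].parents == {"A"}
        # every survivor still reachable from the root
        import networkx as nx

        rev = f.to_networkx().reverse()
        assert set(nx.descendants(rev, f.root)) | {f.root} == set(f.nodes)


class TestCollapseSimilar:
    def _pc(self, n_parent_extra, n_child):
        child = {f"g{i}" for i in range(n_child)}
        extra = {f"x{i}" for i in range(n_parent_extra)}
        spec = {"P": (set(), extra), "C": ({"P"}, child)}
        return propagate_annotations(unify_roots(make_graph(spec)))

    def test_similarity_at_threshold_removes_parent(self):
        g = self._pc(1, 9)  # S = 9/10 = 0.9
        c = collapse_similar(g)
        assert "P" not in c.nodes and "C" in c.nodes

    def test_similarity_below_threshold_keeps_parent(self):
        g = self._pc(1, 8)  # S = 8/9 < 0.9
        c = collapse_similar(g)
        assert "P" in c.nodes

    def test_chain_reconnects_child_to_grandparent(self):
        spec = {
            "G": (set(), {f"x{i}" for i in range(5)}),
            "P": ({"G"}, set()),
            "C": ({"P"}, {f"g{i}" for i in range(4)}),
        }
        g = propagate_annotations(unify_roots(make_graph(spec)))
        c = collapse_similar(g)  # S(P, C) = 1.0
        assert "P" not in c.nodes
        assert "G" in c.nodes["C"].parents

    def test_collapse_is_a_fixed_point(self):
        g = self._pc(1, 9)
        once = collapse_similar(g)
        twice = collapse_similar(once)
        assert set(twice.nodes) == set(once.nodes)
        for nid in once.nodes:
            assert twice.nodes[nid].parents == once.nodes[nid].parents

    def test_pipeline_postconditions_on_random_toy_dags(self):
        """Exhaustive postcondition check on small random DAGs."""
        import networkx as nx

        from hiergwas.synthetic_data import generate_toy_ontology

        for seed in range(3):
            obo, annot, _ = generate_toy_ontology(
                10, max_depth=3, gene_universe_size=120, seed=seed
            )
            g = propagate_annotations(unify_roots(parse_ontology(obo, annot)))
            f = collapse_similar(filter_by_size(g))
            for nid in f.systems():
                node = f.nodes[nid]
                assert 3 <= len(node.genes) <= 75
                for cid in node.children:
                    if cid != f.root:
                        assert len(f.nodes[cid].genes) / len(node.genes) < 0.9
            rev = f.to_networkx().reverse()
            assert set(nx.descendants(rev, f.root)) | {f.root} == set(f.nodes)


class TestPermuteGeneLabels:
    def _graph(self):
        spec = {
            "A": (set(), {"g1", "g2", "g3"}),
            "B": ({"A"}, {"g4", "g5"}),
        }
        return propagate_annotations(unify_roots(make_graph(spec)))

    def test_structure_and_sizes_preserved(self):
        g = self._graph()
        p = permute_gene_labels(g, seed=4)
        assert set(p.nodes) == set(g.nodes)
        for nid in g.nodes:
            assert p.nodes[nid].parents == g.nodes[nid].parents
            assert len(p.nodes[nid].genes) == len(g.nodes[nid].genes)
        assert p.gene_universe == g.gene_universe

    def test_same_seed_reproducible(self):
        g = self._graph()
        a = permute_gene_labels(g, seed=11)
        b = permute_gene_labels(g, seed=11)
        assert all(a.nodes[n].genes == b.nodes[n].genes for n in g.nodes)

    def test_single_gene_universe_is_identity(self):
        g = propagate_annotations(
            unify_roots(make_graph({"A": (set(), {"only"})}))
        )
        p = permute_gene_labels(g, seed=0)
        assert p.nodes["A"].genes == {"only"}
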