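import json

import networkx as nx
import numpy as np
import pytest

import spherotype as st
from spherotype.emap import DEFAULT_STOPWORDS


def _res(name, genes, es=0.5):
    return st.EnrichmentResult(name, es, es, 0.001, 0.01,
                               frozenset(genes), len(genes))


class TestJaccard:
    def test_hand_cases(self):
        assert st.jaccard({"A"}, {"A"}) == 1.0
        assert st.jaccard({"A"}, {"B"}) == 0.0
        assert st.jaccard({"A", "B", "C"}, {"B", "C", "D"}) == 0.5
        assert st.jaccard(set(), set()) == 0.0

    def test_symmetric_and_one_iff_equal(self):
        rng = np.random.default_rng(0)
        universe = list(range(20))
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(1, 10), replace=False))
            b = set(rng.choice(universe, rng.integers(1, 10), replace=False))
            assert st.jaccard(a, b) == st.jaccard(b, a)
            assert (st.jaccard(a, b) == 1.0) == (a == b)


class TestBuildMap:
    def test_exact_threshold_excluded(self):
        # |intersection| = 2, |union| = 5 -> J = 0.4 exactly: no edge
        a = _res("P1", {"g1", "g2", "g3", "g4"})
        b = _res("P2", {"g1", "g2", "g5"})
        g = st.build_enrichment_map([a, b], {f"g{i}" for i in range(1, 6)},
                                    threshold=0.4)
        assert g.n_edges == 0
        assert len(g.collections) == 2

    def test_components(self):
        a = _res("P1", {"g1", "g2", "g3"})
        b = _res("P2", {"g2", "g3", "g4"})  # J(P1,P2) = 0.5
        c = _res("P3", {"g8", "g9"})
        g = st.build_enrichment_map([a, b, c], {f"g{i}" for i in range(10)})
        members = sorted(tuple(i["members"]) for i in g.collections.values())
        assert members == [("P1", "P2"), ("P3",)]

    def test_node_size_counts_gene_subset(self):
        a = _res("P1", {"g1", "g2", "g3"})
        g = st.build_enrichment_map([a], {"g1", "g2", "g3"})
        assert g.graph.nodes["P1"]["size"] == 3

    def test_expressed_set_mode_uses_full_membership(self):
        gsc = st.GeneSetCollection("c", [
            st.GeneSet("P1", "", {"g1", "g2", "g3", "g9"})])
        a = _res("P1", {"g1"})
        g = st.build_enrichment_map([a], {"g1", "g2", "g3"},
                                    subset_mode="expressed_set",
                                    collection=gsc)
        assert g.graph.nodes["P1"]["size"] == 3  # g9 not expressed

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        results = [_res(f"P{i}",
                        set(rng.choice(30, rng.integers(3, 12),
                                       replace=False).astype(str)))
                   for i in range(12)]
        universe = {str(i) for i in range(30)}
        edges = [st.build_enrichment_map(results, universe, t).n_edges
                 for t in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert edges == sorted(edges, reverse=True)

    def test_components_match_union_find(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            results = [_res(f"P{i}",
                            set(rng.choice(15, rng.integers(2, 8),
                                           replace=False).astype(str)))
                       for i in range(8)]
            g = st.build_enrichment_map(results, {str(i) for i in range(15)},
                                        threshold=0.3)
            # brute-force union-find over all pairs
            parent = {r.set_name: r.set_name for r in results}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i, a in enumerate(results):
                for b in results[i + 1:]:
                    if st.jaccard(set(a.leading_edge),
                                  set(b.leading_edge)) > 0.3:
                        parent[find(a.set_name)] = find(b.set_name)
            expected = {}
            for r in results:
                expected.setdefault(find(r.set_name), set()).add(r.set_name)
            got = {frozenset(i["members"]) for i in g.collections.values()}
            assert got == {frozenset(s) for s in expected.values()}


class TestNameCollections:
    def _single_collection(self, names):
        shared = {"g1", "g2"}
        results = [_res(n, shared) for n in names]
        g = st.build_enrichment_map(results, {"g1", "g2"}, threshold=0.5)
        assert len(g.collections) == 1
        return st.name_collections(g)

    def test_top3_tokens(self):
        g = self._single_collection(
            ["REACTOME_CELL_CYCLE_MITOTIC", "KEGG_CELL_CYCLE",
             "REACTOME_MITOTIC_SPINDLE"])
        assert g.collections[0]["words"] == ("CELL", "CYCLE", "MITOTIC")

    def test_singleton_labels_itself(self):
        a = _res("HALLMARK_DNA_REPAIR", {"g1"})
        g = st.name_collections(
            st.build_enrichment_map([a], {"g1"}))
        assert g.collections[0]["words"] == ("DNA", "REPAIR")

    def test_fallback_when_all_stopworded(self):
        a = _res("KEGG_OF_THE", {"g1"})
        g = st.name_collections(st.build_enrichment_map([a], {"g1"}))
        assert g.collections[0]["fallback"]
        assert g.collections[0]["words"] == ("KEGG_OF_THE",)

    def test_stopwords_configurable(self):
        g = self._single_collection(["A_ALPHA_BETA", "B_ALPHA_BETA"])
        st.name_collections(g, stopwords=DEFAULT_STOPWORDS + ("ALPHA",))
        assert "ALPHA" not in g.collections[0]["words"]


class TestConcordance:
    def test_identical_sets_match(self):
        sets = {"km": {"A": {"p1", "p2"}}, "em": {"X": {"p1", "p2"}}}
        tab = st.cluster_concordance(sets)
        assert tab.iloc[0]["jaccard"] == 1.0
        assert bool(tab.iloc[0]["matched"])

    def test_boundary_is_non_strict(self):
        a = {f"p{i}" for i in range(1, 10)} | {"p11"}   # 10 pathways
        b = {f"p{i}" for i in range(1, 11)}             # 10 pathways
        tab = st.cluster_concordance({"km": {"A": a}, "em": {"X": b}})
        assert tab.iloc[0]["jaccard"] == pytest.approx(9 / 11)
        assert bool(tab.iloc[0]["matched"])  # 0.818 >= 0.7

    def test_disjoint_unmatched_and_empty_flagged(self):
        sets = {"km": {"A": {"p1"}, "B": set()},
                "em": {"X": {"p2"}}}
        tab = st.cluster_concordance(sets)
        row_a = tab[tab["cluster_a"] == "A"].iloc[0]
        row_b = tab[tab["cluster_a"] == "B"].iloc[0]
        assert not row_a["matched"] and row_a["note"] == ""
        assert row_b["jaccard"] == 0.0
        assert row_b["note"] == "undefined function"

    def test_needs_two_methods(self):
        with pytest.raises(ValueError, match="2 methods"):
            st.cluster_concordance({"km": {"A": {"p"}}})


class TestExport:
    def _toy_graph(self):
        a = _res("P1", {"g1", "g2"})
        b = _res("P2", {"g1", "g2", "g3"})
        c = _res("P3", {"g9"})
        g = st.build_enrichment_map([a, b, c],
                                    {f"g{i}" for i in range(10)},
                                    threshold=0.4)
        return st.name_collections(g)

    def test_graphml_roundtrip(self, tmp_path):
        g = self._toy_graph()
        p = tmp_path / "map.graphml"
        st.export_graph(g, p, "graphml")
        back = nx.read_graphml(p)
        assert back.number_of_nodes() == g.n_nodes
        assert back.number_of_edges() == g.n_edges
        for a, b, data in back.edges(data=True):
            assert data["weight"] == pytest.approx(
                g.graph.edges[a, b]["weight"])

    def test_sif_lines(self, tmp_path):
        p = tmp_path / "map.sif"
        st.export_graph(self._toy_graph(), p, "sif")
        lines = p.read_text().strip().split("\n")
        assert "P1\tshares_genes\tP2" in lines
        assert "P3" in lines

    def test_json_carries_collections(self, tmp_path):
        p = tmp_path / "map.json"
        st.export_graph(self._toy_graph(), p, "json")
        data = json.loads(p.read_text())
        assert len(data["collections"]) == 2

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            st.export_graph(self._toy_graph(), tmp_path / "x", "dot")
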