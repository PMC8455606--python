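import itertools
import math

import numpy as np
import pytest

import cellont as co
from cellont.ontology import OntologyError

from conftest import TINY_OBO, random_tree_graph


class TestParseObo:
    def test_field_mapping(self, tiny_terms):
        by_id = {t.term_id: t for t in tiny_terms}
        assert by_id["CL:0000084"].name == "T cell"
        assert by_id["CL:0000084"].parent_ids == ["CL:0000542"]
        assert by_id["CL:0000084"].definition.startswith("A type of lymphocyte")

    def test_definition_falls_back_to_name(self, tiny_terms):
        root = next(t for t in tiny_terms if t.term_id == "CL:0000000")
        assert root.definition == "cell"

    def test_obsolete_terms_dropped(self, tiny_terms):
        assert "CL:9999999" not in {t.term_id for t in tiny_terms}

    def test_term_order_is_file_order(self, tiny_terms):
        assert [t.term_id for t in tiny_terms][:2] == ["CL:0000000", "CL:0000542"]

    def test_empty_ontology_errors(self):
        with pytest.raises(OntologyError, match="empty"):
            co.parse_obo("format-version: 1.2\n")

    def test_malformed_stanza_names_line(self):
        bad = "[Term]\nname: orphan stanza without id\n\n[Term]\nid: CL:1\nname: x\n"
        with pytest.raises(OntologyError, match="line"):
            co.parse_obo(bad)

    def test_roundtrip_through_serializer(self, tiny_terms):
        text = co.write_obo(tiny_terms)
        again = co.parse_obo(text)
        assert [(t.term_id, t.name, t.definition, t.parent_ids) for t in again] == [
            (t.term_id, t.name, t.definition, t.parent_ids) for t in tiny_terms
        ]


class TestBuildGraph:
    def test_tree_counts(self, tiny_graph):
        assert tiny_graph.n_terms == 4
        assert len(tiny_graph.undirected_edges()) == 3
        assert all(w == 1.0 for _, _, w in tiny_graph.undirected_edges())

    def test_duplicate_is_a_deduplicated(self):
        terms = [
            co.OntologyTerm("X:A", "a", parent_ids=["X:B"]),
            co.OntologyTerm("X:B", "b", parent_ids=["X:A"]),
        ]
        # both stanzas assert the relation; the undirected edge appears once
        # (note: mutual is_a is a directed cycle, so this must error instead)
        with pytest.raises(OntologyError, match="cycle"):
            co.build_graph(terms)

    def test_repeated_parent_single_edge(self):
        terms = [
            co.OntologyTerm("X:A", "a"),
            co.OntologyTerm("X:B", "b", parent_ids=["X:A", "X:A"]),
        ]
        g = co.build_graph(terms)
        assert len(g.undirected_edges()) == 1

    def test_edge_weights_applied(self):
        terms = [co.OntologyTerm("X:A", "a"), co.OntologyTerm("X:B", "b", parent_ids=["X:A"])]
        g = co.build_graph(terms, edge_weights={("X:A", "X:B"): 0.67})
        assert g.undirected_edges() == [("X:B", "X:A", 0.67)] or g.undirected_edges() == [
            ("X:A", "X:B", 0.67)
        ]

    def test_cycle_detection(self):
        terms = [
            co.OntologyTerm("X:A", "a", parent_ids=["X:C"]),
            co.OntologyTerm("X:B", "b", parent_ids=["X:A"]),
            co.OntologyTerm("X:C", "c", parent_ids=["X:B"]),
        ]
        with pytest.raises(OntologyError, match="cycle"):
            co.build_graph(terms)

    def test_unknown_parent_dropped_with_warning(self):
        terms = [co.OntologyTerm("X:A", "a", parent_ids=["X:MISSING"])]
        with pytest.warns(UserWarning, match="X:MISSING"):
            g = co.build_graph(terms)
        assert g.undirected_edges() == []


class TestGraphQueries:
    def test_hop_distance_basics(self, tiny_graph):
        assert tiny_graph.hop_distance("CL:0000084", "CL:0000084") == 0
        assert tiny_graph.hop_distance("CL:0000084", "CL:0000542") == 1
        assert tiny_graph.hop_distance("CL:0000084", "CL:0000236") == 2

    def test_hop_distance_disconnected_is_inf(self):
        terms = [co.OntologyTerm("X:A", "a"), co.OntologyTerm("X:B", "b")]
        g = co.build_graph(terms)
        assert g.hop_distance("X:A", "X:B") == math.inf

    def test_hop_distance_unknown_term(self, tiny_graph):
        with pytest.raises(OntologyError, match="unknown"):
            tiny_graph.hop_distance("CL:0000084", "CL:404")

    def test_triangle_inequality_exhaustive(self):
        rng = np.random.default_rng(11)
        g = random_tree_graph(rng, 15)
        ids = g.term_ids
        d = {(a, b): g.hop_distance(a, b) for a in ids for b in ids}
        for a, b, c in itertools.product(ids, repeat=3):
            assert d[a, c] <= d[a, b] + d[b, c]

    def test_descendants_chain_and_leaf(self):
        terms = [
            co.OntologyTerm("X:A", "a"),
            co.OntologyTerm("X:B", "b", parent_ids=["X:A"]),
            co.OntologyTerm("X:C", "c", parent_ids=["X:B"]),
        ]
        g = co.build_graph(terms)
        assert g.descendants("X:A") == {"X:B", "X:C"}
        assert g.descendants("X:C") == set()

    def test_descendants_diamond_counted_once(self):
        terms = [
            co.OntologyTerm("X:A", "a"),
            co.OntologyTerm("X:B", "b", parent_ids=["X:A"]),
            co.OntologyTerm("X:C", "c", parent_ids=["X:A"]),
            co.OntologyTerm("X:D", "d", parent_ids=["X:B", "X:C"]),
        ]
        g = co.build_graph(terms)
        assert g.descendants("X:A") == {"X:B", "X:C", "X:D"}

    def test_descendants_match_bruteforce_reachability(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            g = random_tree_graph(rng, 18)
            # brute force: b is a descendant of a iff repeated parent-following
            # from b reaches a
            parents = {t.term_id: set(t.parent_ids) for t in g.terms}

            def reaches(b, a):
                frontier, visited = {b}, set()
                while frontier:
                    x = frontier.pop()
                    if x == a:
                        return True
                    visited.add(x)
                    frontier |= parents[x] - visited
                return False

            for a in g.term_ids:
                brute = {b for b in g.term_ids if b != a and reaches(b, a)}
                assert g.descendants(a) == brute


class TestAugmentEdges:
    def sims(self, value):
        return lambda a, b: value

    def test_dc2_is_identity(self, tiny_graph):
        out = tiny_graph.augment_edges(self.sims(0.99), d_c=2)
        assert sorted(e[:2] for e in out.undirected_edges()) == sorted(
            e[:2] for e in tiny_graph.undirected_edges()
        )

    def test_edge_added_above_threshold(self, tiny_graph):
        # T cell and B cell sit at hop distance 2
        out = tiny_graph.augment_edges(self.sims(0.9), d_c=3)
        assert out.hop_distance("CL:0000084", "CL:0000236") == 1
        weights = {frozenset((a, b)): w for a, b, w in out.undirected_edges()}
        assert weights[frozenset(("CL:0000084", "CL:0000236"))] == 0.9

    def test_no_edge_below_threshold(self, tiny_graph):
        out = tiny_graph.augment_edges(self.sims(0.7), d_c=3)
        assert out.hop_distance("CL:0000084", "CL:0000236") == 2

    def test_monotone_superset(self, fixture_data):
        g = fixture_data.graph
        sim = lambda a, b: 0.85
        before = {frozenset(e[:2]) for e in g.undirected_edges()}
        for d_c in (2, 3, 4):
            after = {frozenset(e[:2]) for e in g.augment_edges(sim, d_c).undirected_edges()}
            assert before <= after

    def test_original_untouched(self, tiny_graph):
        n_edges = len(tiny_graph.undirected_edges())
        tiny_graph.augment_edges(self.sims(0.95), d_c=4)
        assert len(tiny_graph.undirected_edges()) == n_edges

    def test_dc_below_two_errors(self, tiny_graph):
        with pytest.raises(OntologyError, match="d_c"):
            tiny_graph.augment_edges(self.sims(0.9), d_c=1)


class TestEdgeList:
    def test_read_edge_list_with_weights(self):
        tsv = "child1\troot\t0.5\nchild2\troot\n"
        g = co.read_edge_list(tsv)
        assert g.n_terms == 3
        weights = {frozenset((a, b)): w for a, b, w in g.undirected_edges()}
        assert weights[frozenset(("child1", "root"))] == 0.5
        assert weights[frozenset(("child2", "root"))] == 1.0

    def test_export_roundtrip(self, tiny_graph):
        tsv = tiny_graph.to_edge_list()
        g2 = co.read_edge_list(tsv)
        w1 = {frozenset((a, b)): w for a, b, w in tiny_graph.undirected_edges()}
        w2 = {frozenset((a, b)): w for a, b, w in g2.undirected_edges()}
        assert w1 == w2
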