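import networkx as nx
import numpy as np
import pytest

from attppi import (
    AnnotationRecord,
    AttributedNetwork,
    SourceWeights,
    TypedEdgeRecord,
    attributed_density,
    build_network,
    clique_score,
    common_attribute_set,
    enumerate_maximal_cliques,
    structural_correlation,
)
from attppi.network import TYPES, TERMS

from conftest import brute_force_maximal_cliques, brute_force_triangle_vertices


def _from_graph(graph: nx.Graph, terms=None) -> AttributedNetwork:
    g = nx.Graph()
    g.add_nodes_from(str(v) for v in graph.nodes)
    for u, v in graph.edges:
        g.add_edge(str(u), str(v), **{TYPES: frozenset({"T1"})})
    for v in g.nodes:
        g.nodes[v][TERMS] = frozenset((terms or {}).get(v, ()))
    return AttributedNetwork(g)


class TestEnumerateMaximalCliques:
    def test_triangle_with_pendant(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        assert enumerate_maximal_cliques(_from_graph(g)) == [frozenset("ABC")]

    def test_complete_graph_is_one_clique(self):
        net = _from_graph(nx.complete_graph(4))
        assert enumerate_maximal_cliques(net) == [frozenset({"0", "1", "2", "3"})]

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=int(rng.integers(2**31)))
        net = _from_graph(g)
        expected = brute_force_maximal_cliques(net.graph, min_size=3)
        assert set(enumerate_maximal_cliques(net)) == expected

    def test_deterministic_ordering(self):
        g = nx.Graph([("B", "C"), ("C", "D"), ("B", "D"), ("X", "Y"), ("Y", "Z"), ("X", "Z")])
        net = _from_graph(g)
        assert enumerate_maximal_cliques(net) == enumerate_maximal_cliques(net)
        assert enumerate_maximal_cliques(net)[0] == frozenset("BCD")


class TestCommonAttributeSet:
    def test_worked_example_triangle(self, fig3):
        assert common_attribute_set(fig3, {"P2", "P3", "P5"}) == {"GS1", "GS2"}

    def test_single_vertex(self, fig3):
        assert common_attribute_set(fig3, {"P2"}) == {"GS1", "GS2"}

    def test_unannotated_member_forces_empty_set(self):
        net = _from_graph(nx.complete_graph(3), terms={"0": {"GS1"}, "1": {"GS1"}})
        assert common_attribute_set(net, {"0", "1", "2"}) == frozenset()

    def test_empty_clique_rejected(self, fig3):
        with pytest.raises(ValueError):
            common_attribute_set(fig3, set())


class TestStructuralCorrelation:
    def test_worked_example_values(self, fig3):
        assert structural_correlation(fig3, {"GS1"}) == pytest.approx(0.625)
        assert structural_correlation(fig3, {"GS3"}) == 0.0
        assert structural_correlation(fig3, {"GS1", "GS2"}) == pytest.approx(1.0)

    def test_triangle_subgraph_has_eta_one(self):
        net = _from_graph(nx.complete_graph(3), terms={str(i): {"GS1"} for i in range(3)})
        assert structural_correlation(net, {"GS1"}) == 1.0

    def test_empty_induced_graph_gives_zero(self, fig3):
        assert structural_correlation(fig3, {"GS404"}) == 0.0

    @pytest.mark.parametrize("trial", range(30))
    def test_k_set_matches_triangle_oracle(self, trial):
        """eta's numerator equals the brute-force >=3-clique membership count."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.7)), seed=int(rng.integers(2**31)))
        terms = {str(v): {"GS1"} for v in g.nodes}
        net = _from_graph(g, terms=terms)
        expected = len(brute_force_triangle_vertices(net.graph)) / max(n, 1)
        assert structural_correlation(net, {"GS1"}) == pytest.approx(expected)

    def test_eta_bounded(self, fig3):
        for S in [set(), {"GS1"}, {"GS2"}, {"GS3"}, {"GS1", "GS2"}]:
            assert 0.0 <= structural_correlation(fig3, S) <= 1.0


class TestAttributedDensity:
    def test_full_weight_triangle_has_density_one(self):
        g = nx.Graph()
        for u, v in [("A", "B"), ("B", "C"), ("A", "C")]:
            g.add_edge(u, v, **{TYPES: frozenset({"T1", "T2"})})
        net = AttributedNetwork(g)
        for w1 in (0.1, 0.5, 0.9):
            w = SourceWeights.from_pair(w1, 1 - w1)
            assert attributed_density(net, "ABC", w) == pytest.approx(1.0)

    @pytest.mark.parametrize("clique,expected", [
        ({"P2", "P3", "P5"}, 0.867),
        ({"P2", "P3", "P4", "P5"}, 0.833),
        ({"P2", "P5", "P6"}, 0.667),
    ])
    def test_worked_example_densities(self, fig3, w64, clique, expected):
        assert attributed_density(fig3, clique, w64) == pytest.approx(expected, abs=5e-4)

    def test_rejects_single_vertex(self, fig3, w64):
        with pytest.raises(ValueError):
            attributed_density(fig3, {"P2"}, w64)


class TestCliqueScore:
    @pytest.mark.parametrize("clique,s,eta,density,score", [
        ({"P2", "P3", "P4", "P5"}, {"GS1", "GS2"}, 1.0, 0.833, 6.664),
        ({"P2", "P3", "P5"}, {"GS1", "GS2"}, 1.0, 0.867, 5.202),
        ({"P2", "P5", "P6"}, {"GS1"}, 0.625, 0.667, 1.251),
    ])
    def test_worked_example_table(self, fig3, w64, clique, s, eta, density, score):
        occ = clique_score(fig3, clique, w64)
        assert occ.common_attrs == s
        assert occ.eta == pytest.approx(eta)
        assert occ.density == pytest.approx(density, abs=5e-4)
        assert occ.rounded_score() == pytest.approx(score, abs=1e-3)

    def test_empty_common_set_scores_zero(self):
        net = _from_graph(nx.complete_graph(3), terms={"0": {"GS1"}})
        occ = clique_score(net, {"0", "1", "2"}, SourceWeights.equal())
        assert occ.score == 0.0
        assert occ.common_attrs == frozenset()

    def test_non_clique_rejected(self, fig3, w64):
        with pytest.raises(ValueError):
            clique_score(fig3, {"P1", "P2", "P7"}, w64)

    def test_score_invariant_under_relabeling(self, fig3, w64):
        """Scores depend on structure and attributes, not on vertex names."""
        mapping = {v: f"Q{v[1:]}" for v in fig3.vertices}
        relabeled = AttributedNetwork(nx.relabel_nodes(fig3.graph, mapping), fig3.edge_tags)
        orig = clique_score(fig3, {"P2", "P3", "P4", "P5"}, w64)
        new = clique_score(relabeled, {"Q2", "Q3", "Q4", "Q5"}, w64)
        assert new.score == pytest.approx(orig.score)
        assert new.eta == pytest.approx(orig.eta)
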