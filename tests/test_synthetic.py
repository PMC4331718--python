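import pytest

from attppi import (
    SyntheticSpec,
    add_random_edges,
    enumerate_maximal_cliques,
    figure3_fixture,
    generate,
)
from attppi.network import network_to_records
from attppi.io_formats import write_annotations, write_edge_list

from pipeline_helpers import run_pipeline


class TestGenerate:
    def test_zero_noise_cliques_are_exactly_the_planted_complexes(self):
        spec = SyntheticSpec(n_complexes=2, complex_size=(4, 4), p_within=1.0,
                             p_background=0.0, n_background_vertices=10, seed=3)
        network, truth = generate(spec)
        cliques = set(enumerate_maximal_cliques(network))
        assert cliques == {c.members for c in truth}

    def test_determinism_same_seed(self):
        spec = SyntheticSpec(seed=5)
        net_a, truth_a = generate(spec)
        net_b, truth_b = generate(spec)
        assert net_a.edges == net_b.edges
        assert [c.members for c in truth_a] == [c.members for c in truth_b]
        assert all(net_a.terms_of(v) == net_b.terms_of(v) for v in net_a.vertices)
        assert all(net_a.types_of(e) == net_b.types_of(e) for e in net_a.edges)

    def test_serialization_is_byte_identical_under_fixed_seed(self, tmp_path):
        for sub in ("a", "b"):
            network, _ = generate(SyntheticSpec(seed=9))
            by_type, anns = network_to_records(network)
            d = tmp_path / sub
            d.mkdir()
            write_edge_list(by_type["T1"], d / "ht.tsv")
            write_edge_list(by_type["T2"], d / "lit.tsv")
            write_annotations(anns, d / "ann.tsv")
        for name in ("ht.tsv", "lit.tsv", "ann.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_every_edge_has_a_source(self):
        network, _ = generate(SyntheticSpec(seed=1, n_complexes=3,
                                            n_background_vertices=30))
        assert all(network.types_of(e) for e in network.edges)

    def test_planted_members_share_their_complex_term(self):
        network, truth = generate(SyntheticSpec(seed=2, p_background=0.0))
        for ci, complex_ in enumerate(truth):
            terms = set.intersection(*(set(network.terms_of(m)) for m in complex_.members))
            assert any(t.startswith(f"GT{ci:03d}_") for t in terms)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(complex_size=(2, 4))
        with pytest.raises(ValueError):
            SyntheticSpec(p_background=1.5)

    def test_pipeline_recovers_planted_complexes_with_background_noise(self):
        spec = SyntheticSpec(p_background=0.01, n_background_vertices=100, seed=7)
        network, truth = generate(spec)
        report, _ = run_pipeline(network, truth, weight_mode="auto", extend_thres=0.1)
        assert report is not None
        assert report.recall >= 0.8


class TestAddRandomEdges:
    def test_n_zero_is_identity(self):
        network, _ = generate(SyntheticSpec(seed=4, n_background_vertices=20))
        assert add_random_edges(network, 0, seed=1).edges == network.edges

    def test_edge_count_increases_by_n(self):
        network, _ = generate(SyntheticSpec(seed=4, n_complexes=3,
                                            n_background_vertices=10))
        before = network.n_edges()
        out = add_random_edges(network, 10, seed=2)
        assert out.n_edges() == before + 10
        assert network.n_edges() == before  # input unmodified

    def test_new_edges_carry_high_throughput_tag(self):
        network, _ = generate(SyntheticSpec(seed=4, n_complexes=3,
                                            n_background_vertices=10))
        out = add_random_edges(network, 5, seed=3)
        for e in out.edges - network.edges:
            assert out.types_of(e) == {"T1"}

    def test_too_many_edges_rejected(self):
        network, _ = generate(SyntheticSpec(seed=4, n_complexes=2,
                                            complex_size=(4, 4), p_background=0.0,
                                            n_background_vertices=0))
        with pytest.raises(ValueError):
            add_random_edges(network, 10**6, seed=0)

    def test_noise_degrades_mean_f_score(self):
        """Mean F over seeds does not improve as random edges are added."""
        spec = SyntheticSpec(n_complexes=6, complex_size=(4, 6), p_background=0.005,
                             n_background_vertices=60, seed=13)
        network, truth = generate(spec)
        mean_f = {}
        for n_noise in (0, 150):
            fs = []
            for s in range(5):
                noisy = add_random_edges(network, n_noise, seed=100 + s)
                report, _ = run_pipeline(noisy, truth, weight_mode="equal")
                fs.append(report.f_score if report else 0.0)
            mean_f[n_noise] = sum(fs) / len(fs)
        assert mean_f[150] <= mean_f[0] + 1e-9


class TestFigure3Fixture:
    def test_every_vertex_carries_gs1(self):
        net = figure3_fixture()
        assert all("GS1" in net.terms_of(v) for v in net.vertices)
        assert {v for v in net.vertices if "GS2" in net.terms_of(v)} \
            == {"P2", "P3", "P4", "P5"}

    def test_pendant_vertices_are_triangle_free(self):
        import networkx as nx
        net = figure3_fixture()
        triangles = nx.triangles(net.graph)
        assert all(triangles[v] == 0 for v in ("P1", "P7", "P8"))

    def test_gs3_vertices_lie_in_no_triangle(self):
        import networkx as nx
        net = figure3_fixture()
        triangles = nx.triangles(net.graph)
        for v in net.vertices:
            if "GS3" in net.terms_of(v):
                assert triangles[v] == 0
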