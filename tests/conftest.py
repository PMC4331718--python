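import itertools

import networkx as nx
import pytest
from hypothesis import settings

from attppi import SourceWeights, figure3_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig3():
    """The reconstructed 8-protein worked-example network."""
    return figure3_fixture()


@pytest.fixture(scope="session")
def w64():
    """The worked example's source weights: 0.6 high-throughput, 0.4 literature."""
    return SourceWeights.from_pair(0.6, 0.4)


@pytest.fixture(scope="session")
def w_equal():
    return SourceWeights.equal()


# ---------------------------------------------------------------------------
# independent brute-force oracles (subset enumeration; usable up to ~12 nodes)
# ---------------------------------------------------------------------------

def brute_force_maximal_cliques(graph: nx.Graph, min_size: int = 3) -> set[frozenset]:
    """All maximal cliques by exhaustive subset enumeration."""
    nodes = list(graph.nodes)
    cliques = set()
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.add(frozenset(subset))
    maximal = {c for c in cliques if not any(c < other for other in cliques)}
    return {c for c in maximal if len(c) >= min_size}


def brute_force_triangle_vertices(graph: nx.Graph) -> set:
    """Vertices belonging to at least one clique of size >= 3 (i.e. a triangle)."""
    out = set()
    for trio in itertools.combinations(graph.nodes, 3):
        if all(graph.has_edge(u, v) for u, v in itertools.combinations(trio, 2)):
            out.update(trio)
    return out
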