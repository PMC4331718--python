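"""The attributed PPI network data model.

An attributed PPI network is the 6-tuple G = (V, E, A_v, A_e, F_v, F_e):
protein vertices V, undirected interactions E, a vocabulary A_v of GO-slim
terms with F_v mapping each vertex to its (possibly empty) term set, and a
vocabulary A_e of evidence-source tags with F_e mapping each edge to the
non-empty set of sources that reported it. Here A_e defaults to two tags —
T1 (high-throughput experiments) and T2 (literature mining) — but the model
accepts any k >= 1 sources.

Each source tag carries a contribution weight w_i (weights sum to 1); an
edge's weight is the sum of the weights of the sources that reported it, so
an interaction seen by every source weighs exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .io_formats import AnnotationRecord, DEFAULT_TAGS, TypedEdgeRecord

logger = logging.getLogger(__name__)

#: node attribute key holding the frozenset of GO-slim terms
TERMS = "terms"
#: edge attribute key holding the frozenset of evidence-source tags
TYPES = "types"


@dataclass(frozen=True)
class SourceWeights:
    """Per-source contribution weights w_i, non-negative and summing to 1."""

    w: Mapping[str, float]

    def __post_init__(self):
        w = dict(self.w)
        if not w:
            raise ValueError("at least one source tag is required")
        if any(v < 0 for v in w.values()):
            raise ValueError(f"weights must be non-negative: {w}")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        object.__setattr__(self, "w", w)

    def __getitem__(self, tag: str) -> float:
        return self.w[tag]

    @classmethod
    def equal(cls, tags: Iterable[str] = DEFAULT_TAGS) -> "SourceWeights":
        tags = list(tags)
        return cls({t: 1.0 / len(tags) for t in tags})

    @classmethod
    def from_pair(cls, w1: float, w2: float,
                  tags: tuple[str, str] = DEFAULT_TAGS) -> "SourceWeights":
        return cls({tags[0]: w1, tags[1]: w2})


@dataclass
class AttributedNetwork:
    """An attributed PPI network backed by a :class:`networkx.Graph`.

    ``graph`` stores F_v under the node attribute ``terms`` and F_e under the
    edge attribute ``types``; ``edge_tags`` is the declared source vocabulary
    A_e. A_v is derived as the union of all vertex term sets.
    """

    graph: nx.Graph
    edge_tags: tuple[str, ...] = DEFAULT_TAGS

    def __post_init__(self):
        declared = set(self.edge_tags)
        for u, v, data in self.graph.edges(data=True):
            types = data.get(TYPES)
            if not types:
                raise ValueError(f"edge ({u}, {v}) has an empty type attribute set")
            if not set(types) <= declared:
                raise ValueError(f"edge ({u}, {v}) carries undeclared tag(s) {set(types) - declared}")
        for v, data in self.graph.nodes(data=True):
            data.setdefault(TERMS, frozenset())

    # -- 6-tuple accessors -------------------------------------------------
    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def vertex_vocabulary(self) -> frozenset[str]:
        """A_v: the union of all vertex attribute term sets."""
        return frozenset().union(*(self.terms_of(v) for v in self.graph)) \
            if self.graph.number_of_nodes() else frozenset()

    def terms_of(self, vertex: str) -> frozenset[str]:
        """F_v(vertex)."""
        return self.graph.nodes[vertex][TERMS]

    def types_of(self, edge: tuple[str, str]) -> frozenset[str]:
        """F_e(edge)."""
        return self.graph.edges[edge][TYPES]

    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "AttributedNetwork":
        return AttributedNetwork(self.graph.copy(), self.edge_tags)


def build_network(edges: Iterable[TypedEdgeRecord],
                  annotations: Iterable[AnnotationRecord] = (),
                  edge_tags: tuple[str, ...] = DEFAULT_TAGS) -> AttributedNetwork:
    """Assemble an attributed network from typed edge and annotation records.

    Vertices are exactly the proteins appearing in edges. An edge reported
    under several source tags gets the union of those tags. Annotations for
    proteins absent from every edge are ignored (with a logged count);
    unannotated vertices keep an empty term set — they are retained because
    they can still join complexes through connectivity during augmentation.
    """
    g = nx.Graph()
    for rec in edges:
        if g.has_edge(rec.protein_a, rec.protein_b):
            g.edges[rec.protein_a, rec.protein_b][TYPES] |= {rec.source_type}
        else:
            g.add_edge(rec.protein_a, rec.protein_b, **{TYPES: frozenset({rec.source_type})})
    terms: dict[str, set[str]] = {}
    n_orphan = 0
    for ann in annotations:
        if ann.protein in g:
            terms.setdefault(ann.protein, set()).add(ann.go_slim)
        else:
            n_orphan += 1
    if n_orphan:
        logger.info("ignored %d annotation(s) for proteins absent from the edge set", n_orphan)
    for v in g.nodes:
        g.nodes[v][TERMS] = frozenset(terms.get(v, ()))
    # frozensets for edge types too (|= above builds plain sets on merge)
    for u, v in g.edges:
        g.edges[u, v][TYPES] = frozenset(g.edges[u, v][TYPES])
    return AttributedNetwork(g, edge_tags)


def network_to_records(network: AttributedNetwork
                       ) -> tuple[dict[str, list[TypedEdgeRecord]], list[AnnotationRecord]]:
    """Decompose a network back into per-source edge records and annotations.

    Inverse of :func:`build_network` up to record ordering; used to write a
    generated network in the same TSV formats the readers consume.
    """
    by_type: dict[str, list[TypedEdgeRecord]] = {t: [] for t in network.edge_tags}
    for u, v in sorted(network.edges):
        for tag in sorted(network.types_of((u, v))):
            by_type[tag].append(TypedEdgeRecord(u, v, tag))
    anns = [AnnotationRecord(v, t)
            for v in sorted(network.vertices)
            for t in sorted(network.terms_of(v))]
    return by_type, anns


def edge_weight(network: AttributedNetwork, edge: tuple[str, str],
                weights: SourceWeights) -> float:
    """Weight of an edge: the sum of contribution weights of its source tags.

    With normalized weights the result lies in (0, 1]; an edge reported by
    every source weighs exactly 1.
    """
    if not network.graph.has_edge(*edge):
        raise KeyError(f"edge {edge} is not in the network")
    return sum(weights[tag] for tag in network.types_of(edge))


def induced_subgraph(network: AttributedNetwork, S: Iterable[str]) -> AttributedNetwork:
    """The subgraph G(S) induced by an attribute set S.

    V(S) is every vertex whose term set contains all of S; E(S) is the edges
    with both endpoints in V(S). S = {} induces the whole network, and a term
    outside A_v induces the empty network.
    """
    S = frozenset(S)
    keep = [v for v in network.graph if S <= network.terms_of(v)]
    return AttributedNetwork(network.graph.subgraph(keep).copy(), network.edge_tags)
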