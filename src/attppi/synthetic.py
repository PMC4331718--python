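"""Synthetic attributed networks with known ground truth.

Two generators live here:

* :func:`generate` plants vertex-disjoint complexes — cliques whose members
  share a complex-specific GO-slim term — inside a two-source background of
  uniform noise edges, with each edge assigned to the high-throughput and/or
  literature source by per-source retention probabilities. This emulates the
  structure the method assumes (annotated dense modules in a multi-source
  edge set) and gives every pipeline stage a testable ground truth without
  any download.
* :func:`add_random_edges` implements the random-edge degradation control:
  n uniform-random absent pairs are added as high-throughput edges, leaving
  the input network untouched.

:func:`figure3_fixture` returns the 8-vertex worked-example network. Its
exact topology is not printed anywhere, so it is RECONSTRUCTED here to
satisfy every published constraint simultaneously (the K sets and eta values
0.625 / 0 / 1, the three clique densities 0.667 / 0.867 / 0.833 at
w = (0.6, 0.4), and the presence of single-T1, single-T2 and dual-typed
edges weighing 0.6 / 0.4 / 1.0); the regression tests assert each of those
cells. The pendant attachments keeping P1, P7, P8 triangle-free are
otherwise unconstrained; we hang P1 off P3, P7 off P6 and P8 off P4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_formats import (
    AnnotationRecord,
    ComplexRecord,
    DEFAULT_TAGS,
    HIGH_THROUGHPUT,
    LITERATURE,
    TypedEdgeRecord,
)
from .network import TYPES, AttributedNetwork, build_network


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-complex benchmark.

    ``retention`` maps each source tag to a pair
    ``(p_keep_complex_edge, p_keep_background_edge)``: every realized edge is
    independently offered to each source with the probability matching its
    class, and an edge claimed by no source is assigned to the source with
    the highest retention for its class so the realized union graph always
    contains it (planted complexes stay cliques at p_within = 1).
    """

    n_complexes: int = 8
    complex_size: tuple[int, int] = (4, 7)
    p_within: float = 1.0
    p_background: float = 0.01
    n_background_vertices: int = 100
    terms_per_complex: int = 1
    shared_term_prob: float = 0.1
    n_distractor_terms: int = 5
    retention: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {HIGH_THROUGHPUT: (0.9, 0.9), LITERATURE: (0.7, 0.7)})
    seed: int = 0

    def __post_init__(self):
        if self.n_complexes < 1:
            raise ValueError("need at least one planted complex")
        lo, hi = self.complex_size
        if lo < 3 or hi < lo:
            raise ValueError(f"complex sizes must satisfy 3 <= lo <= hi, got {self.complex_size}")
        probs = [self.p_within, self.p_background, self.shared_term_prob,
                 *(p for pair in self.retention.values() for p in pair)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.terms_per_complex < 1:
            raise ValueError("each planted complex needs >= 1 term")


def biased_two_source_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A benchmark where T1 carries the planted cliques and T2 mostly noise.

    Used to exercise the contribution-weight estimator in the regime it is
    built for: one informative and one unreliable source. The background
    density is set so that a single noise edge into a typical seed clique
    straddles the default attachment threshold: under equal weights such
    edges pull spurious neighbors into complexes, while a downweighted noisy
    source keeps them out — at much lower noise both weighting modes
    saturate and the benchmark cannot separate them.
    """
    params = dict(
        n_complexes=8, complex_size=(4, 7), p_within=1.0,
        p_background=0.05, n_background_vertices=100,
        retention={HIGH_THROUGHPUT: (0.95, 0.1), LITERATURE: (0.15, 0.9)},
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def generate(spec: SyntheticSpec) -> tuple[AttributedNetwork, list[ComplexRecord]]:
    """Draw one attributed network and its ground-truth complex list.

    Deterministic under ``spec.seed``. Vertices with no realized edge do not
    appear in the network (a PPI network has no isolated proteins), but every
    planted complex is reported in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    tags = tuple(spec.retention)

    sizes = [int(rng.integers(spec.complex_size[0], spec.complex_size[1] + 1))
             for _ in range(spec.n_complexes)]
    vertex_of = lambda i: f"P{i:04d}"
    complexes: list[ComplexRecord] = []
    complex_of: dict[str, int] = {}
    counter = 0
    for ci, size in enumerate(sizes):
        members = [vertex_of(counter + k) for k in range(size)]
        counter += size
        complexes.append(ComplexRecord(frozenset(members), name=f"complex{ci}"))
        for m in members:
            complex_of[m] = ci
    background = [vertex_of(counter + k) for k in range(spec.n_background_vertices)]
    all_vertices = [v for c in complexes for v in sorted(c.members)] + background

    # realized undirected edges, classed as complex-internal or background
    edges: list[tuple[str, str, bool]] = []
    for i, u in enumerate(all_vertices):
        for v in all_vertices[i + 1:]:
            same = complex_of.get(u) is not None and complex_of.get(u) == complex_of.get(v)
            p = spec.p_within if same else spec.p_background
            if p > 0 and rng.random() < p:
                edges.append((u, v, same))

    records: list[TypedEdgeRecord] = []
    for u, v, same in edges:
        idx = 0 if same else 1
        claimed = [tag for tag in tags if rng.random() < spec.retention[tag][idx]]
        if not claimed:
            claimed = [max(tags, key=lambda t: spec.retention[t][idx])]
        records.extend(TypedEdgeRecord(u, v, tag) for tag in claimed)

    annotations: list[AnnotationRecord] = []
    planted_terms: list[str] = []
    for ci, c in enumerate(complexes):
        terms = [f"GT{ci:03d}_{t}" for t in range(spec.terms_per_complex)]
        planted_terms.extend(terms)
        annotations.extend(AnnotationRecord(m, t) for m in sorted(c.members) for t in terms)
    distractors = [f"NOISE{j}" for j in range(spec.n_distractor_terms)]
    for v in background:
        if planted_terms and rng.random() < spec.shared_term_prob:
            term = planted_terms[int(rng.integers(len(planted_terms)))]
        else:
            term = distractors[int(rng.integers(len(distractors)))] if distractors else None
        if term is not None:
            annotations.append(AnnotationRecord(v, term))

    return build_network(records, annotations, edge_tags=tags), complexes


def add_random_edges(network: AttributedNetwork, n: int, seed: int = 0,
                     source_type: str | None = None) -> AttributedNetwork:
    """Return a copy of *network* with n uniform-random new edges added.

    New edges connect currently non-adjacent vertex pairs and carry the
    high-throughput tag (or *source_type*); the input network is unmodified.
    """
    nodes = sorted(network.graph.nodes)
    n_absent = len(nodes) * (len(nodes) - 1) // 2 - network.n_edges()
    if n > n_absent:
        raise ValueError(f"cannot add {n} edges: only {n_absent} vertex pairs are absent")
    tag = source_type if source_type is not None else network.edge_tags[0]
    out = network.copy()
    rng = np.random.default_rng(seed)
    added = 0
    while added < n:
        i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
        if i == j:
            continue
        u, v = nodes[min(i, j)], nodes[max(i, j)]
        if out.graph.has_edge(u, v):
            continue
        out.graph.add_edge(u, v, **{TYPES: frozenset({tag})})
        added += 1
    return out


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

#: Edge list of the 8-protein worked example with its source-type sets.
FIGURE3_EDGES: tuple[tuple[str, str, frozenset[str]], ...] = (
    ("P2", "P3", frozenset({"T1", "T2"})),
    ("P2", "P5", frozenset({"T1", "T2"})),
    ("P3", "P5", frozenset({"T1"})),
    ("P2", "P4", frozenset({"T1", "T2"})),
    ("P3", "P4", frozenset({"T1", "T2"})),
    ("P4", "P5", frozenset({"T2"})),
    ("P2", "P6", frozenset({"T1"})),
    ("P5", "P6", frozenset({"T2"})),
    # triangle-free pendant attachments
    ("P1", "P3", frozenset({"T1"})),
    ("P6", "P7", frozenset({"T2"})),
    ("P4", "P8", frozenset({"T1"})),
)

#: GO-slim annotation table of the worked example.
FIGURE3_ANNOTATIONS: tuple[tuple[str, str], ...] = (
    *((p, "GS1") for p in ("P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8")),
    *((p, "GS2") for p in ("P2", "P3", "P4", "P5")),
    *((p, "GS3") for p in ("P1", "P7")),
)


def figure3_fixture() -> AttributedNetwork:
    """The reconstructed 8-vertex worked-example network (see module docs)."""
    records = [TypedEdgeRecord(a, b, tag)
               for a, b, types in FIGURE3_EDGES for tag in sorted(types)]
    annotations = [AnnotationRecord(p, t) for p, t in FIGURE3_ANNOTATIONS]
    return build_network(records, annotations, edge_tags=DEFAULT_TAGS)
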