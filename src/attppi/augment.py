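"""Seed augmentation (phase 2): grow seed cliques into predicted complexes.

Real complexes follow a core–attachment architecture: a dense core plus
peripheral subunits that need not interact with every core member. Each
neighbor P_k of a seed clique ((C_j, E_cj), S_j) is therefore scored by

    Close_Score = |S_k ∩ S_j| / (|S_j| + 1)  +  Σ_{e ∈ E_p} weight(e) / |C_j|

where S_k is the neighbor's term set and E_p its edges into the seed: the
first term measures annotation similarity, the second weighted topological
connectivity. Neighbors scoring at least ``extend_thres`` are attached.

Every neighbor is scored against the immutable seed (S_j and C_j fixed) and
all qualifying neighbors are attached in one batch: an incremental variant
that updates the seed after each addition would be order-dependent, and no
ordering rule is defined for it. A direct consequence is that attachment
sets shrink monotonically as extend_thres grows. Predicted complexes may
overlap one another — only the seeds are disjoint — and predictions with
identical final member sets are collapsed to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .cliques import OntologyCorrelatedClique
from .network import AttributedNetwork, SourceWeights, edge_weight


@dataclass(frozen=True)
class PredictedComplex:
    """A seed clique plus the close neighbors attached to it."""

    seed: OntologyCorrelatedClique
    attachments: dict[str, float] = field(default_factory=dict)

    @property
    def members(self) -> frozenset[str]:
        return self.seed.members | set(self.attachments)


def closeness_score(network: AttributedNetwork, vertex: str,
                    seed: OntologyCorrelatedClique,
                    weights: SourceWeights) -> float:
    """Close_Score of a neighbor vertex with respect to a seed clique.

    The vertex must lie outside the seed and have at least one edge into it.
    The score is bounded by |S_j|/(|S_j|+1) + 1 < 2 and is 0 exactly when
    the vertex shares no term with the seed and its connecting edges carry
    zero weight (impossible with positive source weights).
    """
    if vertex in seed.members:
        raise ValueError(f"{vertex!r} is already a member of the seed clique")
    neighbors_in_seed = [u for u in network.graph.neighbors(vertex) if u in seed.members]
    if not neighbors_in_seed:
        raise ValueError(f"{vertex!r} has no edge into the seed clique")
    similarity = len(network.terms_of(vertex) & seed.common_attrs) / (len(seed.common_attrs) + 1)
    connectivity = sum(edge_weight(network, (vertex, u), weights)
                       for u in neighbors_in_seed) / len(seed.members)
    return similarity + connectivity


def augment_seeds(network: AttributedNetwork,
                  seeds: Sequence[OntologyCorrelatedClique],
                  weights: SourceWeights,
                  extend_thres: float = 0.1) -> list[PredictedComplex]:
    """Attach every seed-adjacent vertex scoring >= extend_thres, per seed.

    Seeds are processed independently; duplicate final member sets are
    deduplicated keeping the first (highest-ranked seed) occurrence.
    """
    if not 0.0 <= extend_thres <= 1.0:
        raise ValueError(f"extend_thres must lie in [0, 1], got {extend_thres}")
    complexes: list[PredictedComplex] = []
    seen_member_sets: set[frozenset[str]] = set()
    for seed in seeds:
        frontier = sorted({u for v in seed.members
                           for u in network.graph.neighbors(v)} - seed.members)
        attached = {}
        for vertex in frontier:
            score = closeness_score(network, vertex, seed, weights)
            if score >= extend_thres:
                attached[vertex] = score
        complex_ = PredictedComplex(seed, attached)
        if complex_.members not in seen_member_sets:
            seen_member_sets.add(complex_.members)
            complexes.append(complex_)
    return complexes
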