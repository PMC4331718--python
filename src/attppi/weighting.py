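"""Automatic estimation of per-source contribution weights (phase 1).

Evidence sources differ in reliability: high-throughput screens carry many
false positives, literature-mined interactions have their own error profile.
Rather than fixing the trade-off a priori, the contribution of each source
T_i is estimated from the quality of the seed cliques its data alone can
produce. One single-source attributed network is built per source (every
edge typed {T_i}), seeds are generated at equal initial weights
(w_1 = ... = w_k = 1/k), and the source's contribution degree is

    C_Degree(T_i) = ( Σ_seeds score_j · |E_cj| ) / |E_Ti|

— the seed scores, weighted by the number of clique-internal edges |E_cj|,
normalized by the total number of edges |E_Ti| the source reported. Final
weights are the C_Degrees normalized to sum to 1; if every C_Degree is 0
(no source yields a seed) the weights fall back to equal.

Under equal initial weights every single-source edge weighs 1/k, so phase-1
densities are uniformly scaled by 1/k; this cancels in the C_Degree ratio
and is kept as the literal procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cliques import OntologyCorrelatedClique
from .io_formats import AnnotationRecord, TypedEdgeRecord
from .network import SourceWeights, build_network
from .seeds import generate_candidates, select_seeds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContributionReport:
    """Per-source C_Degree, edge count and resulting contribution weight."""

    c_degrees: Mapping[str, float]
    edge_counts: Mapping[str, int]
    seed_counts: Mapping[str, int]

    @property
    def weights(self) -> SourceWeights:
        total = sum(self.c_degrees.values())
        tags = list(self.c_degrees)
        if total <= 0:
            logger.warning("all C_Degrees are 0; falling back to equal weights")
            return SourceWeights.equal(tags)
        return SourceWeights({t: self.c_degrees[t] / total for t in tags})


def c_degree(seeds: Iterable[OntologyCorrelatedClique], total_type_edges: int) -> float:
    """C_Degree of one source from its seed set and its total edge count."""
    if total_type_edges < 1:
        raise ValueError(f"total_type_edges must be >= 1, got {total_type_edges}")
    return sum(s.score * s.n_internal_edges for s in seeds) / total_type_edges


def compute_source_weights(edges_by_type: Mapping[str, Sequence[TypedEdgeRecord]],
                           annotations: Sequence[AnnotationRecord],
                           min_clique_size: int = 3) -> ContributionReport:
    """Run phase 1: one single-source network per tag, seeds at equal weights,
    C_Degree per source, weights by normalization.

    ``edges_by_type`` maps each declared tag to that source's edge records
    (records are re-tagged to their key, so one parsed dataset can be reused
    under several hypothetical labels). At least one source must be
    non-empty.
    """
    tags = tuple(edges_by_type)
    if not any(len(v) for v in edges_by_type.values()):
        raise ValueError("all sources are empty; cannot estimate contribution weights")
    initial = SourceWeights.equal(tags)
    c_degrees: dict[str, float] = {}
    edge_counts: dict[str, int] = {}
    seed_counts: dict[str, int] = {}
    for tag in tags:
        records = [TypedEdgeRecord(r.protein_a, r.protein_b, tag) for r in edges_by_type[tag]]
        edge_counts[tag] = len(records)
        if not records:
            c_degrees[tag] = 0.0
            seed_counts[tag] = 0
            continue
        net = build_network(records, annotations, edge_tags=tags)
        seeds = select_seeds(net, generate_candidates(net, initial, min_size=min_clique_size),
                             initial, min_size=min_clique_size)
        seed_counts[tag] = len(seeds)
        c_degrees[tag] = c_degree(seeds, len(records))
        logger.info("source %s: %d edges, %d seeds, C_Degree=%.4f",
                    tag, len(records), len(seeds), c_degrees[tag])
    return ContributionReport(c_degrees, edge_counts, seed_counts)
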