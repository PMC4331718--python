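"""Candidate generation and seed-clique selection.

Candidates are all maximal cliques of size >= 3 whose members share at least
one GO-slim term, each scored as an ontology-correlated clique and ranked by
descending score. Because maximal cliques overlap heavily in PPI networks,
the ranked list is then reduced to a pairwise vertex-disjoint seed set: the
top candidate is kept, its vertices are subtracted from every remaining
candidate (a subset of a clique is still a clique), survivors that fall below
three vertices are dropped, the rest are re-scored with their new common
attribute set and re-ranked, and the loop repeats until no candidate is left.

Ties are broken everywhere by (score desc, size desc, lexicographic sorted
member tuple asc) so the procedure is fully deterministic.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

from .cliques import (
    OntologyCorrelatedClique,
    StructuralCorrelationCache,
    clique_score,
    enumerate_maximal_cliques,
)
from .network import AttributedNetwork, SourceWeights

logger = logging.getLogger(__name__)


def generate_candidates(network: AttributedNetwork, weights: SourceWeights,
                        min_size: int = 3) -> list[OntologyCorrelatedClique]:
    """Rank all maximal cliques with a non-empty common attribute set.

    Cliques whose members share no term would score 0 and are excluded from
    candidacy altogether.
    """
    eta = StructuralCorrelationCache(network)
    candidates = []
    for members in enumerate_maximal_cliques(network, min_size=min_size):
        occ = clique_score(network, members, weights, eta=eta)
        if occ.common_attrs:
            candidates.append(occ)
    candidates.sort(key=OntologyCorrelatedClique.sort_key)
    return candidates


def select_seeds(network: AttributedNetwork,
                 candidates: Sequence[OntologyCorrelatedClique],
                 weights: SourceWeights,
                 min_size: int = 3,
                 overlap_mode: Literal["prune", "discard"] = "prune",
                 discard_threshold: float = 0.5
                 ) -> list[OntologyCorrelatedClique]:
    """Reduce ranked candidates to a pairwise vertex-disjoint seed set.

    ``overlap_mode="prune"`` (default) subtracts already-seeded vertices from
    every remaining candidate. ``overlap_mode="discard"`` first drops any
    candidate whose fraction of already-seeded vertices exceeds
    *discard_threshold*, then prunes the survivors; it trades seed count for
    seed purity. Both modes re-score pruned cliques with their recomputed
    common attribute set and keep only those with |C| >= min_size, |S| >= 1
    and score > 0.
    """
    eta = StructuralCorrelationCache(network)
    pool = sorted(candidates, key=OntologyCorrelatedClique.sort_key)
    seeds: list[OntologyCorrelatedClique] = []
    used: set[str] = set()
    while pool:
        top = pool.pop(0)
        seeds.append(top)
        used |= top.members
        survivors: list[OntologyCorrelatedClique] = []
        for cand in pool:
            overlap = cand.members & used
            if not overlap:
                survivors.append(cand)
                continue
            if overlap_mode == "discard" and len(overlap) / len(cand.members) > discard_threshold:
                continue
            remaining = cand.members - used
            if len(remaining) < min_size:
                continue
            rescored = clique_score(network, remaining, weights, eta=eta)
            if rescored.common_attrs and rescored.score > 0:
                survivors.append(rescored)
        survivors.sort(key=OntologyCorrelatedClique.sort_key)
        pool = survivors
    # belt-and-braces: the construction guarantees disjointness
    assert sum(len(s.members) for s in seeds) == len(set().union(*(s.members for s in seeds)) if seeds else set())
    return [s for s in seeds if s.score > 0 and s.common_attrs]
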