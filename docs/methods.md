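# Methods

## Model and procedure

`attppi` treats complex prediction as attributed-graph mining. The network is
a 6-tuple G = (V, E, A_v, A_e, F_v, F_e): proteins with GO-slim term sets
(F_v, possibly empty) and undirected interactions with non-empty
evidence-source sets (F_e ⊆ A_e). The pipeline is hard-wired to two sources —
T1 high-throughput, T2 literature-extracted — but every formula generalizes
to k ≥ 1 sources and the data model accepts that.

The unit of inference is the *ontology-correlated clique*: a clique C of
≥ 3 proteins plus S = ∩ F_v(p), the terms its members share. Its score

    Clique_Score = η(S) · |C| · |S| · Density(C)

combines four signals. η(S) = |K_S| / |V(S)| measures how predictive the term
set is of cohesive structure: V(S) is every protein carrying all of S, K_S
those of them inside a ≥ 3-clique of the S-induced subgraph. Because every
clique of size ≥ 3 contains a triangle and every triangle is such a clique,
K_S is computed exactly as the triangle-participating vertices of G(S) (a
per-vertex triangle count), and the tests cross-check this against a
brute-force subset oracle. Density is the weighted analogue of edge density;
with normalized source weights it is 1 exactly when every internal edge is
corroborated by every source. |S| = 0 annihilates the product, so cliques
with no shared term are never candidates.

Prediction runs in two phases. Phase 1 estimates the source weights: for
each source alone, candidates are mined at equal initial weights (1/k per
source, so every single-source edge weighs 1/k — the uniform halving cancels
in the final ratio), reduced to a disjoint seed set, and summarized as

    C_Degree(T_i) = Σ_seeds Clique_Score_j · |E_cj| / |E_Ti| ,

where |E_cj| is the seed's internal edge count and |E_Ti| the *total* number
of edges the source reported — a deliberate, literal reading: the denominator
normalizes seed quality by the bulk of data the source contributed. Weights
are the C_Degrees normalized to sum to 1, with a fallback to equal weights
when no source yields any seed (empty seed sets never arise in realistic
data, but a robust tool must not divide by zero). Phase 2 rebuilds the
combined network, selects seeds under the estimated weights and augments
them.

## Seed selection

Maximal cliques come from pivoted Bron–Kerbosch recursion
(`networkx.find_cliques`), exact at PPI scale. Candidates are ranked by
(score desc, |C| desc, lexicographic member tuple asc) — the tie-break makes
every downstream step platform-independent. Disjointness is enforced by
prune-by-subtraction: the top candidate becomes a seed, its vertices are
deleted from all remaining candidates, survivors below 3 vertices are
dropped, and the rest are *re-scored with their recomputed common attribute
set* (a subset of a clique is a clique, but its S can only grow and its
density can change) and re-ranked. Whether the original procedure re-scored
pruned cliques is unstated; re-scoring is the choice consistent with ranking
always reflecting current clique content. A stricter variant
(`overlap_mode="discard"`, threshold 0.5 on the already-seeded fraction)
drops heavily-overlapping candidates outright instead of shrinking them.

## Augmentation

Each neighbor P_k of a seed ((C_j, E_cj), S_j) is scored

    Close_Score = |S_k ∩ S_j| / (|S_j| + 1) + Σ_{e ∈ E_p} weight(e) / |C_j|

(annotation similarity plus weighted connectivity; the +1 in the first
denominator keeps unannotated seeds meaningful and bounds the term below 1).
Neighbors scoring ≥ extend_thres are attached. All neighbors are scored
against the *immutable* seed and attached as a batch: an incremental variant
that grows C_j between scorings would be order-dependent, and no ordering is
defined for it. Batch scoring also makes attachment sets exactly monotone
non-increasing in extend_thres, which the tests assert. Final complexes may
overlap each other (only seeds are disjoint); identical member sets are
deduplicated. The default extend_thres = 0.1 is the empirically optimal
operating point for this score on yeast-scale networks and is exposed as a
flag; unannotated proteins are retained in the network throughout, since the
connectivity term alone can justify their attachment.

## Evaluation

A prediction P matches a benchmark complex B when
NA = |P∩B|²/(|P||B|) strictly exceeds the threshold (default 0.2; equality
does not match). Precision, recall and F follow from the matching;
clustering-wise Sn and PPV come from the overlap contingency
t_ij = |B_i ∩ P_j| (Sn = Σ_i max_j t_ij / Σ_i |B_i|,
PPV = Σ_j max_i t_ij / Σ_ij t_ij, 0 when the denominator vanishes), and
Acc = √(Sn·PPV). Predictions with fewer than two members are excluded before
evaluation with a logged count; the report carries both raw and evaluated
prediction counts so complex tallies are unambiguous.

## The worked-example fixture

The published 8-protein example network is specified only through its
printed consequences, not its full topology. `figure3_fixture()` therefore
reconstructs it from the complete constraint set: all of P1…P8 carry GS1,
exactly {P2,P3,P4,P5} carry GS2, GS3 marks only triangle-free proteins
(P1, P7); at w = (0.6, 0.4) the densities of {P2,P5,P6} / {P2,P3,P5} /
{P2,P3,P4,P5} are 0.667 / 0.867 / 0.833 and the η values of {GS1} / {GS3} /
{GS1,GS2} are 0.625 / 0 / 1. Those densities force the edge-type assignment
inside the 4-clique up to symmetry (four dual-source edges, one T1-only —
P3P5 — and one T2-only — P4P5), and the triangle {P2,P5,P6} fixes P2P6 as
T1-only and P5P6 as T2-only. The pendant attachments of P1, P7, P8 are
unconstrained beyond triangle-freeness; we hang them off P3, P6 and P4
respectively. The constraint system was verified by brute force before
freezing, and a regression test asserts every published cell.

Published clique scores are hand-computed from densities already rounded to
3 decimals (1·4·2·0.833 = 6.664, whereas full precision gives 20/3 ≈ 6.667).
Ranking therefore uses full-precision scores internally, and
`OntologyCorrelatedClique.rounded_score()` reproduces the printed-precision
convention for reporting and for the acceptance script.

## Synthetic data

The generator plants `n_complexes` vertex-disjoint cliques (sizes uniform on
`complex_size`, default 4–7, the typical small-complex range), each tagged
with a complex-specific GO term on all members, inside a background of
`n_background_vertices` (default 100) proteins and uniform noise edges at
`p_background`. Every realized edge is offered independently to each source
with a class-specific retention probability (complex edges vs. background
edges); an edge claimed by no source is assigned to the source with the
highest retention for its class, so at p_within = 1 planted complexes are
cliques of the union network by construction. Background proteins draw one
term each — a planted term with probability `shared_term_prob` (default 0.1,
exercising η < 1 regimes), otherwise one of `n_distractor_terms` decoys.
Everything is driven by one `numpy` generator seed; equal seeds give
byte-identical serializations.

`biased_two_source_spec` is the benchmark for the weighting mechanism: T1
retains complex edges at 0.95 and background at 0.1, T2 the reverse (0.15 /
0.9) — one informative and one unreliable source. Its background density
(p_background = 0.05) is chosen so that a single noise edge into a typical
seed clique straddles the default attachment cutoff: under equal weights
such edges weigh 0.5 and drag spurious neighbors into complexes, while
estimated weights suppress the noisy source and keep them out. At much lower
noise both weighting modes recover every complex perfectly and the benchmark
cannot separate them.

`add_random_edges` implements the degradation control — n uniform-random
absent pairs added as high-throughput edges, input left untouched — and the
tests confirm mean F does not improve as noise is added.

What the generator does **not** emulate: overlapping true complexes (planted
complexes are disjoint; real catalogues overlap), degree heterogeneity and
hub proteins, correlated false negatives within a bait's pull-down, the
hierarchical structure of real GO annotations (terms here are flat, opaque
labels), and literature-mining error modes beyond uniform noise. Passing the
synthetic suites therefore demonstrates correctness of the algorithmics and
the claimed qualitative behaviors, not field performance on yeast data.

## Problem sizes and numerics

Tests and the acceptance script run on the 8-protein fixture, exhaustively
checkable random graphs (≤ 12 vertices, against subset-enumeration oracles),
and synthetic benchmarks of roughly 30–140 proteins with 5–10 replicate
seeds — sizes at which every oracle is exact and full suites complete in
seconds. All scoring arithmetic is double precision; comparisons in tests
use absolute tolerances of 5e-4 for quantities published at 3 decimals.
Degenerate inputs are contracts, not silent defaults: empty cliques,
sub-minimum densities, out-of-range thresholds and empty evaluation inputs
raise `ValueError`.

## Known limitations

- Protein IDs are verbatim strings; reconciling experimental accessions with
  literature-normalized names is upstream of this tool, and inputs are
  assumed to share one namespace.
- No post-processing merges highly overlapping predictions.
- η is exact but recomputed per distinct attribute set; on networks with very
  many distinct common-attribute sets the memoized cache grows accordingly.
- The literature-mining pipeline that produces the T2 edge list is out of
  scope; `attppi` consumes its output as a plain edge list.
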