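"""In-memory pipeline runner shared by synthetic-benchmark tests."""

from attppi import (
    ComplexRecord,
    SourceWeights,
    augment_seeds,
    compute_source_weights,
    generate_candidates,
    match_and_score,
    select_seeds,
)
from attppi.network import network_to_records


def run_pipeline(network, truth, weight_mode="auto", extend_thres=0.1):
    """Predict complexes on a generated network and score them against truth.

    Returns (EvaluationReport, SourceWeights used).
    """
    if weight_mode == "auto":
        by_type, annotations = network_to_records(network)
        weights = compute_source_weights(by_type, annotations).weights
    elif weight_mode == "equal":
        weights = SourceWeights.equal(network.edge_tags)
    else:
        weights = weight_mode
    candidates = generate_candidates(network, weights)
    seeds = select_seeds(network, candidates, weights)
    complexes = augment_seeds(network, seeds, weights, extend_thres=extend_thres)
    predicted = [ComplexRecord(c.members) for c in complexes if len(c.members) >= 2]
    if not predicted:
        return None, weights
    return match_and_score(predicted, truth), weights
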