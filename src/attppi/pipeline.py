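"""End-to-end orchestration of the two-phase prediction method.

Phase 1 builds one single-source attributed network per evidence type and
estimates the contribution weights from seed-clique quality (or uses fixed /
equal weights, per configuration). Phase 2 builds the combined attributed
network from all sources, generates and selects seed cliques under the
estimated weights, augments them with close neighbors, and writes the
predicted complexes plus a machine-readable run report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .augment import PredictedComplex, augment_seeds
from .evaluation import EvaluationReport, format_report, match_and_score, report_to_tsv
from .io_formats import (
    ComplexRecord,
    DEFAULT_TAGS,
    HIGH_THROUGHPUT,
    LITERATURE,
    read_annotations,
    read_complexes,
    read_edge_list,
    write_complexes,
)
from .network import SourceWeights, build_network
from .seeds import generate_candidates, select_seeds
from .weighting import compute_source_weights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one prediction run."""

    ht_edges: str
    lit_edges: str
    annotations: str
    out_dir: str
    benchmark: str | None = None
    extend_thres: float = 0.1
    na_threshold: float = 0.2
    min_clique_size: int = 3
    #: "auto" (estimate from data), "equal", or "w1,w2" fixed weights
    weight_mode: str = "auto"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0.0 <= self.extend_thres <= 1.0:
            raise ValueError("extend_thres must lie in [0, 1]")
        if not 0.0 <= self.na_threshold <= 1.0:
            raise ValueError("na_threshold must lie in [0, 1]")
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")

    def resolve_weights(self) -> SourceWeights | None:
        """Fixed weights from the config, or None when mode is 'auto'."""
        if self.weight_mode == "auto":
            return None
        if self.weight_mode == "equal":
            return SourceWeights.equal(DEFAULT_TAGS)
        parts = [float(x) for x in self.weight_mode.split(",")]
        if len(parts) != 2:
            raise ValueError(f"weight_mode must be auto, equal or 'w1,w2'; got {self.weight_mode!r}")
        total = parts[0] + parts[1]
        if total <= 0:
            raise ValueError("fixed weights must have a positive sum")
        return SourceWeights.from_pair(parts[0] / total, parts[1] / total)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML config; keyword overrides win."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_predict(config: RunConfig) -> tuple[list[PredictedComplex], dict]:
    """Execute both phases; write predictions, attachment scores and report.

    Returns the predicted complexes and the report dict. The whole procedure
    is deterministic for a fixed config, so identical configs produce
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ht = read_edge_list(config.ht_edges, HIGH_THROUGHPUT)
    lit = read_edge_list(config.lit_edges, LITERATURE)
    annotations = read_annotations(config.annotations)
    logger.info("read %d high-throughput and %d literature edges, %d annotations",
                len(ht), len(lit), len(annotations))

    report: dict = {
        "tool": "attppi", "version": __version__,
        "config": {k: getattr(config, k) for k in (
            "ht_edges", "lit_edges", "annotations", "benchmark", "out_dir",
            "extend_thres", "na_threshold", "min_clique_size", "weight_mode",
            "seed")},
        "counts": {"ht_edges": len(ht), "lit_edges": len(lit),
                   "annotations": len(annotations)},
    }

    fixed = config.resolve_weights()
    if fixed is None:
        contrib = compute_source_weights(
            {HIGH_THROUGHPUT: ht, LITERATURE: lit}, annotations,
            min_clique_size=config.min_clique_size)
        weights = contrib.weights
        report["contribution"] = {
            tag: {"c_degree": contrib.c_degrees[tag],
                  "n_edges": contrib.edge_counts[tag],
                  "n_seeds": contrib.seed_counts[tag],
                  "weight": weights[tag]}
            for tag in contrib.c_degrees}
    else:
        weights = fixed
    report["weights"] = dict(weights.w)
    logger.info("source weights: %s", dict(weights.w))

    network = build_network(ht + lit, annotations)
    candidates = generate_candidates(network, weights, min_size=config.min_clique_size)
    seeds = select_seeds(network, candidates, weights, min_size=config.min_clique_size)
    complexes = augment_seeds(network, seeds, weights, extend_thres=config.extend_thres)
    report["counts"].update({
        "vertices": network.n_vertices(), "edges": network.n_edges(),
        "candidates": len(candidates), "seeds": len(seeds),
        "complexes": len(complexes),
    })
    if not candidates:
        logger.warning("no candidate cliques found; prediction file will be empty")

    records = [ComplexRecord(c.members) for c in complexes if len(c.members) >= 2]
    write_complexes(records, out / "predictions.tsv")
    with open(out / "attachments.tsv", "w", encoding="utf-8") as fh:
        fh.write("complex_index\tseed_members\tattached_protein\tcloseness\n")
        for idx, c in enumerate(complexes):
            seed_str = ",".join(sorted(c.seed.members))
            for vertex in sorted(c.attachments):
                fh.write(f"{idx}\t{seed_str}\t{vertex}\t{c.attachments[vertex]:.4f}\n")

    if config.benchmark:
        evaluation = run_evaluate(out / "predictions.tsv", config.benchmark,
                                  config.na_threshold, out / "evaluation.tsv")
        report["evaluation"] = evaluation.as_row()

    with open(out / "report.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    return complexes, report


def run_evaluate(predictions_path: str | Path, benchmark_path: str | Path,
                 na_threshold: float = 0.2,
                 out_path: str | Path | None = None) -> EvaluationReport:
    """Evaluate a prediction file against a benchmark file; optionally write TSV."""
    predicted = read_complexes(predictions_path)
    benchmark = read_complexes(benchmark_path)
    if not predicted:
        logger.warning("empty prediction file; reporting zero metrics")
        report = EvaluationReport(0, 0, len(benchmark), (), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    else:
        report = match_and_score(predicted, benchmark, na_threshold=na_threshold)
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(report_to_tsv(report))
    logger.info("\n%s", format_report(report))
    return report
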