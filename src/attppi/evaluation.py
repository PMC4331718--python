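"""Evaluation of predicted complexes against a benchmark catalogue.

Matching uses the neighborhood affinity NA(P, B) = |P ∩ B|² / (|P| · |B|);
a prediction and a benchmark complex match when NA strictly exceeds the
threshold (0.2 by convention — equality does not match). From the matching:

* precision — fraction of predictions matching >= 1 benchmark complex;
* recall — fraction of benchmark complexes matched by >= 1 prediction;
* F-score — their harmonic mean.

Complementary clustering-wise metrics come from the overlap contingency
t_ij = |B_i ∩ P_j|: sensitivity Sn = Σ_i max_j t_ij / Σ_i |B_i|, positive
predictive value PPV = Σ_j max_i t_ij / Σ_ij t_ij, and the accuracy
Acc = sqrt(Sn · PPV), their geometric mean, which is low whenever either
component is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .io_formats import ComplexRecord

logger = logging.getLogger(__name__)


def neighborhood_affinity(P: frozenset[str] | set[str],
                          B: frozenset[str] | set[str]) -> float:
    """NA(P, B) = |P ∩ B|² / (|P| · |B|), symmetric, in [0, 1]."""
    if not P or not B:
        raise ValueError("neighborhood affinity is undefined for empty sets")
    return len(P & B) ** 2 / (len(P) * len(B))


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean; 0 when both components are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def accuracy(sn: float, ppv: float) -> float:
    """Geometric mean of clustering-wise sensitivity and PPV."""
    return math.sqrt(sn * ppv)


@dataclass(frozen=True)
class EvaluationReport:
    n_predicted: int          # predictions evaluated (size >= 2, deduplicated)
    n_predicted_raw: int      # predictions supplied before filtering
    n_benchmark: int
    matches: tuple[tuple[int, int, float], ...]  # (predicted idx, benchmark idx, NA)
    precision: float
    recall: float
    f_score: float
    sn: float
    ppv: float
    acc: float

    def as_row(self) -> dict[str, float | int]:
        return {
            "P": self.precision, "R": self.recall, "F": self.f_score,
            "Sn": self.sn, "PPV": self.ppv, "Acc": self.acc,
            "n_complexes": self.n_predicted, "n_complexes_raw": self.n_predicted_raw,
        }


def match_and_score(predicted: Sequence[ComplexRecord],
                    benchmark: Sequence[ComplexRecord],
                    na_threshold: float = 0.2) -> EvaluationReport:
    """Match predictions to benchmark complexes and compute all metrics.

    Predictions of fewer than two members are excluded up front with a
    logged count (a complex is >= 2 proteins by definition); the report
    carries both the raw and the evaluated prediction counts.
    """
    if not predicted or not benchmark:
        raise ValueError("both the predicted and the benchmark set must be non-empty")
    n_raw = len(predicted)
    preds = [p.members for p in predicted if len(p.members) >= 2]
    if len(preds) < n_raw:
        logger.info("excluded %d prediction(s) of size < 2", n_raw - len(preds))
    bench = [b.members for b in benchmark]

    matches: list[tuple[int, int, float]] = []
    matched_pred: set[int] = set()
    matched_bench: set[int] = set()
    for j, P in enumerate(preds):
        for i, B in enumerate(bench):
            na = neighborhood_affinity(P, B)
            if na > na_threshold:
                matches.append((j, i, na))
                matched_pred.add(j)
                matched_bench.add(i)

    precision = len(matched_pred) / len(preds) if preds else 0.0
    recall = len(matched_bench) / len(bench)

    # clustering-wise Sn / PPV from the overlap contingency t_ij
    t = [[len(B & P) for P in preds] for B in bench]
    sn_den = sum(len(B) for B in bench)
    sn = sum(max(row, default=0) for row in t) / sn_den if sn_den else 0.0
    ppv_den = sum(sum(row) for row in t)
    if ppv_den:
        ppv = sum(max(t[i][j] for i in range(len(bench))) for j in range(len(preds))) / ppv_den
    else:
        ppv = 0.0

    return EvaluationReport(
        n_predicted=len(preds), n_predicted_raw=n_raw, n_benchmark=len(bench),
        matches=tuple(matches),
        precision=precision, recall=recall, f_score=f_score(precision, recall),
        sn=sn, ppv=ppv, acc=accuracy(sn, ppv),
    )


_COLUMNS = ("P", "R", "F", "Sn", "PPV", "Acc", "n_complexes", "n_complexes_raw")


def report_to_tsv(report: EvaluationReport) -> str:
    row = report.as_row()
    header = "\t".join(_COLUMNS)
    values = "\t".join(f"{row[c]:.3f}" if isinstance(row[c], float) else str(row[c])
                       for c in _COLUMNS)
    return f"{header}\n{values}\n"


def format_report(report: EvaluationReport) -> str:
    """Human-readable multi-line summary."""
    lines = [
        f"predicted complexes : {report.n_predicted} "
        f"({report.n_predicted_raw} before size filter/dedup)",
        f"benchmark complexes : {report.n_benchmark}",
        f"precision / recall / F : {report.precision:.3f} / {report.recall:.3f} / {report.f_score:.3f}",
        f"Sn / PPV / Acc         : {report.sn:.3f} / {report.ppv:.3f} / {report.acc:.3f}",
    ]
    return "\n".join(lines) + "\n"
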