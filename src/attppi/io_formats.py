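"""Readers and writers for the on-disk formats.

Three plain-text formats are supported:

* typed PPI edge lists — TSV with two columns ``protein_a  protein_b``; the
  evidence source (high-throughput vs. literature) is a property of the file,
  supplied by the caller, not of individual lines;
* vertex annotation tables — TSV with columns ``protein  go_slim_term``
  (a GAF 2.x convenience reader is also provided);
* complex files — one complex per line, whitespace-separated member IDs
  (the CYC2008 / MIPS convention).

Lines starting with ``#`` are comments everywhere. Protein IDs are taken
verbatim and are case-sensitive: no normalization is attempted, since folding
case could silently merge distinct loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Default evidence-source tags: T1 = high-throughput, T2 = literature-mined.
HIGH_THROUGHPUT = "T1"
LITERATURE = "T2"
DEFAULT_TAGS = (HIGH_THROUGHPUT, LITERATURE)


class ParseError(ValueError):
    """A line of an input file could not be parsed.

    Carries the path and 1-based line number of the offending line.
    """

    def __init__(self, path: str | Path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class TypedEdgeRecord:
    """An undirected PPI with its evidence-source tag.

    Endpoints are canonicalized so that ``protein_a < protein_b``
    lexicographically; PPIs are undirected in every source considered here.
    """

    protein_a: str
    protein_b: str
    source_type: str = HIGH_THROUGHPUT

    def __post_init__(self):
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein IDs must be non-empty")
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction {self.protein_a!r} is not a valid edge")
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True, order=True)
class AnnotationRecord:
    """One (protein, GO-slim term) annotation pair."""

    protein: str
    go_slim: str

    def __post_init__(self):
        if not self.protein or not self.go_slim:
            raise ValueError("protein and term IDs must be non-empty")


@dataclass(frozen=True)
class ComplexRecord:
    """A protein complex: a set of at least two member proteins."""

    members: frozenset[str]
    name: str | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 2:
            raise ValueError(f"a complex needs >= 2 members, got {sorted(self.members)}")


def _content_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, source_type: str = HIGH_THROUGHPUT) -> list[TypedEdgeRecord]:
    """Read a two-column edge list, tagging every edge with *source_type*.

    Self-loops are dropped (with a logged count) and duplicate unordered
    pairs are collapsed to one record. Raises :class:`ParseError` on lines
    with fewer than two fields and :class:`FileNotFoundError` for a missing
    file.
    """
    records: list[TypedEdgeRecord] = []
    seen: set[tuple[str, str]] = set()
    n_self_loops = 0
    n_duplicates = 0
    for lineno, line in _content_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected >= 2 fields, got {len(fields)}")
        a, b = fields[0], fields[1]
        if a == b:
            n_self_loops += 1
            continue
        rec = TypedEdgeRecord(a, b, source_type)
        if rec.pair in seen:
            n_duplicates += 1
            continue
        seen.add(rec.pair)
        records.append(rec)
    if n_self_loops:
        logger.info("%s: dropped %d self-loop line(s)", path, n_self_loops)
    if n_duplicates:
        logger.info("%s: collapsed %d duplicate pair(s)", path, n_duplicates)
    return records


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a two-column (protein, GO-slim term) table, deduplicated."""
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, line in _content_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(path, lineno, f"expected >= 2 fields, got {len(fields)}")
        key = (fields[0], fields[1])
        if key in seen:
            continue
        seen.add(key)
        records.append(AnnotationRecord(*key))
    return records


def read_annotations_gaf(path: str | Path) -> list[AnnotationRecord]:
    """Convenience reader for GAF 2.x: takes columns 2 (object ID) and 5 (GO ID).

    GAF comment lines start with ``!``. Terms are opaque labels; no ontology
    structure is interpreted.
    """
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(path, lineno, f"GAF line has {len(fields)} column(s), need >= 5")
            key = (fields[1], fields[4])
            if key in seen:
                continue
            seen.add(key)
            records.append(AnnotationRecord(*key))
    return records


def read_complexes(path: str | Path) -> list[ComplexRecord]:
    """Read one complex per line; lines with < 2 members are skipped with a warning."""
    records: list[ComplexRecord] = []
    for lineno, line in _content_lines(path):
        members = frozenset(line.split())
        if len(members) < 2:
            logger.warning("%s:%d: skipping degenerate complex with %d member(s)",
                           path, lineno, len(members))
            continue
        records.append(ComplexRecord(members))
    return records


def write_complexes(records: Sequence[ComplexRecord], path: str | Path) -> None:
    """Write complexes one per line, members sorted, complexes in input order."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(" ".join(sorted(rec.members)) + "\n")


def write_edge_list(records: Sequence[TypedEdgeRecord], path: str | Path) -> None:
    """Write edges as two-column TSV (the source tag is per-file, not per-line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in sorted(records):
            fh.write(f"{rec.protein_a}\t{rec.protein_b}\n")


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in sorted(records):
            fh.write(f"{rec.protein}\t{rec.go_slim}\n")
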