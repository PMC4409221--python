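"""Nearest-exon assignment and exonic/intronic/intergenic classification.

Distances are interval gaps in 0-based half-open coordinates:
``max(0, hit_start - exon_end, exon_start - hit_end)``; overlapping or
directly abutting intervals get distance 0. Exons farther than the
assignment radius (strictly ``distance < radius``) yield NA. Annotation
ignores the hit strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ExonRecord", "ExonAnnotation", "ExonSet", "load_exons", "closest_exon", "classify_location"]


@dataclass(frozen=True)
class ExonRecord:
    chrom: str
    start: int
    end: int
    gene_name: str
    gene_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"exon start must be < end, got [{self.start}, {self.end})")


@dataclass(frozen=True)
class ExonAnnotation:
    """Closest-exon assignment for one off-target hit.

    ``distance`` is None (NA) when no exon lies within the radius on the
    hit's chromosome; then gene fields are None and the category is
    intergenic.
    """

    distance: int | None
    gene_name: str | None
    gene_id: str | None
    category: str  # "exonic" | "intronic" | "intergenic"


class ExonSet:
    """Exon intervals queryable by chromosome, with per-gene spans."""

    def __init__(self, records: Iterable[ExonRecord]):
        by_chrom: dict[str, list[ExonRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._records: dict[str, list[ExonRecord]] = {}
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.gene_spans: dict[tuple[str, str], tuple[int, int]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.start, r.end, r.gene_id))
            self._records[chrom] = recs
            self._starts[chrom] = np.array([r.start for r in recs], dtype=np.int64)
            self._ends[chrom] = np.array([r.end for r in recs], dtype=np.int64)
            for r in recs:
                key = (chrom, r.gene_id)
                lo, hi = self.gene_spans.get(key, (r.start, r.end))
                self.gene_spans[key] = (min(lo, r.start), max(hi, r.end))

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    def chromosomes(self) -> list[str]:
        return sorted(self._records)

    def records(self, chrom: str) -> Sequence[ExonRecord]:
        return self._records.get(chrom, ())

    def gap_distances(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Gap distance from [start, end) to every exon on *chrom* (record order)."""
        if chrom not in self._records:
            return np.empty(0, dtype=np.int64)
        s, e = self._starts[chrom], self._ends[chrom]
        return np.maximum(0, np.maximum(start - e, s - end))


def load_exons(path: str | Path, name_delimiter: str = "|") -> ExonSet:
    """Load a BED file of exons (>= 4 columns) into an :class:`ExonSet`.

    The name field carries ``gene_name<delimiter>gene_id``; without the
    delimiter the whole name serves as both. Malformed lines are rejected
    with their line numbers.
    """
    records: list[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: exon start must be < end")
            if name_delimiter in name:
                gene_name, gene_id = name.split(name_delimiter, 1)
            else:
                gene_name = gene_id = name
            strand = fields[5] if len(fields) >= 6 else "+"
            records.append(ExonRecord(chrom, start, end, gene_name, gene_id, strand))
    return ExonSet(records)


def _interval_of(hit) -> tuple[str, int, int]:
    if isinstance(hit, tuple):
        return hit
    return hit.chrom, hit.start, hit.end


def closest_exon(hit, exons: ExonSet, radius: int = 100_000) -> ExonAnnotation:
    """Assign the closest exon within *radius* (strict) to *hit*.

    Ties between equidistant exons are broken by lower exon start, then
    lexicographic gene_id. Returns an NA/intergenic annotation when no exon
    qualifies.
    """
    chrom, start, end = _interval_of(hit)
    gaps = exons.gap_distances(chrom, start, end)
    if gaps.size == 0:
        return ExonAnnotation(None, None, None, "intergenic")
    best = int(gaps.min())
    if best >= radius:
        return ExonAnnotation(None, None, None, "intergenic")
    recs = exons.records(chrom)
    tied = [recs[i] for i in np.flatnonzero(gaps == best)]
    chosen = min(tied, key=lambda r: (r.start, r.gene_id))
    category = classify_location(hit, exons, assigned_gene_id=chosen.gene_id)
    return ExonAnnotation(best, chosen.gene_name, chosen.gene_id, category)


def classify_location(hit, exons: ExonSet, assigned_gene_id: str | None = None) -> str:
    """Classify *hit* as exonic, intronic or intergenic.

    Exonic: overlaps any exon. Intronic: non-exonic but within the assigned
    gene's span (min exon start to max exon end over exons sharing its
    gene_id on this chromosome). Intergenic otherwise.
    """
    chrom, start, end = _interval_of(hit)
    for rec in exons.records(chrom):
        if rec.start < end and start < rec.end:
            return "exonic"
    if assigned_gene_id is None:
        ann_gaps = exons.gap_distances(chrom, start, end)
        if ann_gaps.size:
            recs = exons.records(chrom)
            best = int(ann_gaps.min())
            tied = [recs[i] for i in np.flatnonzero(ann_gaps == best)]
            assigned_gene_id = min(tied, key=lambda r: (r.start, r.gene_id)).gene_id
    if assigned_gene_id is not None:
        span = exons.gene_spans.get((chrom, assigned_gene_id))
        if span is not None and span[0] < end and start < span[1]:
            return "intronic"
    return "intergenic"
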