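"""Per-off-target mismatch scoring and per-candidate aggregate ranking.

The off-target score sums ``base**pos`` over mismatch positions (1-based
from the protospacer 5' end), so PAM-proximal mismatches weigh more. The
site score aggregates, over exon-associated off-targets only,
``log10(dist) + mismatch_score / total`` and then subtracts the count of
ALL retained off-targets; higher is better (fewer, more distal, more
exon-remote off-targets). Distances are clamped to >= 1 before the log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .annotation import ExonAnnotation
from .discovery import CandidateSite
from .offtargets import OffTargetHit
from .oligos import OligoPair

__all__ = ["RankedSite", "off_target_score", "site_rank_score", "rank_sites"]


@dataclass
class RankedSite:
    """A candidate together with its scored off-target list and oligos."""

    candidate: CandidateSite
    off_targets: list[tuple[OffTargetHit, ExonAnnotation]]
    rank_score: float = 0.0
    rank: int | None = None
    oligos: OligoPair | None = None
    on_target: OffTargetHit | None = None

    @property
    def total_off_targets(self) -> int:
        return len(self.off_targets)


def off_target_score(
    mismatch_positions, base: float = 1.2, protospacer_length: int = 20
) -> float:
    """Sum of ``base**pos`` over mismatch positions; empty set scores 0."""
    positions = sorted(mismatch_positions)
    for p in positions:
        if not 1 <= p <= protospacer_length:
            raise ValueError(
                f"mismatch position {p} outside [1, {protospacer_length}]"
            )
    return float(sum(base**p for p in positions))


def site_rank_score(off_targets: list[tuple[OffTargetHit, ExonAnnotation]]) -> float:
    """Aggregate score for one candidate from its retained off-targets.

    Requires ``mismatch_score`` to be filled on every hit. Off-targets with
    an NA exon distance contribute only through the subtracted count term.
    """
    total = len(off_targets)
    if total == 0:
        return 0.0
    acc = 0.0
    for hit, ann in off_targets:
        if ann.distance is None:
            continue
        if hit.mismatch_score is None:
            raise ValueError("hit.mismatch_score must be computed before ranking")
        acc += math.log10(max(ann.distance, 1)) + hit.mismatch_score / total
    return acc - total


def rank_sites(sites: list[RankedSite]) -> list[RankedSite]:
    """Order sites best-first and assign ranks and T-labels.

    Descending rank_score; ties go to fewer off-targets, then smaller query
    start, then '+' strand.
    """
    ordered = sorted(
        sites,
        key=lambda s: (
            -s.rank_score,
            s.total_off_targets,
            s.candidate.query_start,
            0 if s.candidate.strand == "+" else 1,
        ),
    )
    for i, site in enumerate(ordered, start=1):
        site.rank = i
        site.candidate.site_id = f"T{i}"
    return ordered
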