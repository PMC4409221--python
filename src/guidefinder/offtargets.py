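"""Genome-wide off-target enumeration under the core/total mismatch model.

Two independent engines share one contract:

* :func:`search_off_targets` — seed-and-verify. The PAM-proximal core of the
  protospacer is partitioned into ``max_core_mismatches + 1`` near-equal
  segments; by pigeonhole, any genomic site with at most that many core
  mismatches matches at least one segment exactly, so an exact k-mer index
  over the genome (both strands) finds every candidate window, which is then
  verified against the full constraint set.
* :func:`brute_force_search` — a vectorized full window scan with no index,
  kept as the testing oracle.

A hit is retained iff: core mismatches <= max_core_mismatches, total
protospacer mismatches <= max_total_mismatches, and the adjacent PAM matches
the off-target PAM motif. Mismatch positions are 1-based from the
protospacer 5' end (position ``protospacer_length`` is PAM-adjacent); PAM
bases are matched by motif and never counted as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .config import PatternConfig
from .discovery import CandidateSite
from .sequence import encode, iupac_match, pam_code_table, revcomp

__all__ = [
    "OffTargetHit",
    "count_mismatches",
    "core_segments",
    "SeedIndex",
    "search_off_targets",
    "brute_force_search",
]


@dataclass
class OffTargetHit:
    """One genomic site matching a candidate under the mismatch model.

    ``start``/``end`` are 0-based half-open on the forward strand of
    ``chrom`` and span protospacer+PAM; ``site_sequence``/``pam_observed``
    are read 5'->3' on the PAM strand.
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_sequence: str
    pam_observed: str
    mismatch_positions: frozenset[int]
    mismatch_score: float | None = None
    is_on_target: bool = field(default=False)

    @property
    def total_mismatches(self) -> int:
        return len(self.mismatch_positions)

    def core_mismatches(self, cfg: PatternConfig) -> int:
        threshold = cfg.protospacer_length - cfg.core_length
        return sum(1 for p in self.mismatch_positions if p > threshold)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def count_mismatches(a: str, b: str) -> set[int]:
    """1-based positions where *a* and *b* differ (case-insensitive).

    Any non-ACGT character in *b* counts as a mismatch at its position.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    return {
        i + 1
        for i, (x, y) in enumerate(zip(a, b))
        if y not in "ACGT" or x != y
    }


def core_segments(cfg: PatternConfig) -> list[tuple[int, int]]:
    """Pigeonhole partition of the core into ``max_core_mismatches + 1`` segments.

    Returns (offset_within_protospacer, length) pairs; segment sizes differ
    by at most one base. Core length 12 with 2 allowed core mismatches gives
    three 4-mers.
    """
    n_seg = cfg.max_core_mismatches + 1
    if cfg.core_length < n_seg:
        raise ValueError("core_length must be >= max_core_mismatches + 1")
    base, extra = divmod(cfg.core_length, n_seg)
    core_start = cfg.protospacer_length - cfg.core_length
    segments = []
    offset = core_start
    for i in range(n_seg):
        size = base + (1 if i < extra else 0)
        segments.append((offset, size))
        offset += size
    return segments


class SeedIndex:
    """Exact-substring k-mer index over both strands of a genome.

    Indexes every k-mer for each distinct core-segment length implied by the
    configuration, so seed lookups are O(1) per segment.
    """

    def __init__(self, genome: Mapping[str, str], cfg: PatternConfig):
        if not genome:
            raise ValueError("empty genome")
        self.segment_lengths = sorted({size for _, size in core_segments(cfg)})
        self.oriented: dict[tuple[str, str], str] = {}
        self._index: dict[int, dict[str, list[tuple[str, str, int]]]] = {
            k: {} for k in self.segment_lengths
        }
        for chrom in sorted(genome):
            seq = str(genome[chrom]).upper()
            for strand, oseq in (("+", seq), ("-", revcomp(seq))):
                self.oriented[(chrom, strand)] = oseq
                for k in self.segment_lengths:
                    bucket = self._index[k]
                    for pos in range(len(oseq) - k + 1):
                        bucket.setdefault(oseq[pos : pos + k], []).append((chrom, strand, pos))

    def lookup(self, k: int, kmer: str) -> list[tuple[str, str, int]]:
        """Positions of *kmer* as (chrom, strand, offset-in-oriented-sequence)."""
        if k not in self._index:
            raise KeyError(f"index holds no {k}-mers (have {self.segment_lengths})")
        return self._index[k].get(kmer, [])

    def kmers(self, k: int) -> set[str]:
        return set(self._index[k])


def _forward_interval(strand: str, offset: int, site_len: int, chrom_len: int) -> tuple[int, int]:
    """Map an oriented-sequence window to forward-strand coordinates."""
    if strand == "+":
        return offset, offset + site_len
    return chrom_len - (offset + site_len), chrom_len - offset


def _verify_window(
    proto: str, oseq: str, offset: int, cfg: PatternConfig
) -> tuple[frozenset[int], str, str] | None:
    """Check one oriented window against the constraint set; None if rejected."""
    length = cfg.protospacer_length
    pam_motif = cfg.offtarget_pam
    site_len = length + len(pam_motif)
    if offset < 0 or offset + site_len > len(oseq):
        return None
    proto_g = oseq[offset : offset + length]
    mismatches = count_mismatches(proto, proto_g)
    if len(mismatches) > cfg.max_total_mismatches:
        return None
    threshold = length - cfg.core_length
    if sum(1 for p in mismatches if p > threshold) > cfg.max_core_mismatches:
        return None
    pam_g = oseq[offset + length : offset + site_len]
    if not all(iupac_match(p, g) for p, g in zip(pam_motif, pam_g)):
        return None
    return frozenset(mismatches), proto_g, pam_g


def _finalize(
    hits: list[OffTargetHit],
    cfg: PatternConfig,
    on_target_locus: tuple[str, int, int] | None,
    include_on_target: bool,
) -> list[OffTargetHit]:
    """Sort, flag the presumed on-target, optionally drop it, sanity-assert."""
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    for h in hits:
        assert h.total_mismatches <= cfg.max_total_mismatches
        assert h.core_mismatches(cfg) <= cfg.max_core_mismatches
    if hits:
        if on_target_locus is not None:
            for h in hits:
                if h.overlaps(*on_target_locus):
                    h.is_on_target = True
                    break
        else:
            best = min(
                hits,
                key=lambda h: (h.total_mismatches, h.core_mismatches(cfg), h.chrom, h.start),
            )
            best.is_on_target = True
    if include_on_target:
        return hits
    return [h for h in hits if not h.is_on_target]


def _protospacer_of(candidate: CandidateSite | str) -> str:
    proto = candidate.protospacer if isinstance(candidate, CandidateSite) else candidate
    proto = proto.upper()
    if set(proto) - set("ACGT"):
        raise ValueError("candidate protospacer must be pure ACGT")
    return proto


def search_off_targets(
    candidate: CandidateSite | str,
    genome_or_index: Mapping[str, str] | SeedIndex,
    cfg: PatternConfig,
    on_target_locus: tuple[str, int, int] | None = None,
    include_on_target: bool = False,
) -> list[OffTargetHit]:
    """Seed-and-verify enumeration of genomic sites matching *candidate*.

    The presumed on-target hit (the one overlapping *on_target_locus* when
    given, otherwise the single best alignment: fewest total mismatches,
    then fewest core mismatches, then lowest (chrom, start)) is flagged
    ``is_on_target`` and, unless *include_on_target*, removed from the
    returned list. Hits are sorted by (chrom, start).
    """
    proto = _protospacer_of(candidate)
    if len(proto) != cfg.protospacer_length:
        raise ValueError("protospacer length does not match configuration")
    index = (
        genome_or_index
        if isinstance(genome_or_index, SeedIndex)
        else SeedIndex(genome_or_index, cfg)
    )
    pam_len = len(cfg.offtarget_pam)
    site_len = cfg.protospacer_length + pam_len
    seen: set[tuple[str, str, int]] = set()
    hits: list[OffTargetHit] = []
    for seg_offset, seg_len in core_segments(cfg):
        seg = proto[seg_offset : seg_offset + seg_len]
        for chrom, strand, pos in index.lookup(seg_len, seg):
            window = pos - seg_offset
            key = (chrom, strand, window)
            if key in seen:
                continue
            seen.add(key)
            oseq = index.oriented[(chrom, strand)]
            verdict = _verify_window(proto, oseq, window, cfg)
            if verdict is None:
                continue
            mismatches, proto_g, pam_g = verdict
            start, end = _forward_interval(strand, window, site_len, len(oseq))
            hits.append(
                OffTargetHit(chrom, start, end, strand, proto_g, pam_g, mismatches)
            )
    return _finalize(hits, cfg, on_target_locus, include_on_target)


def brute_force_search(
    candidate: CandidateSite | str,
    genome: Mapping[str, str],
    cfg: PatternConfig,
    on_target_locus: tuple[str, int, int] | None = None,
    include_on_target: bool = False,
) -> list[OffTargetHit]:
    """Full window scan with no index; same contract as :func:`search_off_targets`."""
    proto = _protospacer_of(candidate)
    if len(proto) != cfg.protospacer_length:
        raise ValueError("protospacer length does not match configuration")
    length = cfg.protospacer_length
    pam_len = len(cfg.offtarget_pam)
    site_len = length + pam_len
    proto_codes = encode(proto)
    pam_tables = pam_code_table(cfg.offtarget_pam)
    core_start = length - cfg.core_length
    hits: list[OffTargetHit] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom]).upper()
        for strand, oseq in (("+", seq), ("-", revcomp(seq))):
            n_win = len(oseq) - site_len + 1
            if n_win <= 0:
                continue
            codes = encode(oseq)
            total_mm = np.zeros(n_win, dtype=np.int16)
            core_mm = np.zeros(n_win, dtype=np.int16)
            for i in range(length):
                diff = codes[i : i + n_win] != proto_codes[i]
                total_mm += diff
                if i >= core_start:
                    core_mm += diff
            pam_ok = np.ones(n_win, dtype=bool)
            for j, table in enumerate(pam_tables):
                pam_ok &= table[codes[length + j : length + j + n_win]]
            keep = (
                (total_mm <= cfg.max_total_mismatches)
                & (core_mm <= cfg.max_core_mismatches)
                & pam_ok
            )
            for w in np.flatnonzero(keep):
                w = int(w)
                proto_g = oseq[w : w + length]
                pam_g = oseq[w + length : w + site_len]
                start, end = _forward_interval(strand, w, site_len, len(oseq))
                hits.append(
                    OffTargetHit(
                        chrom, start, end, strand, proto_g, pam_g,
                        frozenset(count_mismatches(proto, proto_g)),
                    )
                )
    return _finalize(hits, cfg, on_target_locus, include_on_target)
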