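"""Candidate target-site discovery: scan a query sequence on both strands.

Every window whose PAM matches the discovery motif and whose protospacer
satisfies the configured 5'/3' dinucleotide constraints is reported;
overlapping and nested sites are all kept. Coordinates are 0-based
half-open on the query's forward strand regardless of site strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PatternConfig
from .sequence import IUPAC_CODES, iupac_match, revcomp

__all__ = ["CandidateSite", "find_candidate_sites"]


@dataclass
class CandidateSite:
    """One sgRNA target site found in the query.

    ``protospacer`` and ``pam`` are given 5'->3' on the strand carrying the
    PAM; ``query_start``/``query_end`` span protospacer+PAM on the query's
    forward strand.
    """

    query_start: int
    query_end: int
    strand: str
    protospacer: str
    pam: str
    site_id: str | None = field(default=None)

    @property
    def sequence(self) -> str:
        return self.protospacer + self.pam


def _passes_constraints(protospacer: str, cfg: PatternConfig) -> bool:
    if cfg.five_prime_constraint == "GN" and not protospacer.startswith("G"):
        return False
    if cfg.five_prime_constraint == "GG" and not protospacer.startswith("GG"):
        return False
    if cfg.three_prime_constraint == "GG" and not protospacer.endswith("GG"):
        return False
    return True


def _scan_strand(seq: str, cfg: PatternConfig):
    """Yield (offset_in_seq, protospacer, pam) for matches on one oriented sequence."""
    length, pam_motif = cfg.protospacer_length, cfg.discovery_pam
    site_len = length + len(pam_motif)
    acgt = frozenset("ACGT")
    for i in range(len(seq) - site_len + 1):
        proto = seq[i : i + length]
        if not acgt.issuperset(proto):
            continue
        pam = seq[i + length : i + site_len]
        if not all(iupac_match(p, g) for p, g in zip(pam_motif, pam)):
            continue
        if _passes_constraints(proto, cfg):
            yield i, proto, pam


def find_candidate_sites(query: str, cfg: PatternConfig) -> list[CandidateSite]:
    """Find all candidate sites in *query* on both strands.

    Raises ``ValueError`` on non-IUPAC query characters. A query shorter
    than one site yields an empty list.
    """
    q = query.strip().upper()
    bad = set(q) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"query contains non-IUPAC characters: {sorted(bad)}")
    n = len(q)
    site_len = cfg.site_length
    sites: list[CandidateSite] = []
    for i, proto, pam in _scan_strand(q, cfg):
        sites.append(CandidateSite(i, i + site_len, "+", proto, pam))
    rc = revcomp(q)
    for j, proto, pam in _scan_strand(rc, cfg):
        start = n - (j + site_len)
        sites.append(CandidateSite(start, start + site_len, "-", proto, pam))
    sites.sort(key=lambda s: (s.query_start, 0 if s.strand == "+" else 1))
    return sites
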