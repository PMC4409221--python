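"""Nucleotide sequence primitives: IUPAC semantics, reverse complement, encoding.

All comparison in this package is case-insensitive; sequences are normalized
to upper case at the boundaries. Genome characters outside A/C/G/T (masked
``N`` runs, ambiguity codes) are treated as indeterminate: they never match
any pattern base and always count as mismatches.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "complement",
    "revcomp",
    "iupac_match",
    "encode",
    "pam_code_table",
]

#: IUPAC degenerate nucleotide codes mapped to the set of concrete bases matched.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def complement(seq: str) -> str:
    """Base-wise complement, preserving case and IUPAC degeneracy."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case and IUPAC degeneracy."""
    return complement(seq)[::-1]


def iupac_match(pattern_base: str, genome_base: str) -> bool:
    """True if *genome_base* is one of the concrete bases allowed by *pattern_base*.

    Genome characters outside A/C/G/T never match, including against pattern
    ``N``: an indeterminate genome base cannot be asserted to satisfy any
    pattern position.
    """
    p = pattern_base.upper()
    try:
        allowed = IUPAC_CODES[p]
    except KeyError:
        raise ValueError(f"unknown IUPAC pattern code: {pattern_base!r}") from None
    g = genome_base.upper()
    return g in "ACGT" and g in allowed


# uint8 encoding: A=0 C=1 G=2 T=3, everything else 4 (never matches ACGT codes)
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def pam_code_table(pam_motif: str) -> list[np.ndarray]:
    """Per-position boolean lookup tables (indexed by base code 0..4) for a PAM motif."""
    tables = []
    for letter in pam_motif.upper():
        allowed = IUPAC_CODES[letter]
        table = np.zeros(5, dtype=bool)
        for base in allowed:
            table["ACGT".index(base)] = True
        tables.append(table)
    return tables
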