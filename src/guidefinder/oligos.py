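"""Cloning oligo pairs for golden-gate insertion into the DR274 sgRNA vector.

T7 transcription needs the guide to start with GG. When the protospacer does
not, the 5' end is fixed either by *extension* (prepending one or two ``g``)
or *substitution* (overwriting the first base(s) with ``g``); added or
substituted bases are written lowercase in the forward oligo, exactly as
ordered. Annealed pairs leave the 4-nt 5' overhangs TAGG / AAAC expected by
the BsaI-cut vector.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence import revcomp

__all__ = ["OligoPair", "design_oligos"]


@dataclass(frozen=True)
class OligoPair:
    forward: str
    reverse: str
    modification: str  # "none" | "extended" | "substituted"
    fixed_protospacer: str  # the sequence actually transcribed; lowercase marks changes


def design_oligos(protospacer: str, mode: str = "extension") -> OligoPair:
    """Design the annealing oligo pair for one protospacer.

    GG-fixing rules: a protospacer already starting GG is used unchanged;
    one starting with a single G gets one ``g`` (prepended in extension
    mode, substituted for base 2 otherwise); any other start gets ``gg``.
    """
    if mode not in ("extension", "substitution"):
        raise ValueError(f"mode must be 'extension' or 'substitution', got {mode!r}")
    p = protospacer.upper()
    if not p or set(p) - set("ACGT"):
        raise ValueError("protospacer must be non-empty pure ACGT")

    if p.startswith("GG"):
        fixed, modification = p, "none"
    elif p.startswith("G"):
        if mode == "extension":
            fixed, modification = "g" + p, "extended"
        else:
            fixed, modification = p[0] + "g" + p[2:], "substituted"
    else:
        if mode == "extension":
            fixed, modification = "gg" + p, "extended"
        else:
            fixed, modification = "gg" + p[2:], "substituted"

    forward = "TA" + fixed
    reverse = "AAAC" + revcomp(fixed[2:]).upper()
    return OligoPair(forward, reverse, modification, fixed)
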