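"""Run configuration: the target-site pattern grammar and all tunable parameters.

A pattern string such as ``"N20NGG"`` compactly describes the protospacer
(one IUPAC code repeated *n* times) followed by the PAM motif. The full
:class:`PatternConfig` additionally carries the off-target search ceilings,
5'/3' dinucleotide constraints, exon assignment radius and scoring base.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path

import yaml

from .sequence import IUPAC_CODES

__all__ = ["PatternConfig", "parse_pattern", "render_pattern", "load_config_file"]

_ALLOWED_PAMS = ("NGG", "NRG")
_FIVE_PRIME = ("NN", "GN", "GG")
_THREE_PRIME = ("NN", "GG")
_GG_MODES = ("extension", "substitution")

_PATTERN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z]+)$")


class PatternError(ValueError):
    """Raised for malformed pattern strings or invalid configuration values."""


def parse_pattern(pattern: str) -> tuple[int, str]:
    """Parse a pattern string like ``"N20NGG"`` into (protospacer_length, pam_motif).

    The grammar is ``<IUPAC code><count><PAM motif>``; every letter must be a
    valid IUPAC nucleotide code.

    >>> parse_pattern("N20NGG")
    (20, 'NGG')
    """
    m = _PATTERN_RE.match(pattern.strip())
    if not m:
        raise PatternError(f"malformed pattern {pattern!r}: expected <code><count><PAM>")
    code, count, pam = m.group(1).upper(), m.group(2), m.group(3).upper()
    if code not in IUPAC_CODES:
        raise PatternError(f"malformed pattern {pattern!r}: {code!r} is not an IUPAC code")
    for letter in pam:
        if letter not in IUPAC_CODES:
            raise PatternError(
                f"malformed pattern {pattern!r}: PAM letter {letter!r} is not an IUPAC code"
            )
    length = int(count)
    if length <= 0:
        raise PatternError(f"malformed pattern {pattern!r}: length must be positive")
    return length, pam


def render_pattern(cfg: "PatternConfig") -> str:
    """Inverse of :func:`parse_pattern` for the discovery pattern."""
    return f"N{cfg.protospacer_length}{cfg.discovery_pam}"


@dataclass(frozen=True)
class PatternConfig:
    """All user-tunable parameters of a run.

    ``discovery_pam`` constrains candidate sites found in the query;
    ``offtarget_pam`` (independently selectable) constrains genomic
    off-target sites. The core is the PAM-proximal ``core_length`` bases
    of the protospacer.
    """

    protospacer_length: int = 20
    discovery_pam: str = "NGG"
    offtarget_pam: str = "NGG"
    five_prime_constraint: str = "NN"
    three_prime_constraint: str = "NN"
    core_length: int = 12
    max_core_mismatches: int = 2
    max_total_mismatches: int = 4
    exon_assignment_radius: int = 100_000
    score_base: float = 1.2
    oligo_gg_mode: str = "extension"

    def __post_init__(self) -> None:
        if self.discovery_pam not in _ALLOWED_PAMS:
            raise PatternError(f"discovery_pam must be one of {_ALLOWED_PAMS}")
        if self.offtarget_pam not in _ALLOWED_PAMS:
            raise PatternError(f"offtarget_pam must be one of {_ALLOWED_PAMS}")
        if self.five_prime_constraint not in _FIVE_PRIME:
            raise PatternError(f"five_prime_constraint must be one of {_FIVE_PRIME}")
        if self.three_prime_constraint not in _THREE_PRIME:
            raise PatternError(f"three_prime_constraint must be one of {_THREE_PRIME}")
        if self.oligo_gg_mode not in _GG_MODES:
            raise PatternError(f"oligo_gg_mode must be one of {_GG_MODES}")
        if self.protospacer_length <= 0:
            raise PatternError("protospacer_length must be positive")
        if not (0 < self.core_length <= self.protospacer_length):
            raise PatternError("require 0 < core_length <= protospacer_length")
        if not (0 <= self.max_core_mismatches <= self.max_total_mismatches):
            raise PatternError("require 0 <= max_core_mismatches <= max_total_mismatches")
        if not self.score_base > 1:
            raise PatternError("score_base must be > 1")
        if self.exon_assignment_radius <= 0:
            raise PatternError("exon_assignment_radius must be positive")

    @property
    def pam_length(self) -> int:
        return len(self.discovery_pam)

    @property
    def site_length(self) -> int:
        """Protospacer plus PAM."""
        return self.protospacer_length + len(self.discovery_pam)

    def replace(self, **changes) -> "PatternConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_pattern(cls, pattern: str, **overrides) -> "PatternConfig":
        length, pam = parse_pattern(pattern)
        return cls(protospacer_length=length, discovery_pam=pam, **overrides)

    @classmethod
    def from_sources(cls, config_file: str | Path | None = None, **cli_overrides) -> "PatternConfig":
        """Build a config from an optional key-value file plus CLI overrides.

        CLI values win over file values; unset fields fall back to defaults.
        """
        values: dict = {}
        if config_file is not None:
            values.update(load_config_file(config_file))
        values.update({k: v for k, v in cli_overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise PatternError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**values)


def load_config_file(path: str | Path) -> dict:
    """Load a flat key-value (YAML) config file mirroring PatternConfig fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PatternError(f"config file {path} must contain a flat key-value mapping")
    return data
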