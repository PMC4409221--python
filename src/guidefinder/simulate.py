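"""Deterministic synthetic genomes with planted target/off-target sites.

Backgrounds are uniform-random ACGT from a seeded generator; each plant
writes a protospacer copy carrying exactly the requested substitutions
(every substituted base differs from the original) followed by its PAM, on
either strand. A truth table records the expected hit geometry, and exon
intervals are placed at requested gaps from the planted sites. Background
stretches that happen to create unintended near-matches of a planted
protospacer are re-randomized (rejection sampling), so the truth table is
exhaustive for the screening configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import ExonRecord
from .config import PatternConfig
from .offtargets import brute_force_search
from .sequence import revcomp

__all__ = ["PlantSpec", "SyntheticGenome", "make_synthetic_genome"]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantSpec:
    """One site to plant: a mutated copy of *base_protospacer* plus *pam*."""

    base_protospacer: str
    mismatch_positions: frozenset[int] = frozenset()
    pam: str = "TGG"
    strand: str = "+"
    chrom: str = "chr1"
    offset: int = 0
    nearest_exon_gap: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mismatch_positions", frozenset(self.mismatch_positions))
        if set(self.base_protospacer.upper()) - set(_BASES):
            raise ValueError("base_protospacer must be pure ACGT")
        bad = [p for p in self.mismatch_positions if not 1 <= p <= len(self.base_protospacer)]
        if bad:
            raise ValueError(f"mismatch positions out of range: {sorted(bad)}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def site_length(self) -> int:
        return len(self.base_protospacer) + len(self.pam)


@dataclass
class SyntheticGenome:
    """Generated genome + exons + per-plant truth rows."""

    seed: int
    genome: dict[str, str]
    truth: list[dict]
    exons: list[ExonRecord]

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.genome):
                fh.write(f">{name}\n")
                seq = self.genome[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_exon_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.exons:
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t"
                    f"{rec.gene_name}|{rec.gene_id}\t0\t{rec.strand}\n"
                )

    def write_truth_tsv(self, path: str | Path) -> None:
        cols = [
            "plant", "chrom", "start", "end", "strand", "base_protospacer",
            "site_sequence", "pam", "mismatch_positions", "nearest_exon_gap",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.truth:
                mm = ",".join(str(p) for p in sorted(row["mismatch_positions"])) or "-"
                gap = "NA" if row["nearest_exon_gap"] is None else str(row["nearest_exon_gap"])
                fh.write(
                    f"{row['plant']}\t{row['chrom']}\t{row['start']}\t{row['end']}\t"
                    f"{row['strand']}\t{row['base_protospacer']}\t{row['site_sequence']}\t"
                    f"{row['pam']}\t{mm}\t{gap}\n"
                )


def _mutate(proto: str, positions: frozenset[int], rng: np.random.Generator) -> str:
    out = list(proto)
    for p in sorted(positions):
        original = out[p - 1]
        alternatives = [b for b in _BASES if b != original]
        out[p - 1] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def make_synthetic_genome(
    seed: int,
    n_chroms: int = 1,
    chrom_length: int = 5000,
    plants: Sequence[PlantSpec] = (),
    screen_cfg: PatternConfig | None = None,
    exon_length: int = 100,
    max_fix_rounds: int = 50,
) -> SyntheticGenome:
    """Generate a reproducible genome with the requested plants.

    *screen_cfg* defines the constraint set used to purge accidental
    background matches of any planted protospacer (default: standard
    parameters with the permissive NRG off-target PAM). Overlapping or
    out-of-bounds plants raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    chroms: dict[str, np.ndarray] = {
        name: rng.integers(0, 4, size=chrom_length) for name in names
    }

    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    for plant in plants:
        if plant.chrom not in chroms:
            raise ValueError(f"unknown chromosome {plant.chrom!r}")
        lo, hi = plant.offset, plant.offset + plant.site_length
        if lo < 0 or hi > chrom_length:
            raise ValueError(f"plant at {plant.chrom}:{lo}-{hi} exceeds chromosome bounds")
        for a, b in occupied[plant.chrom]:
            if lo < b and a < hi:
                raise ValueError(f"overlapping plants on {plant.chrom} at [{lo}, {hi})")
        occupied[plant.chrom].append((lo, hi))

    truth: list[dict] = []
    exons: list[ExonRecord] = []
    for i, plant in enumerate(plants):
        proto = plant.base_protospacer.upper()
        mutated = _mutate(proto, plant.mismatch_positions, rng)
        site = mutated + plant.pam.upper()
        written = site if plant.strand == "+" else revcomp(site)
        arr = chroms[plant.chrom]
        codes = [("ACGT".index(b)) for b in written]
        arr[plant.offset : plant.offset + len(written)] = codes
        start, end = plant.offset, plant.offset + len(written)
        truth.append(
            {
                "plant": i,
                "chrom": plant.chrom,
                "start": start,
                "end": end,
                "strand": plant.strand,
                "base_protospacer": proto,
                "site_sequence": mutated,
                "pam": plant.pam.upper(),
                "mismatch_positions": frozenset(plant.mismatch_positions),
                "nearest_exon_gap": plant.nearest_exon_gap,
            }
        )
        if plant.nearest_exon_gap is not None:
            gap = plant.nearest_exon_gap
            if gap == 0:
                ex_start = max(0, start - 5)
                ex_end = min(chrom_length, end + 5)
            elif end + gap + exon_length <= chrom_length:
                ex_start, ex_end = end + gap, end + gap + exon_length
            elif start - gap - exon_length >= 0:
                ex_start, ex_end = start - gap - exon_length, start - gap
            else:
                raise ValueError(f"no room for an exon at gap {gap} from plant {i}")
            exons.append(
                ExonRecord(plant.chrom, ex_start, ex_end, f"gene{i + 1}", f"G{i + 1:03d}")
            )

    genome = {name: "".join(_BASES[c] for c in chroms[name]) for name in names}

    # Rejection sampling: purge background windows that accidentally satisfy
    # the screening constraints for any planted protospacer.
    cfg = screen_cfg or PatternConfig(offtarget_pam="NRG")
    expected = {
        (row["base_protospacer"], row["chrom"], row["start"], row["strand"])
        for row in truth
    }
    protospacers = sorted({row["base_protospacer"] for row in truth})
    for _ in range(max_fix_rounds):
        spurious: list = []
        for proto in protospacers:
            if len(proto) != cfg.protospacer_length:
                continue
            for hit in brute_force_search(proto, genome, cfg, include_on_target=True):
                if (proto, hit.chrom, hit.start, hit.strand) not in expected:
                    spurious.append(hit)
        if not spurious:
            break
        for hit in spurious:
            arr = chroms[hit.chrom]
            plant_spans = occupied[hit.chrom]
            for pos in range(hit.start, hit.end):
                if any(a <= pos < b for a, b in plant_spans):
                    continue
                arr[pos] = int(rng.integers(0, 4))
        genome = {name: "".join(_BASES[c] for c in chroms[name]) for name in names}
    else:
        raise RuntimeError("could not purge accidental off-target matches")

    return SyntheticGenome(seed=seed, genome=genome, truth=truth, exons=exons)
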