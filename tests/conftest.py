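import numpy as np
import pytest

from guidefinder import PatternConfig, PlantSpec, make_synthetic_genome

BASES = "ACGT"


@pytest.fixture
def default_cfg():
    return PatternConfig()


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_genome(rng: np.random.Generator, n_chroms: int, length: int) -> dict:
    return {f"chr{i + 1}": random_sequence(rng, length) for i in range(n_chroms)}


def derive_candidate(rng: np.random.Generator, genome: dict, cfg: PatternConfig) -> str:
    """Extract a random genomic 20-mer and mutate <= max_total positions.

    Guarantees at least one near-perfect genomic match so oracle-equivalence
    tests exercise non-empty hit sets.
    """
    chrom = sorted(genome)[int(rng.integers(0, len(genome)))]
    seq = genome[chrom]
    length = cfg.protospacer_length
    pos = int(rng.integers(0, len(seq) - length))
    proto = list(seq[pos : pos + length])
    n_mut = int(rng.integers(0, cfg.max_total_mismatches + 1))
    for p in rng.choice(length, size=n_mut, replace=False):
        alternatives = [b for b in BASES if b != proto[p]]
        proto[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(proto)


PROTO = "GGCGAGGGCGATGCCACCTA"  # printed sgRNA-1 protospacer, reused as plant base


@pytest.fixture(scope="session")
def planted_instance():
    """Synthetic genome with plants spanning the constraint truth table."""
    plants = [
        PlantSpec(PROTO, frozenset(), "CGG", "+", "chr1", 100, nearest_exon_gap=0),
        PlantSpec(PROTO, frozenset({1, 2, 9, 10}), "TGG", "-", "chr1", 900, nearest_exon_gap=300),
        PlantSpec(PROTO, frozenset({10, 11, 12, 13}), "AGG", "+", "chr1", 1700),
        PlantSpec(PROTO, frozenset({3}), "TAG", "+", "chr1", 2500),
        PlantSpec(PROTO, frozenset({1, 2, 3, 4, 5}), "CGG", "+", "chr1", 3300),
    ]
    return make_synthetic_genome(seed=2, n_chroms=1, chrom_length=4200, plants=plants)
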