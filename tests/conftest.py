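import numpy as np
import pytest

from paralocus import (
    MapParams,
    SimParams,
    build_haplotype,
    generate_block,
    inject_allelic_snps,
    revcomp,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def brute_force_hits(read: str, references: list[tuple[str, str]], max_mm: int):
    """Exhaustive ungapped scan: every (ref_id, start, strand, mismatches)
    placement with <= max_mm substitutions, sorted like the mapper sorts."""
    hits = []
    L = len(read)
    for strand, query in (("+", read), ("-", revcomp(read))):
        for rid, seq in references:
            for start in range(len(seq) - L + 1):
                mm = sum(1 for a, b in zip(seq[start : start + L], query) if a != b)
                if mm <= max_mm:
                    hits.append((rid, start, strand, mm))
    return sorted(hits, key=lambda h: (h[3], h[0], h[1], h[2]))


@pytest.fixture(scope="session")
def small_block():
    """One 8-kb ancestral block with 2 genes in 2 groups."""
    return generate_block(8000, 2, ["groupA", "groupB"], seed=11)


@pytest.fixture(scope="session")
def duplicated_haplotype(small_block):
    """Two copies of the block at 2% divergence: 4 genes, 2 paralog groups."""
    return build_haplotype(small_block, 2, 0.02, seed=12)


@pytest.fixture(scope="session")
def allelic_haplotype(duplicated_haplotype):
    return inject_allelic_snps(duplicated_haplotype, 200, seed=13)


@pytest.fixture
def map_params():
    return MapParams(k=11, max_mismatches=2)


@pytest.fixture
def sim_params():
    return SimParams(seed=7)
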