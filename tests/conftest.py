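import numpy as np
import pytest

from majoref import Genome, SimConfig, SwapSite, SwapTable, build_fixture

BASES = "ACGT"


def random_genome(rng: np.random.Generator, n_chroms=2, length=200) -> Genome:
    seqs = {}
    for i in range(n_chroms):
        chars = rng.choice(list(BASES), size=length)
        # sprinkle soft-masking and the occasional N
        lower = rng.random(length) < 0.2
        seq = [c.lower() if lo else c for c, lo in zip(chars, lower)]
        for j in np.flatnonzero(rng.random(length) < 0.02):
            seq[j] = "N"
        seqs[f"chr{i + 1}"] = "".join(seq)
    return Genome(seqs)


def random_swap_table(rng: np.random.Generator, genome: Genome, max_sites=30) -> SwapTable:
    """A swap table consistent with the genome (skipping N bases)."""
    table = SwapTable(chrom_order=genome.names)
    for chrom in genome.names:
        seq = genome[chrom]
        n = int(rng.integers(0, max_sites + 1))
        positions = rng.choice(len(seq), size=min(n, len(seq)), replace=False)
        for pos0 in sorted(int(p) for p in positions):
            base = seq[pos0].upper()
            if base == "N":
                continue
            major = str(rng.choice([b for b in BASES if b != base]))
            table.add(
                SwapSite(
                    chrom=chrom,
                    pos=pos0 + 1,
                    base_allele=base,
                    major_allele=major,
                    major_af=round(float(rng.uniform(0.5 + 1e-6, 1.0)), 6),
                )
            )
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture():
    """A small in-memory cohort shared by read-only tests."""
    cfg = SimConfig(
        n_chroms=2, chrom_length=4000, n_sites=150, n_individuals=6, seed=123
    )
    return build_fixture(cfg)
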