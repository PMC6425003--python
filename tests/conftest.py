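import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fstatkit.eigendata import GenotypeDataset, IndividualRecord, SNPRecord

ALLELES = ("A", "C", "G", "T")


def make_snps(n, chromosomes=("1",), spacing=100_000, genetic=False, rng=None):
    """Evenly spaced SNP records across the given chromosomes."""
    per = n // len(chromosomes)
    extra = n % len(chromosomes)
    snps = []
    i = 0
    rng = rng or np.random.default_rng(0)
    for c, chrom in enumerate(chromosomes):
        count = per + (1 if c < extra else 0)
        for j in range(count):
            pos = (j + 1) * spacing
            ref, alt = rng.choice(4, size=2, replace=False)
            snps.append(
                SNPRecord(
                    snp_id=f"rs{i}",
                    chromosome=chrom,
                    genetic_position=pos * 1e-8 if genetic else 0.0,
                    physical_position=pos,
                    ref_allele=ALLELES[ref],
                    alt_allele=ALLELES[alt],
                )
            )
            i += 1
    return snps


def random_dataset(
    rng,
    n_snps=200,
    pops=("A", "B"),
    n_per_pop=3,
    missing_rate=0.1,
    pseudo_haploid=(),
    chromosomes=("1", "2"),
):
    """Random genotype dataset with structured frequencies per population."""
    snps = make_snps(n_snps, chromosomes=chromosomes, rng=rng)
    individuals = []
    ph = []
    cols = []
    for pop in pops:
        p = rng.uniform(0.05, 0.95, size=n_snps)
        for k in range(n_per_pop):
            is_ph = pop in pseudo_haploid
            g = rng.binomial(2, p).astype(np.int8)
            if is_ph:
                het = g == 1
                g[het] = 2 * rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
            if missing_rate > 0:
                g[rng.random(n_snps) < missing_rate] = -1
            cols.append(g)
            ph.append(is_ph)
            individuals.append(
                IndividualRecord(f"{pop}{k}", "U", pop)
            )
    return GenotypeDataset(snps, individuals, np.column_stack(cols), np.array(ph))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng, n_snps=300, pops=("A", "B", "C", "D"), n_per_pop=4)
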