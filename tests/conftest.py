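import numpy as np
import pytest

from recwas.io import GenotypeMatrix, VariantRecord
from recwas.simulate import CohortSpec, VariantSpec, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_geno():
    """4 individuals x 3 variants, hand-written phased haplotypes."""
    variants = [
        VariantRecord("1", 100, "A", "C", gene="G1"),
        VariantRecord("1", 200, "G", "T", gene="G1"),
        VariantRecord("2", 300, "T", "A", gene="G2"),
    ]
    haps = np.array([
        [[0, 1], [1, 0], [0, 0]],
        [[1, 1], [0, 0], [0, 1]],
        [[0, 0], [0, 0], [1, 1]],
        [[0, 1], [0, 1], [-1, -1]],
    ], dtype=np.int8)
    return GenotypeMatrix(variants=variants, haplotypes=haps,
                          phased=np.array([True, True, True, False]),
                          sample_ids=["I0", "I1", "I2", "I3"])


@pytest.fixture
def small_cohort():
    """600-individual simulated cohort, 4 variants in 2 genes."""
    spec = CohortSpec(
        n_individuals=600,
        variants=[
            VariantSpec(maf=0.10, chrom="1", pos=1_000_000, gene="GENE1",
                        clinical_category="likely_pathogenic"),
            VariantSpec(maf=0.08, chrom="1", pos=1_200_000, gene="GENE1",
                        clinical_category="likely_pathogenic"),
            VariantSpec(maf=0.15, chrom="2", pos=5_000_000, gene="GENE2",
                        clinical_category="likely_pathogenic"),
            VariantSpec(maf=0.20, chrom="2", pos=5_100_000, gene="GENE2"),
        ],
        inbreeding=0.02, seed=7)
    return simulate_genotypes(spec)
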