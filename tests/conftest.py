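import numpy as np
import pytest

from paleogen.datamodel_io import GenotypePanel, Individual, SNPRecord
from paleogen.synthetic_data import DemographyGraph


def make_snp(i=0, chrom="1", pos=None, ref="C", alt="T", anc=None, tags=()):
    return SNPRecord(
        f"snp{i}", chrom, pos if pos is not None else 100 * (i + 1), ref, alt,
        ancestral_allele=anc, ascertainment_tags=frozenset(tags),
    )


@pytest.fixture
def small_panel():
    """3 individuals x 4 SNPs covering both ploidies and missingness."""
    snps = [
        make_snp(0, pos=100, ref="C", alt="T", anc="C"),
        make_snp(1, pos=200, ref="G", alt="A", anc="A"),
        make_snp(2, pos=300, ref="A", alt="C", anc="A"),
        make_snp(3, chrom="2", pos=100, ref="T", alt="G", anc="T", tags=("YRI",)),
    ]
    individuals = [
        Individual("mod1", "POP1", "modern", 2),
        Individual("mod2", "POP2", "modern", 2),
        Individual("anc1", "ANC", "ancient", 1),
    ]
    genotypes = np.array(
        [[0, 1, 2, -1],
         [2, 0, 1, 1],
         [1, 0, -1, 1]], dtype=np.int8,
    )
    return GenotypePanel(snps, individuals, genotypes)


@pytest.fixture
def two_pop_graph():
    return DemographyGraph.from_dict({
        "root": {"name": "R"},
        "edges": [
            {"child": "A", "parent": "R", "F": 0.2},
            {"child": "B", "parent": "R", "F": 0.2},
        ],
        "samples": [
            {"population": "A", "n": 10},
            {"population": "B", "n": 10},
        ],
    })


def random_panel(rng, n_ind=3, n_snp=5, haploid_rows=()):
    """Random valid panel for roundtrip property tests."""
    snps = []
    pairs = [("A", "C"), ("C", "T"), ("G", "A"), ("T", "G")]
    pos = 0
    for m in range(n_snp):
        pos += int(rng.integers(1, 1000))
        ref, alt = pairs[int(rng.integers(len(pairs)))]
        anc = [None, ref, alt][int(rng.integers(3))]
        snps.append(SNPRecord(f"s{m}", "1", pos, ref, alt, ancestral_allele=anc))
    individuals = []
    g = np.empty((n_ind, n_snp), dtype=np.int8)
    for i in range(n_ind):
        ploidy = 1 if i in haploid_rows else 2
        individuals.append(Individual(f"i{i}", f"P{i % 2}", "modern", ploidy))
        g[i] = rng.integers(-1, ploidy + 1, size=n_snp)
    return GenotypePanel(snps, individuals, g)
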