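import pytest

from hlaquant import build_kmer_index, parse_allele_fasta, simulate_allele_db

TOY_FASTA = """\
>A*01:01:01:01
ACGTACGTACGTAAGGCTTACCGGATACGATCGGCTAGCTAGGATCCAGT
ACCGGTTTACGATCGATCGGATTACGATCGGCTAACGGTATCGATCAGGT
>HLA-A*02:01
ACGTACGTACGTAAGGCTTACCGGATACGATCGGCTAGCTAGGATCCAGT
ACCGGTTTACGATCGATCGGATTACGATCGGCTAACGGTATCGATCAGAA
>HLA:HLA00132 B*07:02:01 100 bp
TTGTACGTACGTAAGGCTTACCGGATACGATCGGCTAGCTAGGATCCAGT
ACCGGTTTACGATCGATCGGATTACGATCGGCTAACGGTATCGATCAGGT
"""


@pytest.fixture
def toy_db():
    """Three-allele reference exercising all header dialects."""
    return parse_allele_fasta(TOY_FASTA)


@pytest.fixture
def sim_db():
    """Small indexed simulated reference: 2 class I loci, 4 alleles each."""
    db = simulate_allele_db(
        ["A", "G"],
        alleles_per_locus=4,
        allele_length=500,
        within_locus_divergence=0.03,
        between_locus_divergence=0.15,
        seed=42,
    )
    return build_kmer_index(db, k=16)
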