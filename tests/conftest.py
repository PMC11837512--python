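import pytest

from bestop import load_annotation, load_genome
from bestop.synthetic import make_genome


@pytest.fixture(scope="session")
def fixture_genome():
    """A small planted genome shared by read-only tests."""
    fasta, gff, manifest = make_genome(8, seed=3)
    genome = load_genome(fasta)
    genes = load_annotation(gff, genome)
    return fasta, gff, manifest, genome, genes


@pytest.fixture(scope="session")
def multi_contig_genome():
    fasta, gff, manifest = make_genome(9, seed=11, n_contigs=3)
    genome = load_genome(fasta)
    genes = load_annotation(gff, genome)
    return fasta, gff, manifest, genome, genes
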