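import pytest

from taledesign.fixtures import FixtureSpec, Plant, make_synthetic_genome
from taledesign.preference import default_preference_matrix
from taledesign.reference import DTALE1_EBE


@pytest.fixture(scope="session")
def dtale1():
    return DTALE1_EBE


@pytest.fixture(scope="session")
def matrix():
    return default_preference_matrix()


@pytest.fixture(scope="session")
def planted_genome(dtale1):
    """10 kb genome with plants at mismatch distances 0, 2, 2, 3 (mixed strands)."""
    spec = FixtureSpec(
        genome_length=10_000,
        plants=(
            Plant(dtale1, 0, strand="+"),
            Plant(dtale1, 2, strand="+"),
            Plant(dtale1, 2, strand="-"),
            Plant(dtale1, 3, strand="-"),
        ),
        rng_seed=42,
    )
    return make_synthetic_genome(spec)


@pytest.fixture
def toy_gff3(tmp_path):
    """Two-exon + strand gene with explicit span 1001..3000 (1-based)."""
    text = (
        "##gff-version 3\n"
        "chr1\ttest\tgene\t1001\t3000\t.\t+\t.\tID=g1\n"
        "chr1\ttest\tmRNA\t1001\t3000\t.\t+\t.\tID=g1.1;Parent=g1\n"
        "chr1\ttest\texon\t1001\t1500\t.\t+\t.\tParent=g1.1\n"
        "chr1\ttest\texon\t2001\t3000\t.\t+\t.\tParent=g1.1\n"
        "chr1\ttest\tCDS\t1201\t1500\t.\t+\t0\tParent=g1.1\n"
        "chr1\ttest\tCDS\t2001\t2800\t.\t+\t0\tParent=g1.1\n"
    )
    path = tmp_path / "toy.gff3"
    path.write_text(text)
    return path
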