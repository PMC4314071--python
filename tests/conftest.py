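import pytest

from yeastprimers import (
    ChromosomeRecord,
    FixtureSpec,
    GenomicFeature,
    generate_synthetic_genome,
    genome_index,
    read_annotation,
    read_fasta,
)

# Hand-checkable toy chromosomes: chr1 carries a plus-strand ORF ATGAAATAG at
# 9-17; chr2 carries the same ORF geometry on the minus strand (sense
# ATGCCCTAA, plus-strand span 9-17).
TOY_CHR1 = "ACGTACGTATGAAATAGTTGGCCAA"
TOY_CHR2 = "ACGTACGTTTAGGGCATTTGGCCAA"


@pytest.fixture(scope="session")
def toy_genome():
    return genome_index(
        [
            ChromosomeRecord("chr1", TOY_CHR1, len(TOY_CHR1)),
            ChromosomeRecord("chr2", TOY_CHR2, len(TOY_CHR2)),
        ]
    )


@pytest.fixture(scope="session")
def toy_cds_plus():
    return GenomicFeature(
        chrom_id="chr1", start=9, end=17, systematic_name="toy1",
        common_name="", strand="+", ftype="CDS",
    )


@pytest.fixture(scope="session")
def toy_cds_minus():
    return GenomicFeature(
        chrom_id="chr2", start=9, end=17, systematic_name="toy2",
        common_name="", strand="-", ftype="CDS",
    )


class SynFixture:
    """A generated genome plus its files and parsed records."""

    def __init__(self, spec, directory):
        self.genome = generate_synthetic_genome(spec)
        self.paths = self.genome.write(directory)
        self.chromosomes = read_fasta(self.paths["fasta"])
        self.index = genome_index(self.chromosomes)
        self.records = read_annotation(self.paths["gff3"])
        self.truth = self.genome.truth


@pytest.fixture(scope="session")
def small_syn(tmp_path_factory):
    spec = FixtureSpec(seed=7, n_features=40)
    return SynFixture(spec, tmp_path_factory.mktemp("small_syn"))


@pytest.fixture(scope="session")
def big_syn(tmp_path_factory):
    spec = FixtureSpec(seed=11, n_features=520)
    return SynFixture(spec, tmp_path_factory.mktemp("big_syn"))
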