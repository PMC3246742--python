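import pytest

from cvitpy import GenomeSpec, generate, load_config, parse_gff, partition


MINIMAL_GFF = (
    "##gff-version 3\n"
    "Gm09\t.\tchromosome\t1\t50000000\t.\t.\t.\tName=Gm09\n"
)


@pytest.fixture
def default_config():
    return load_config()


@pytest.fixture
def minimal_gff_text():
    return MINIMAL_GFF


@pytest.fixture
def small_fixture():
    """A 3-chromosome synthetic genome with recorded ground truth."""
    return generate(GenomeSpec(n_chromosomes=3, genes_per_chromosome=60, n_synteny_blocks=10, seed=11))


@pytest.fixture
def small_collection(small_fixture, default_config):
    records = parse_gff(small_fixture.backbone_gff) + parse_gff(small_fixture.feature_gff)
    return partition(records, default_config)
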