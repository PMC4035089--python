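"""Shared fixtures: one desk-scale synthetic genome pair per session."""

import pytest

from nmcompare import synthetic

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_config():
    return synthetic.GeneratorConfig()


@pytest.fixture(scope="session")
def desk_pair(desk_config):
    """(genome_a, genome_b, families, truth) at the default desk scale."""
    return synthetic.generate_genome_pair(desk_config, DESK_SEED)
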