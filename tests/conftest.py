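import numpy as np
import pytest
from hypothesis import settings

from sdlocus import homology, synth
from sdlocus.core import SpeciesTree, load_table1_fixture

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tree():
    return SpeciesTree.default()


@pytest.fixture(scope="session")
def fixture_data():
    """(LocusMap, CharacterMatrix) from the packaged published table."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def human_arch():
    """Human-like SD architecture realized once: blueprint, sequence,
    truth, self-alignment records and merged blocks."""
    blueprint = synth.human_sd_blueprint(seed=7)
    seq, truth = synth.build_ancestral_locus(blueprint, np.random.default_rng(7))
    records = homology.anchor_align(
        seq, seq, qname=blueprint.name, tname=blueprint.name
    )
    blocks = homology.merge_to_blocks(records)
    return blueprint, seq, truth, records, blocks


def match_planted_block(blocks, pair):
    """The recovered block matching a planted SD pair, or None."""
    hits = [
        b
        for b in blocks
        if (
            b.a.overlap_len(pair.source) > 0.5 * pair.source.length()
            and b.b.overlap_len(pair.copy) > 0.5 * pair.copy.length()
        )
        or (
            b.b.overlap_len(pair.source) > 0.5 * pair.source.length()
            and b.a.overlap_len(pair.copy) > 0.5 * pair.copy.length()
        )
    ]
    return max(hits, key=lambda b: b.length) if hits else None
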