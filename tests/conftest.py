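"""Shared fixtures: the standard probe set is expensive to build, so it is
session-scoped; everything else is generated fresh and seeded."""

import numpy as np
import pytest

from specmosaic import build_match_lookup, generate_vocabulary


@pytest.fixture(scope="session")
def std_vocab():
    """Standard probe set: L=10, min pairwise distance 6 (256 words)."""
    return generate_vocabulary(10, 6, rng_seed=1)


@pytest.fixture(scope="session")
def std_lookup(std_vocab):
    """Match table for the standard set at r=3."""
    return build_match_lookup(std_vocab, 3)


@pytest.fixture(scope="session")
def std_vocab_alt():
    """A second, independently seeded standard set (a distinct translate)."""
    return generate_vocabulary(10, 6, rng_seed=22)


@pytest.fixture(scope="session")
def std_lookup_alt(std_vocab_alt):
    return build_match_lookup(std_vocab_alt, 3)


@pytest.fixture(scope="session")
def small_vocab():
    """Tiny probe set (L=5) for tests where exhaustive oracles must run."""
    return generate_vocabulary(5, 3, seed_word="ACGTA")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_segments(sequence, window, vocab, lookup, source_id="seq"):
    from specmosaic import segment_sequence
    return segment_sequence(sequence, window, source_id=source_id,
                            vocab=vocab, r=lookup.r, lookup=lookup)
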