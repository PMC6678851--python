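"""Shared fixtures: small seeded synthetic reference sets and helpers."""

from __future__ import annotations

import random

import pytest

from groelamp import refdb, simulate
from groelamp.primers import LAC_GROEL, expand_degenerate, reverse_complement


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_template(rng: random.Random, insert_len: int = 445,
                  flank5: int = 339, flank3: int = 200) -> str:
    """A template with exact primer expansions planted at 1-based 340/824."""
    fwd = rng.choice(sorted(expand_degenerate(LAC_GROEL.forward)))
    rev = rng.choice(sorted(expand_degenerate(LAC_GROEL.reverse)))
    return (random_dna(rng, flank5) + fwd + random_dna(rng, insert_len)
            + reverse_complement(rev) + random_dna(rng, flank3))


def split_pair(amplicon: str, read_len: int = 300, q: int = 38):
    """Error-free R1/R2 covering an amplicon from its two ends."""
    from groelamp.reads import ReadRecord

    r1 = ReadRecord("pair", amplicon[:read_len], [q] * read_len)
    r2 = ReadRecord("pair", reverse_complement(amplicon)[:read_len],
                    [q] * read_len)
    return r1, r2


@pytest.fixture(scope="session")
def small_refset() -> simulate.SynthReferenceSet:
    """Three species, two strains each, seeded."""
    return simulate.synth_reference_set(
        simulate.SynthRefConfig(n_species=3, strains_per_species=2, seed=11)
    )


@pytest.fixture(scope="session")
def small_db(small_refset) -> refdb.ReferenceDB:
    return refdb.build_db_from_records(small_refset.records,
                                       small_refset.taxonomy)
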