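"""Shared fixtures: the worked micro-instance and seeded random corpora."""

from __future__ import annotations

import random

import pytest

from centerstring import BitString, Instance, brute_force_dopt


@pytest.fixture(scope="session")
def micro():
    """The canonical worked 3x6 instance: d_opt = 2, unique center 001000."""
    return Instance.from_texts(["000000", "111000", "001110"])


def make_random_instance(rng: random.Random, k: int, L: int) -> Instance:
    return Instance(tuple(BitString(rng.getrandbits(L), L) for _ in range(k)))


@pytest.fixture(scope="session")
def small_corpus():
    """300 random instances (k 2..6, L 4..10) for module-level checks."""
    rng = random.Random(20110419)
    return [
        make_random_instance(rng, rng.randint(2, 6), rng.randint(4, 10))
        for _ in range(300)
    ]


@pytest.fixture(scope="session")
def acceptance_corpus():
    """1000 random instances with k in 3..6, L in 6..12, plus each one's
    oracle d_opt (shared across the equivalence and soundness suites)."""
    rng = random.Random(106)
    corpus = []
    for _ in range(1000):
        inst = make_random_instance(rng, rng.randint(3, 6), rng.randint(6, 12))
        d_opt, _ = brute_force_dopt(inst)
        corpus.append((inst, d_opt))
    return corpus
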