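"""Shared fixtures: small synthetic datasets and trained ensembles.

Everything is generated at test time from fixed seeds; the heavier trained
models are session-scoped so the suite trains them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import rosmine as rm
from rosmine.synth import _random_sequence


@pytest.fixture(scope="session")
def small_reference() -> rm.ReferenceSet:
    """3 families x 8 members, enough to exercise screening and networks."""
    return rm.gen_reference_families(3, 8, seed=42)


@pytest.fixture(scope="session")
def medium_reference() -> rm.ReferenceSet:
    """6 families x 10 members for classifier fixtures."""
    return rm.gen_reference_families(6, 10, seed=7)


def make_background(n: int, seed: int, length_range=(80, 150)) -> list[str]:
    rng = np.random.default_rng(seed)
    return [
        _random_sequence(rng, int(rng.integers(*length_range)), np.full(20, 0.05))
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def trained_ensembles(medium_reference):
    """A small fitted (level0, level1) pair shared across tests."""
    ref = medium_reference
    neg = make_background(len(ref.records), seed=8)
    cfg = rm.EnsembleConfig(seed=7)
    level0 = rm.train_level0([s for _, s in ref.records], neg, cfg)
    level1 = rm.train_level1(
        [s for _, s in ref.records], [ref.labels[i] for i, _ in ref.records], cfg
    )
    return level0, level1


class MotifScorer:
    """Toy level-0 stand-in: probability reflects intactness of one motif.

    Score = 0.1 + 0.8 * (fraction of motif positions matching the motif),
    evaluated at a fixed location.  Substituting a motif position drops the
    score; substituting anywhere else leaves it unchanged.
    """

    def __init__(self, motif: str = "WWW", start: int = 10):
        self.motif = motif
        self.start = start

    def positive_proba(self, sequences):
        out = []
        for s in sequences:
            window = s[self.start:self.start + len(self.motif)]
            match = sum(a == b for a, b in zip(window, self.motif)) / len(self.motif)
            out.append(0.1 + 0.8 * match)
        return np.asarray(out)
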