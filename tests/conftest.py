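"""Shared fixtures: the three-option universe with its eight relations,
and the 4x4 two-component design."""

from __future__ import annotations

import numpy as np
import pytest

from korders import PairUniverse, Relation, TwoComponentDesign

# The eight preference relations on {a, b, c}, keyed by their conventional
# three-bit labels, given by set content (the labels are historical; tests
# match sets, not vectors).
EIGHT_RELATIONS = {
    "000": {("a", "b"), ("b", "c"), ("c", "a")},
    "001": {("a", "b"), ("b", "c"), ("a", "c")},
    "010": {("a", "b"), ("c", "b"), ("c", "a")},
    "100": {("b", "a"), ("b", "c"), ("c", "a")},
    "011": {("a", "b"), ("c", "b"), ("a", "c")},
    "101": {("b", "a"), ("b", "c"), ("a", "c")},
    "110": {("b", "a"), ("c", "b"), ("c", "a")},
    "111": {("b", "a"), ("c", "b"), ("a", "c")},
}


@pytest.fixture(scope="session")
def universe3() -> PairUniverse:
    return PairUniverse(("a", "b", "c"))


@pytest.fixture(scope="session")
def eight(universe3) -> dict[str, Relation]:
    return {
        label: Relation.from_pairs(universe3, pairs)
        for label, pairs in EIGHT_RELATIONS.items()
    }


@pytest.fixture(scope="session")
def design44() -> TwoComponentDesign:
    return TwoComponentDesign(4, 4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
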