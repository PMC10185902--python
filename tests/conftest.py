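from __future__ import annotations

import numpy as np
import pytest

from cladescreen.tree import HaplogroupTree, MarkerDef, parse_tree

TOY_NEWICK = "(((O1a,O1b)O1,O2)O,N)Y;"

# one defining SNP per branch, positions 101..106
TOY_MARKERS = [
    MarkerDef("mN", "N", 101, "A", "G"),
    MarkerDef("mO", "O", 102, "A", "G"),
    MarkerDef("mO1", "O1", 103, "A", "G"),
    MarkerDef("mO1a", "O1a", 104, "A", "G"),
    MarkerDef("mO1b", "O1b", 105, "A", "G"),
    MarkerDef("mO2", "O2", 106, "A", "G"),
]

TOY_SAMPLES = ["s1", "s2", "s3", "s4", "s5", "s6"]
TOY_CALLS = {"s1": "N", "s2": "N", "s3": "O1a", "s4": "O1a",
             "s5": "O1b", "s6": "O2"}


@pytest.fixture
def toy_tree() -> HaplogroupTree:
    tree = parse_tree(TOY_NEWICK)
    for marker in TOY_MARKERS:
        tree.add_marker(marker)
    return tree


@pytest.fixture
def toy_samples() -> list[str]:
    return list(TOY_SAMPLES)


@pytest.fixture
def toy_calls() -> dict[str, str]:
    return dict(TOY_CALLS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
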