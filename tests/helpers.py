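"""Shared test utilities: matrix builders and independent brute-force oracles.

The oracles here deliberately avoid the package's own traversal logic so
they can serve as second, independent routes to the same answers.
"""

from __future__ import annotations

import numpy as np

from cladescreen.tree import HaplogroupTree
from cladescreen.variantio import MISSING, BuildStats, GenotypeMatrix

CHROM = "chrY"


def make_matrix(rows, samples):
    """Build a GenotypeMatrix from (pos, ref, alt, codes) tuples.

    ``codes`` is a per-sample list over {0, 1, MISSING}.
    """
    variants = [(CHROM, pos, ref, alt) for pos, ref, alt, _ in rows]
    ids = [None] * len(rows)
    calls = (np.array([codes for *_, codes in rows], dtype=np.int8)
             if rows else np.empty((0, len(samples)), dtype=np.int8))
    stats = BuildStats(seen=len(rows), retained=len(rows))
    return GenotypeMatrix(variants=variants, ids=ids, samples=list(samples),
                          calls=calls, stats=stats)


def lca_bruteforce(tree: HaplogroupTree, names) -> str:
    """LCA by explicit root-path intersection (independent of tree.lca)."""
    paths = []
    for name in names:
        path = []
        cur = name
        while cur is not None:
            path.append(cur)
            cur = tree.nodes[cur].parent
        paths.append(list(reversed(path)))
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest common ancestor = last element of any root-path that is common
    return [n for n in paths[0] if n in common][-1]


def oracle_assign(tree: HaplogroupTree, states: dict[str, int],
                  min_support: float = 0.5) -> str:
    """Exhaustive-node assignment oracle.

    Enumerates every node and keeps those whose entire root-path (root
    excluded) has derived count >= 1 and support > min_support per branch;
    returns the deepest valid node. Raises if the deepest level is
    ambiguous, which cannot happen for tree-consistent inputs.
    """

    def branch_ok(node: str) -> bool:
        d = a = 0
        for m in tree.nodes[node].markers:
            s = states.get(m, MISSING)
            if s == 1:
                d += 1
            elif s == 0:
                a += 1
        return d >= 1 and d / (d + a) > min_support

    valid = []
    for node in tree.nodes:
        path = tree.path(node)
        if all(branch_ok(n) for n in path[1:]):
            valid.append(node)
    deepest = max(valid, key=tree.depth)
    ties = [n for n in valid if tree.depth(n) == tree.depth(deepest)]
    assert len(ties) == 1, f"ambiguous oracle result: {ties}"
    return deepest


def consistent_states(rng: np.random.Generator, tree: HaplogroupTree,
                      true_node: str, missing_rate: float = 0.0,
                      backmutation_rate: float = 0.0) -> dict[str, int]:
    """Marker states for a sample truly at `true_node`.

    Path markers are derived, everything else ancestral; optional noise
    masks markers to MISSING or flips on-path markers back to ancestral.
    Off-path markers are never flipped to derived, so assignment stays
    well-defined for the exhaustive oracle.
    """
    on_path = set()
    for node in tree.path(true_node)[1:]:
        on_path.update(tree.nodes[node].markers)
    states = {}
    for name in tree.marker_index:
        state = 1 if name in on_path else 0
        u = rng.random()
        if u < missing_rate:
            state = MISSING
        elif state == 1 and u < missing_rate + backmutation_rate:
            state = 0
        states[name] = state
    return states
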