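"""Haplogroup assignment by greedy descent on derived-state defining markers.

From the root, each child branch is scored on its defining markers: d =
derived calls, a = ancestral calls (missing ignored). A branch is eligible
when d >= 1 and d/(d+a) exceeds ``min_support``; descent follows the
eligible branch with the best (support, d) score, ties resolved by
lexicographic child order. Samples with no informative marker stay at the
root and are flagged ``no-data``. Back-mutations are not modeled: a
recurrent ancestral state on the accepted path simply lowers support and
is recorded as a conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .tree import HaplogroupTree, MarkerDef
from .variantio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

ANCESTRAL = 0
DERIVED = 1
# MISSING (-1) shared with variantio


@dataclass
class HaplogroupCall:
    sample: str
    node: str
    path: list[str]
    derived_support: int
    conflicts: int
    no_data: bool = False


def genotype_marker(matrix: GenotypeMatrix, marker: MarkerDef) -> np.ndarray:
    """Per-sample marker states {ANCESTRAL, DERIVED, MISSING} for one marker.

    The marker is matched against matrix rows by position plus allele set;
    orientation is resolved from which of REF/ALT equals the derived
    allele. An absent or allele-discordant site yields MISSING everywhere.
    """
    states = np.full(len(matrix.samples), MISSING, dtype=np.int8)
    hit = None
    position_seen = False
    for i, (_, pos, ref, alt) in enumerate(matrix.variants):
        if pos != marker.position:
            continue
        position_seen = True
        if {ref, alt} == {marker.ancestral, marker.derived}:
            hit = (i, ref == marker.ancestral)
            break
    if hit is None:
        if position_seen:
            logger.warning(
                "marker %s: allele set mismatch at position %d; marker skipped",
                marker.name, marker.position,
            )
        else:
            logger.warning("marker %s: site %d absent from matrix", marker.name,
                           marker.position)
        return states
    row_idx, alt_is_derived = hit
    row = matrix.calls[row_idx]
    called = row != MISSING
    if alt_is_derived:
        states[called] = np.where(row[called] == 1, DERIVED, ANCESTRAL)
    else:
        states[called] = np.where(row[called] == 0, DERIVED, ANCESTRAL)
    return states


def _branch_score(tree: HaplogroupTree, node: str,
                  states: Mapping[str, int]) -> tuple[int, int]:
    d = a = 0
    for marker_name in tree.nodes[node].markers:
        state = states.get(marker_name, MISSING)
        if state == DERIVED:
            d += 1
        elif state == ANCESTRAL:
            a += 1
    return d, a


def assign_haplogroup(
    sample: str,
    states: Mapping[str, int],
    tree: HaplogroupTree,
    min_support: float = 0.5,
) -> HaplogroupCall:
    """Assign one sample given its per-marker states (marker name -> state)."""
    node = tree.root
    path = [node]
    support_total = 0
    conflict_total = 0
    while True:
        best: tuple[float, int] | None = None
        best_child = None
        for child in tree.nodes[node].children:  # lexicographic
            d, a = _branch_score(tree, child, states)
            if d < 1:
                continue
            support = d / (d + a)
            if support <= min_support:
                continue
            score = (support, d)
            if best is None or score > best:
                best, best_child = score, child
        if best_child is None:
            break
        d, a = _branch_score(tree, best_child, states)
        support_total += d
        conflict_total += a
        node = best_child
        path.append(node)
    no_data = all(states.get(m, MISSING) == MISSING for m in tree.marker_index)
    return HaplogroupCall(sample=sample, node=node, path=path,
                          derived_support=support_total,
                          conflicts=conflict_total, no_data=no_data)


def assign_all(
    matrix: GenotypeMatrix,
    tree: HaplogroupTree,
    min_support: float = 0.5,
) -> list[HaplogroupCall]:
    """One call per matrix sample; logs a per-node summary."""
    marker_states = {
        name: genotype_marker(matrix, marker)
        for name, marker in tree.marker_index.items()
    }
    calls = []
    for j, sample in enumerate(matrix.samples):
        states = {name: int(vec[j]) for name, vec in marker_states.items()}
        call = assign_haplogroup(sample, states, tree, min_support=min_support)
        if call.no_data:
            logger.warning("sample %s: no informative markers; called at root", sample)
        calls.append(call)
    tally: dict[str, int] = {}
    for call in calls:
        tally[call.node] = tally.get(call.node, 0) + 1
    logger.info("assignments per node: %s", dict(sorted(tally.items())))
    return calls


def calls_to_map(calls: list[HaplogroupCall]) -> dict[str, str]:
    return {c.sample: c.node for c in calls}


CALLS_TSV_COLUMNS = ("sample", "haplogroup", "path", "derived_support",
                     "conflicts", "status")


def calls_to_tsv(calls: list[HaplogroupCall]) -> str:
    lines = ["\t".join(CALLS_TSV_COLUMNS)]
    for c in calls:
        status = "no-data" if c.no_data else "ok"
        lines.append(f"{c.sample}\t{c.node}\t{'|'.join(c.path)}"
                     f"\t{c.derived_support}\t{c.conflicts}\t{status}")
    return "\n".join(lines) + "\n"


def parse_calls_tsv(text: str) -> dict[str, str]:
    """Read a calls TSV back into a sample -> node mapping."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("sample\t"):
        raise ValidationError("calls TSV must start with a 'sample' header row")
    out = {}
    for line in lines[1:]:
        fields = line.split("\t")
        out[fields[0]] = fields[1]
    return out
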