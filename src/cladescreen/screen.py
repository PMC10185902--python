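"""Clade-exactness screen for haploid bi-allelic InDels.

A variant is phylogenetically informative for a clade C when its derived
allele is carried by every called member of C (criterion 1) and by no
called sample outside C (criterion 2). The candidate clade is proposed as
the LCA of the derived carriers' assigned nodes and then both criteria are
re-verified against the full cohort.

Because the reference chromosome need not belong to the focal haplogroup,
a clade-confined allele may appear as either REF or ALT; the focal
restriction therefore resolves an orientation (which allele is treated as
derived) before clade assignment. Criteria are evaluated over called
samples only; ``strict_missing`` additionally rejects candidates whose
assigned clade contains any missing call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .tree import HaplogroupTree, MarkerDef
from .variantio import MISSING, GenotypeMatrix, VariantKey

logger = logging.getLogger(__name__)

REF, ALT, NONE = "REF", "ALT", "NONE"


@dataclass
class ScreenConfig:
    focal_clade: str = "O"
    min_call_fraction: float = 0.9
    strict_missing: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.min_call_fraction <= 1.0):
            raise ConfigError("min_call_fraction must be in (0, 1]")


@dataclass
class CandidateMarker:
    key: VariantKey
    id: str | None
    assigned_clade: str
    derived_is: str  # REF | ALT
    carriers: int
    clade_called: int
    outside_derived: int
    status: str = "novel"
    low_evidence: bool = False


@dataclass
class Rejection:
    key: VariantKey
    stage: str
    reason: str


@dataclass
class ScreenResult:
    counters: dict[str, int]
    candidates: list[CandidateMarker]
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def novel(self) -> list[CandidateMarker]:
        return [c for c in self.candidates if c.status == "novel"]


def clade_samples(tree: HaplogroupTree, calls: Mapping[str, str], node: str) -> set[str]:
    """Samples whose assigned node lies in the subtree rooted at `node`."""
    members = tree.descendants(node)
    return {s for s, n in calls.items() if n in members}


def clade_frequencies(
    matrix: GenotypeMatrix,
    calls: Mapping[str, str],
    tree: HaplogroupTree,
) -> pd.DataFrame:
    """Alternate-allele frequency of every variant in every clade, by direct counting.

    One row per (variant, node) with called_count > 0. ``derived_count``
    counts the ALT allele; REF-oriented variants read as 1 - frequency.
    """
    sample_pos = matrix.sample_index()
    node_indices = {}
    for node in tree.nodes:
        members = clade_samples(tree, calls, node)
        idx = np.array(sorted(sample_pos[s] for s in members if s in sample_pos),
                       dtype=np.intp)
        node_indices[node] = idx
    rows = []
    for i, key in enumerate(matrix.variants):
        keystr = f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"
        row = matrix.calls[i]
        for node, idx in node_indices.items():
            if idx.size == 0:
                continue
            sub = row[idx]
            called = int(np.count_nonzero(sub != MISSING))
            if called == 0:
                continue
            derived = int(np.count_nonzero(sub == 1))
            rows.append((keystr, node, derived, called, derived / called))
    return pd.DataFrame(
        rows, columns=["variant_key", "clade", "derived_count", "called_count",
                       "frequency"],
    )


def _carrier_sets(row: np.ndarray, samples: Sequence[str]) -> tuple[set[str], set[str]]:
    alt = {samples[j] for j in np.flatnonzero(row == 1)}
    ref = {samples[j] for j in np.flatnonzero(row == 0)}
    return ref, alt


def focal_restricted(
    row: np.ndarray,
    samples: Sequence[str],
    focal_samples: set[str],
    min_call_fraction: float = 0.9,
) -> tuple[str, str]:
    """Orientation (REF/ALT/NONE) of the allele confined to the focal clade.

    Returns (orientation, reason); reason is "ok", "low-call" or "not-focal".
    """
    called = int(np.count_nonzero(row != MISSING))
    if called < min_call_fraction * len(samples):
        return NONE, "low-call"
    ref_carriers, alt_carriers = _carrier_sets(row, samples)
    if alt_carriers and alt_carriers <= focal_samples:
        return ALT, "ok"
    if ref_carriers and ref_carriers <= focal_samples:
        return REF, "ok"
    return NONE, "not-focal"


def assign_clade(
    row: np.ndarray,
    samples: Sequence[str],
    orientation: str,
    calls: Mapping[str, str],
    tree: HaplogroupTree,
    config: ScreenConfig,
    key: VariantKey,
    id: str | None = None,
) -> CandidateMarker | Rejection:
    """Propose the carriers' LCA clade and verify both exactness criteria."""
    if orientation not in (REF, ALT):
        raise ContractError("assign_clade requires a resolved orientation")
    derived_code = 1 if orientation == ALT else 0
    carriers = {samples[j] for j in np.flatnonzero(row == derived_code)}
    if not carriers:
        raise ContractError("empty derived-carrier set; run focal_restricted first")
    clade = tree.lca({calls[s] for s in carriers})
    members = clade_samples(tree, calls, clade)
    sample_pos = {s: j for j, s in enumerate(samples)}
    called_members = {s for s in members if row[sample_pos[s]] != MISSING}
    if called_members - carriers:
        return Rejection(key=key, stage="assign_clade", reason="criterion1")
    outside_derived = {s for s in carriers if s not in members}
    if outside_derived:  # impossible given the LCA, re-verified anyway
        return Rejection(key=key, stage="assign_clade", reason="criterion2")
    if config.strict_missing and len(called_members) < len(members):
        return Rejection(key=key, stage="assign_clade", reason="unverifiable")
    low = len(members) < 3
    if low:
        logger.warning("candidate %s: clade %s census %d < 3 (low evidence)",
                       key, clade, len(members))
    return CandidateMarker(
        key=key, id=id, assigned_clade=clade, derived_is=orientation,
        carriers=len(carriers), clade_called=len(called_members),
        outside_derived=0, low_evidence=low,
    )


def dedup_known(
    candidates: list[CandidateMarker],
    known: Iterable[MarkerDef],
) -> list[CandidateMarker]:
    """Annotate candidates identical to known markers on (position, allele set)."""
    index = {(m.position, m.allele_set): m.name for m in known}
    positions = {m.position for m in known}
    for cand in candidates:
        _, pos, ref, alt = cand.key
        name = index.get((pos, frozenset((ref, alt))))
        if name is not None:
            cand.status = f"duplicate_of:{name}"
        elif pos in positions:
            logger.warning(
                "candidate at known-marker position %d has different alleles; "
                "kept as novel", pos,
            )
    return candidates


def screen(
    matrix: GenotypeMatrix,
    calls: Mapping[str, str],
    tree: HaplogroupTree,
    config: ScreenConfig | None = None,
    known: Iterable[MarkerDef] = (),
) -> ScreenResult:
    """Full screen: call-fraction gate, focal restriction, clade assignment, dedup."""
    config = config or ScreenConfig()
    if config.focal_clade not in tree.nodes:
        raise ConfigError(f"focal clade {config.focal_clade!r} absent from tree")
    samples = matrix.samples
    focal = clade_samples(tree, calls, config.focal_clade)
    counters = {
        "records_seen": max(matrix.stats.seen, matrix.n_variants),
        "biallelic_indels": matrix.n_variants,
        "focal_restricted": 0,
        "clade_exact": 0,
        "novel": 0,
    }
    candidates: list[CandidateMarker] = []
    rejections: list[Rejection] = []
    for i, key in enumerate(matrix.variants):
        row = matrix.calls[i]
        orientation, reason = focal_restricted(
            row, samples, focal, min_call_fraction=config.min_call_fraction
        )
        if orientation == NONE:
            rejections.append(Rejection(key=key, stage="focal_restricted", reason=reason))
            continue
        counters["focal_restricted"] += 1
        outcome = assign_clade(row, samples, orientation, calls, tree, config,
                               key=key, id=matrix.ids[i])
        if isinstance(outcome, Rejection):
            rejections.append(outcome)
            continue
        counters["clade_exact"] += 1
        candidates.append(outcome)
    candidates = dedup_known(candidates, known)
    counters["novel"] = sum(1 for c in candidates if c.status == "novel")
    candidates.sort(key=lambda c: (tree.depth(c.assigned_clade), c.key[1]))
    return ScreenResult(counters=counters, candidates=candidates,
                        rejections=rejections)


def format_mutation(ref: str, alt: str, derived_is: str) -> str:
    """Render an ancestral > derived event string ("TAAAG > -", "- > T")."""
    ancestral, derived = (ref, alt) if derived_is == ALT else (alt, ref)
    longer, shorter = (ancestral, derived) if len(ancestral) > len(derived) else (derived, ancestral)
    if longer.startswith(shorter):
        inserted = longer[len(shorter):]
        if len(ancestral) > len(derived):
            return f"{inserted} > -"
        return f"- > {inserted}"
    return f"{ancestral} > {derived}"


CANDIDATES_TSV_COLUMNS = (
    "variant_key", "rsid", "position", "mutation", "assigned_clade",
    "orientation", "carriers", "clade_called", "status",
)


def candidates_to_tsv(candidates: list[CandidateMarker]) -> str:
    lines = ["\t".join(CANDIDATES_TSV_COLUMNS)]
    for c in candidates:
        chrom, pos, ref, alt = c.key
        lines.append("\t".join([
            f"{chrom}:{pos}:{ref}:{alt}", c.id or ".", str(pos),
            format_mutation(ref, alt, c.derived_is), c.assigned_clade,
            c.derived_is, str(c.carriers), str(c.clade_called), c.status,
        ]))
    return "\n".join(lines) + "\n"
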