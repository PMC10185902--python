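"""End-to-end runs plus the cross-assignment consistency validator."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import caller, screen as screen_mod, variantio
from .errors import ParseError, ValidationError
from .screen import CandidateMarker, ScreenConfig, ScreenResult
from .tree import HaplogroupTree, parse_marker_table, parse_tree
from .variantio import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

MARKER_CLASSES = {"snp", "biallelic_indel"}


@dataclass
class ConflictRow:
    sample: str
    variant_key: str
    expected: str  # "derived" | "ancestral"
    observed: str


@dataclass
class RunOutputs:
    result: ScreenResult
    calls: list[caller.HaplogroupCall]
    matrix: GenotypeMatrix
    summary: dict = field(default_factory=dict)


def load_tree(tree_path: str | Path, marker_path: str | Path) -> HaplogroupTree:
    return parse_tree(Path(tree_path).read_text(), Path(marker_path).read_text())


def load_known(known_path: str | Path | None):
    if known_path is None:
        return []
    return parse_marker_table(Path(known_path).read_text())


def run_screen(
    vcf_path: str | Path,
    tree_path: str | Path,
    marker_path: str | Path,
    known_path: str | Path | None = None,
    config: ScreenConfig | None = None,
    mask_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> RunOutputs:
    """Assign haplogroups, screen InDels, and (optionally) write all outputs.

    Everything is computed before anything is written, so a failing stage
    leaves no partial output files behind.
    """
    config = config or ScreenConfig()
    tree = load_tree(tree_path, marker_path)
    known = load_known(known_path)
    samples, records = variantio.read_vcf(str(vcf_path))
    mask = None
    if mask_path is not None:
        mask = variantio.load_bed(Path(mask_path).read_text())
    marker_matrix = variantio.build_matrix(records, samples, keep_class=MARKER_CLASSES)
    calls = caller.assign_all(marker_matrix, tree)
    calls_map = caller.calls_to_map(calls)
    indel_matrix = variantio.build_matrix(records, samples,
                                          keep_class="biallelic_indel",
                                          region_mask=mask)
    result = screen_mod.screen(indel_matrix, calls_map, tree, config, known)
    frequencies = screen_mod.clade_frequencies(indel_matrix, calls_map, tree)

    per_clade: dict[str, int] = {}
    for cand in result.candidates:
        if cand.status == "novel":
            per_clade[cand.assigned_clade] = per_clade.get(cand.assigned_clade, 0) + 1
    warnings = []
    if indel_matrix.stats.unanchored:
        warnings.append(
            f"{len(indel_matrix.stats.unanchored)} retained indels lack a shared anchor base")
    for cand in result.candidates:
        if cand.low_evidence:
            warnings.append(f"low-evidence candidate (clade census < 3): {cand.key}")
    summary = {
        "counters": result.counters,
        "candidate_count": len(result.candidates),
        "novel_count": len(result.novel),
        "per_clade": dict(sorted(per_clade.items())),
        "warnings": warnings,
        "config": {
            "focal_clade": config.focal_clade,
            "min_call_fraction": config.min_call_fraction,
            "strict_missing": config.strict_missing,
        },
    }
    outputs = RunOutputs(result=result, calls=calls, matrix=indel_matrix,
                         summary=summary)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "calls.tsv").write_text(caller.calls_to_tsv(calls))
        (out / "candidates.tsv").write_text(
            screen_mod.candidates_to_tsv(result.candidates))
        (out / "frequencies.tsv").write_text(
            frequencies.to_csv(sep="\t", index=False))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return outputs


def validate_consistency(
    candidates: list[CandidateMarker],
    matrix: GenotypeMatrix,
    calls: Mapping[str, str],
    tree: HaplogroupTree,
) -> list[ConflictRow]:
    """Check that each sample's derived candidate InDels are exactly those
    whose assigned clade is an ancestor-or-self of the sample's node."""
    key_to_row = {key: i for i, key in enumerate(matrix.variants)}
    sample_pos = matrix.sample_index()
    conflicts: list[ConflictRow] = []
    for cand in candidates:
        row_idx = key_to_row.get(cand.key)
        if row_idx is None:
            raise ValidationError(f"candidate {cand.key} absent from matrix")
        row = matrix.calls[row_idx]
        derived_code = 1 if cand.derived_is == "ALT" else 0
        keystr = f"{cand.key[0]}:{cand.key[1]}:{cand.key[2]}:{cand.key[3]}"
        for sample, node in calls.items():
            j = sample_pos.get(sample)
            if j is None or row[j] == MISSING:
                continue
            expected = tree.is_ancestor(cand.assigned_clade, node)
            observed = row[j] == derived_code
            if expected != observed:
                conflicts.append(ConflictRow(
                    sample=sample, variant_key=keystr,
                    expected="derived" if expected else "ancestral",
                    observed="derived" if observed else "ancestral",
                ))
    return conflicts


def conflicts_to_tsv(conflicts: list[ConflictRow]) -> str:
    lines = ["sample\tvariant_key\texpected\tobserved"]
    for c in conflicts:
        lines.append(f"{c.sample}\t{c.variant_key}\t{c.expected}\t{c.observed}")
    return "\n".join(lines) + "\n"


def parse_candidates_tsv(text: str) -> list[CandidateMarker]:
    """Read a candidates TSV (as written by ``candidates_to_tsv``) back in."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0].split("\t") != list(screen_mod.CANDIDATES_TSV_COLUMNS):
        raise ParseError("candidates TSV header mismatch")
    out = []
    for line in lines[1:]:
        f = dict(zip(screen_mod.CANDIDATES_TSV_COLUMNS, line.split("\t")))
        chrom, pos, ref, alt = f["variant_key"].split(":")
        out.append(CandidateMarker(
            key=(chrom, int(pos), ref, alt),
            id=None if f["rsid"] == "." else f["rsid"],
            assigned_clade=f["assigned_clade"], derived_is=f["orientation"],
            carriers=int(f["carriers"]), clade_called=int(f["clade_called"]),
            outside_derived=0, status=f["status"],
        ))
    return out
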