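"""Packaged O-M175 haplogroup fixture: topology, marker index, panel table.

The topology is reconstructed from hierarchical haplogroup nomenclature: a
node's parent is its name minus the trailing maximal run of same-type
characters (digits or letters), so O1b1a1a -> O1b1a1, O2a4 -> O2a. The
haplogroup O hangs under a two-branch root (outgroup N) so that
focal-restriction logic is exercisable.

Known-marker coordinates and alleles below are synthetic placeholders laid
out in a reserved coordinate range (22-24 Mb); only marker names, defined
nodes and variant classes are meaningful for deduplication bookkeeping and
the InDel-determinable-haplogroup ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParseError
from .tree import HaplogroupTree, MarkerDef


@dataclass(frozen=True)
class PanelEntry:
    """One row of the 22-InDel reference panel."""

    clade: str
    rsid: str
    position: int
    mutation: str  # "X > -" deletion / "- > X" insertion, ancestral > derived


PANEL_TABLE: tuple[PanelEntry, ...] = (
    PanelEntry("O1a1", "rs79011057", 15_870_505, "C > -"),
    PanelEntry("O1a1", "rs75465866", 14_101_642, "T > -"),
    PanelEntry("O1a1a", "rs756897195", 14_444_770, "TTG > -"),
    PanelEntry("O1a1a1", "rs776778598", 19_623_371, "GAA > -"),
    PanelEntry("O1b", "rs200942940", 12_416_056, "C > -"),
    PanelEntry("O1b1", "rs760314663", 20_774_821, "C > -"),
    PanelEntry("O1b1a", "rs749761428", 6_796_839, "- > T"),
    PanelEntry("O1b1a1a", "rs774008684", 17_452_553, "AAGA > -"),
    PanelEntry("O1b1a1a1a1a1", "rs774805227", 16_596_493, "A > -"),
    PanelEntry("O1b2", "rs201451931", 7_765_543, "T > -"),
    PanelEntry("O1b2a1a", "rs200704310", 12_173_532, "TAA > -"),
    PanelEntry("O2a", "rs201101541", 16_693_737, "- > C"),
    PanelEntry("O2a1a1", "rs2044026501", 16_599_674, "A > -"),
    PanelEntry("O2a1b", "rs1569514296", 13_477_987, "TAC > -"),
    PanelEntry("O2a1b1a", "rs754348496", 12_420_208, "T > -"),
    PanelEntry("O2a1b1a1a1a1", "rs759556853", 12_663_077, "T > -"),
    PanelEntry("O2a2a", "rs768760512", 13_353_588, "- > T"),
    PanelEntry("O2a2a1a", "rs776330196", 13_497_196, "T > -"),
    PanelEntry("O2a2b", "rs79480324", 14_153_309, "A > -"),
    PanelEntry("O2a2b1a1a1a4a", "rs796937681", 12_821_143, "- > A"),
    PanelEntry("O2a2b1a2a", "rs201510546", 8_044_404, "TAAAG > -"),
    PanelEntry("O2a2b1a2a1a", "rs762474604", 15_235_863, "AT > -"),
)

# Clades the 2019-2020 tree defines with a single representative Y-SNP.
SINGLE_SNP_CLADES: tuple[str, ...] = ("O1a1", "O1b1a", "O2a1b1a", "O2a2a")

ROOT_NAME = "Y"
OUTGROUP_NAME = "N"
FOCAL_CLADE = "O"

# Nodes named in the index beyond the panel clades themselves.
_EXTRA_NODES: tuple[str, ...] = (
    "O1b1a1a1a1a1a1a1a",  # A15721
    "O2a1a1a1a1",         # M121
    "O2a2b1",             # M134
    "O2a2b1a1",           # M117
    "O2a2b1a1a",          # M133
    "O2a4",               # M333
    "O1b1a2",             # cross-check outgroup-within-O branch
)

# name -> (haplogroup, ancestral, derived); positions assigned below.
_KNOWN_INDELS: tuple[tuple[str, str, str, str], ...] = (
    ("M175", "O", "ACTCTC", "A"),
    ("M111", "O1b1a1a1a1a1", "AG", "A"),
    ("A15721", "O1b1a1a1a1a1a1a1a", "A", "AT"),
    ("M121", "O2a1a1a1a1", "AC", "A"),
    ("FGC12511", "O2a1b1a", "ATT", "A"),
    ("M134", "O2a2b1", "AG", "A"),
    ("M117", "O2a2b1a1", "ACA", "A"),
    ("M133", "O2a2b1a1a", "A", "AG"),
    ("M333", "O2a4", "AAC", "A"),
)

_KNOWN_SNPS: tuple[tuple[str, str, str, str], ...] = (
    ("B384", "O1a1", "C", "T"),
    ("M1470", "O1b1a", "G", "A"),
    ("M188", "O2a2a", "A", "G"),
    ("CTS4658", "O2a2b1a1a1a4a", "T", "C"),
)

_KNOWN_INDEL_BASE = 22_000_000
_KNOWN_SNP_BASE = 23_000_000


def nomenclature_parent(name: str) -> str | None:
    """Parent haplogroup name by trailing same-type-run truncation; None at top."""
    if len(name) <= 1:
        return None
    last_is_digit = name[-1].isdigit()
    i = len(name) - 1
    while i > 0 and name[i - 1].isdigit() == last_is_digit:
        i -= 1
    return name[:i] if i > 0 else None


def parse_mutation(mutation: str, anchor: str = "A") -> tuple[str, str]:
    """Anchored (ancestral, derived) VCF-style alleles for an event string.

    Deletions "X > -" become (anchor+X, anchor); insertions "- > X" become
    (anchor, anchor+X). The event position is used as POS of the anchored
    record (anchor occupies POS itself).
    """
    parts = [p.strip() for p in mutation.replace("−", "-").split(">")]
    if len(parts) != 2:
        raise ParseError(f"cannot parse mutation string {mutation!r}")
    anc, der = parts
    if anc == "-" and der != "-":
        return anchor, anchor + der
    if der == "-" and anc != "-":
        return anchor + anc, anchor
    raise ParseError(f"mutation {mutation!r} is not a one-sided insertion/deletion")


def known_indel_markers() -> list[MarkerDef]:
    """The nine tree-defining Y-InDels used for candidate deduplication."""
    return [
        MarkerDef(name=name, haplogroup=node, position=_KNOWN_INDEL_BASE + 1000 * i,
                  ancestral=anc, derived=der)
        for i, (name, node, anc, der) in enumerate(_KNOWN_INDELS)
    ]


def known_snp_markers() -> list[MarkerDef]:
    return [
        MarkerDef(name=name, haplogroup=node, position=_KNOWN_SNP_BASE + 1000 * i,
                  ancestral=anc, derived=der)
        for i, (name, node, anc, der) in enumerate(_KNOWN_SNPS)
    ]


def packaged_markers() -> list[MarkerDef]:
    """The full packaged O-M175 marker index (9 InDels + representative SNPs)."""
    return known_indel_markers() + known_snp_markers()


def om175_node_names() -> set[str]:
    """Panel clades, extra named nodes, and all nomenclature ancestors down to O."""
    names: set[str] = set()
    frontier = {e.clade for e in PANEL_TABLE} | set(_EXTRA_NODES) | {FOCAL_CLADE}
    for name in frontier:
        while name is not None:
            names.add(name)
            name = nomenclature_parent(name)
    return names


def om175_tree(with_markers: bool = True) -> HaplogroupTree:
    """The packaged fixture tree: root Y over focal O subtree and outgroup N."""
    parent_of: dict[str, str | None] = {ROOT_NAME: None, OUTGROUP_NAME: ROOT_NAME}
    for name in om175_node_names():
        parent = nomenclature_parent(name)
        parent_of[name] = parent if parent is not None else ROOT_NAME
    markers = packaged_markers() if with_markers else []
    return HaplogroupTree.from_parent_map(parent_of, markers)


def indel_determinable_haplogroups(markers: list[MarkerDef] | None = None) -> set[str]:
    """Distinct nodes carrying at least one InDel-class defining marker."""
    markers = packaged_markers() if markers is None else markers
    return {m.haplogroup for m in markers if m.variant_class == "indel"}
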