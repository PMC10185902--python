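"""Labeled haplogroup tree plus marker index.

The tree is the coordinate system for every clade computation: membership,
descendant sets and lowest common ancestors. Topology comes from a Newick
string with labeled internal nodes; branch-defining markers come from a
separate tab-separated table (columns ``name  haplogroup  position
ancestral  derived``). Branch lengths, if present, are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

from .errors import ContractError, ParseError, ValidationError

_ALLELE_RE = re.compile(r"^[ACGT]+$")

MARKER_TSV_COLUMNS = ("name", "haplogroup", "position", "ancestral", "derived")


@dataclass(frozen=True)
class MarkerDef:
    """A branch-defining variant: derived state places a chromosome in `haplogroup`.

    Alleles are anchored strings over ACGT; ``position`` is the 1-based
    coordinate of the anchored representation (VCF POS convention).
    """

    name: str
    haplogroup: str
    position: int
    ancestral: str
    derived: str

    def __post_init__(self) -> None:
        if not self.ancestral or not self.derived:
            raise ValidationError(f"marker {self.name}: empty allele string")
        for allele in (self.ancestral, self.derived):
            if not _ALLELE_RE.match(allele):
                raise ValidationError(
                    f"marker {self.name}: allele {allele!r} not over ACGT"
                )
        if self.ancestral == self.derived:
            raise ValidationError(f"marker {self.name}: ancestral == derived")
        if self.position < 1:
            raise ValidationError(f"marker {self.name}: position must be >= 1")

    @property
    def variant_class(self) -> str:
        return "indel" if len(self.ancestral) != len(self.derived) else "snp"

    @property
    def allele_set(self) -> frozenset[str]:
        return frozenset((self.ancestral, self.derived))


@dataclass
class TreeNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=list)


class HaplogroupTree:
    """Rooted labeled tree with per-node defining markers.

    Children are kept in lexicographic order so every traversal is
    deterministic. All query methods raise :class:`ValidationError` for
    unknown node names.
    """

    def __init__(self, nodes: Mapping[str, TreeNode], markers: Iterable[MarkerDef] = ()):
        self.nodes: dict[str, TreeNode] = dict(nodes)
        roots = [n.name for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            node.children.sort()
            for child in node.children:
                if child not in self.nodes:
                    raise ValidationError(f"node {node.name} lists unknown child {child}")
        self._check_connected()
        self.marker_index: dict[str, MarkerDef] = {}
        self.position_index: dict[tuple[int, str, str], str] = {}
        for marker in markers:
            self.add_marker(marker)
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_parent_map(
        cls, parent_of: Mapping[str, str | None], markers: Iterable[MarkerDef] = ()
    ) -> "HaplogroupTree":
        nodes = {name: TreeNode(name=name, parent=parent) for name, parent in parent_of.items()}
        for name, parent in parent_of.items():
            if parent is not None:
                if parent not in nodes:
                    raise ValidationError(f"node {name} has unknown parent {parent}")
                nodes[parent].children.append(name)
        return cls(nodes, markers)

    def add_marker(self, marker: MarkerDef) -> None:
        if marker.haplogroup not in self.nodes:
            raise ValidationError(
                f"marker {marker.name} references unknown node {marker.haplogroup}"
            )
        if marker.name in self.marker_index:
            raise ValidationError(f"duplicate marker name {marker.name}")
        key = (marker.position, marker.ancestral, marker.derived)
        if key in self.position_index:
            raise ValidationError(
                f"duplicate marker site {key}: {self.position_index[key]} vs {marker.name}"
            )
        self.marker_index[marker.name] = marker
        self.position_index[key] = marker.name
        self.nodes[marker.haplogroup].markers.append(marker.name)

    def _check_connected(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise ValidationError(f"cycle detected at node {name}")
            seen.add(name)
            stack.extend(self.nodes[name].children)
        if seen != set(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise ValidationError(f"nodes unreachable from root: {orphans}")

    # -- queries ----------------------------------------------------------

    def _require(self, name: str) -> TreeNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise ValidationError(f"unknown tree node {name!r}") from None

    def descendants(self, name: str) -> frozenset[str]:
        """All nodes in the subtree rooted at `name`, inclusive."""
        cached = self._desc_cache.get(name)
        if cached is not None:
            return cached
        self._require(name)
        out: set[str] = set()
        stack = [name]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(self.nodes[cur].children)
        result = frozenset(out)
        self._desc_cache[name] = result
        return result

    def path(self, name: str) -> list[str]:
        """Root-to-node name list (both endpoints included)."""
        self._require(name)
        out = []
        cur: str | None = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        out.reverse()
        return out

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def is_ancestor(self, ancestor: str, node: str) -> bool:
        """True when `ancestor` is an ancestor of `node` or the node itself."""
        return ancestor in self.path(node)

    def lca(self, names: Iterable[str]) -> str:
        names = list(names)
        if not names:
            raise ContractError("lca of an empty node set is undefined")
        common: set[str] | None = None
        for name in names:
            ancestors = set(self.path(name))
            common = ancestors if common is None else common & ancestors
        assert common
        return max(common, key=self.depth)

    def markers_of(self, name: str) -> list[MarkerDef]:
        return [self.marker_index[m] for m in self._require(name).markers]

    # -- serialization ----------------------------------------------------

    def to_newick(self) -> str:
        def render(name: str) -> str:
            children = self.nodes[name].children
            if not children:
                return name
            return "(" + ",".join(render(c) for c in children) + ")" + name

        return render(self.root) + ";"

    def markers_to_tsv(self) -> str:
        lines = ["\t".join(MARKER_TSV_COLUMNS)]
        for marker in self.marker_index.values():
            lines.append(
                f"{marker.name}\t{marker.haplogroup}\t{marker.position}"
                f"\t{marker.ancestral}\t{marker.derived}"
            )
        return "\n".join(lines) + "\n"


def parse_marker_table(text: str) -> list[MarkerDef]:
    """Parse the marker index TSV. Header row is mandatory; '.' alleles are rejected."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("marker table is empty")
    header = tuple(col.strip() for col in lines[0].split("\t"))
    if header != MARKER_TSV_COLUMNS:
        raise ParseError(
            f"marker table header must be {MARKER_TSV_COLUMNS}, got {header}"
        )
    markers = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 5:
            raise ParseError(f"marker table line {lineno}: expected 5 columns")
        name, haplogroup, pos_s, anc, der = fields
        if "." in anc or "." in der:
            raise ParseError(f"marker table line {lineno}: '.' not allowed in alleles")
        try:
            pos = int(pos_s.replace(",", ""))
        except ValueError:
            raise ParseError(f"marker table line {lineno}: bad position {pos_s!r}") from None
        markers.append(MarkerDef(name=name, haplogroup=haplogroup, position=pos,
                                 ancestral=anc, derived=der))
    return markers


def parse_newick(newick_text: str) -> dict[str, TreeNode]:
    """Parse a Newick topology with labeled internal nodes into a node map."""
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"malformed Newick: {exc}") from exc

    nodes: dict[str, TreeNode] = {}

    def label_of(dnode) -> str:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        if label is None or not str(label).strip():
            raise ParseError("Newick topology contains an unlabeled node")
        return str(label).strip()

    def walk(dnode, parent: str | None) -> None:
        name = label_of(dnode)
        if name in nodes:
            raise ValidationError(f"duplicate node name {name!r} in Newick topology")
        nodes[name] = TreeNode(name=name, parent=parent)
        if parent is not None:
            nodes[parent].children.append(name)
        for child in dnode.child_nodes():
            walk(child, name)

    walk(dtree.seed_node, None)
    return nodes


def parse_tree(newick_text: str, marker_table: str = "") -> HaplogroupTree:
    """Build a validated :class:`HaplogroupTree` from Newick text and a marker TSV."""
    nodes = parse_newick(newick_text)
    markers = parse_marker_table(marker_table) if marker_table.strip() else []
    return HaplogroupTree(nodes, markers)
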