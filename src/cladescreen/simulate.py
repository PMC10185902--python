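"""Seeded cohort simulator with a planted-variant truth ledger.

Generates a labeled tree (or reuses a supplied one), assigns samples to
nodes, gives every branch at least one defining SNP so the caller can
recover assignments, and plants InDels in controlled categories:

* ``clade_perfect``  — derived in exactly the samples of one focal-subtree
  clade (the signal the screen must recover);
* ``incomplete``     — derived in a strict subset of a clade (criterion-1
  violation);
* ``leaky``          — derived in a clade plus extra outside carriers
  (criterion-2 violation);
* ``homoplasic``     — derived in two disjoint clades whose LCA census
  exceeds the carrier set;
* ``duplicate_known``— exact position/allele copy of a known tree marker;
* ``outside_focal``  — clade-perfect for a node outside the focal clade;
* ``snp_decoy``      — clade-patterned substitutions (class-filtered
  upstream).

Missing-call and heterozygous-call noise are applied after construction;
the truth ledger reflects pre-noise states. A fixed seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fixtures import (
    FOCAL_CLADE,
    PANEL_TABLE,
    known_indel_markers,
    om175_tree,
    parse_mutation,
)
from .tree import HaplogroupTree, MarkerDef
from .variantio import MISSING  # noqa: F401  (re-exported convenience)

_BASES = ("A", "C", "G", "T")
_MAX_TRIES = 200

CATEGORIES = ("clade_perfect", "incomplete", "leaky", "homoplasic",
              "duplicate_known", "outside_focal", "snp_decoy")


@dataclass
class SimConfig:
    seed: int = 0
    tree: HaplogroupTree | None = None
    n_focal_nodes: int = 12
    samples_per_node: int | Mapping[str, int] = 3
    clade_perfect: int = 5
    incomplete: int = 0
    leaky: int = 0
    homoplasic: int = 0
    duplicate_known: int = 0
    outside_focal: int = 0
    snp_decoys: int = 0
    missing_rate: float = 0.0
    het_rate: float = 0.0
    focal_clade: str = FOCAL_CLADE
    known: Sequence[MarkerDef] = ()
    snps_per_branch: int = 1
    ref_orient_fraction: float = 0.25
    chrom: str = "chrY"

    def __post_init__(self) -> None:
        for name in ("clade_perfect", "incomplete", "leaky", "homoplasic",
                     "duplicate_known", "outside_focal", "snp_decoys",
                     "snps_per_branch", "n_focal_nodes"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("missing_rate", "het_rate", "ref_orient_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.missing_rate + self.het_rate > 1.0:
            raise ConfigError("missing_rate + het_rate must not exceed 1")


@dataclass
class _Planted:
    pos: int
    id: str | None
    ref: str
    alt: str
    codes: np.ndarray  # pre-noise {0,1} per sample
    category: str
    intended_clade: str | None
    derived_is: str


@dataclass
class SimResult:
    tree: HaplogroupTree
    samples: list[str]
    vcf_text: str
    truth: pd.DataFrame
    calls_truth: pd.DataFrame
    known: list[MarkerDef]

    def truth_tsv(self) -> str:
        return self.truth.to_csv(sep="\t", index=False)

    def calls_truth_tsv(self) -> str:
        return self.calls_truth.to_csv(sep="\t", index=False)


def random_tree(rng: np.random.Generator, n_focal_nodes: int,
                focal: str = FOCAL_CLADE) -> HaplogroupTree:
    """Random nomenclature-named topology: root Y over focal subtree and outgroup N."""
    parent_of: dict[str, str | None] = {"Y": None, focal: "Y", "N": "Y", "N1": "N"}
    focal_nodes = [focal]
    for _ in range(max(0, n_focal_nodes - 1)):
        parent = focal_nodes[int(rng.integers(len(focal_nodes)))]
        existing = sum(1 for n in parent_of.values() if n == parent)
        token = (str(existing + 1) if not parent[-1].isdigit()
                 else "abcdefghijklmnopqrstuvwxyz"[existing])
        child = parent + token
        parent_of[child] = parent
        focal_nodes.append(child)
    return HaplogroupTree.from_parent_map(parent_of)


class _Simulator:
    def __init__(self, config: SimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        base = config.tree if config.tree is not None else random_tree(
            self.rng, config.n_focal_nodes, config.focal_clade)
        if config.focal_clade not in base.nodes:
            raise ConfigError(f"focal clade {config.focal_clade!r} absent from tree")
        # work on a marker-free clone so branch SNPs can be attached freely
        self.tree = HaplogroupTree.from_parent_map(
            {n: node.parent for n, node in base.nodes.items()})
        self.samples: list[str] = []
        self.true_node: dict[str, str] = {}
        self._assign_samples()
        self.clade_sets = {
            node: frozenset(s for s in self.samples
                            if self.true_node[s] in self.tree.descendants(node))
            for node in self.tree.nodes
        }
        self.exact_sets = {v for v in self.clade_sets.values() if v}
        reserved = {m.position for m in config.known}
        reserved |= {e.position for e in PANEL_TABLE}
        self.used_positions: set[int] = set(reserved)
        self.records: list[_Planted] = []
        self.generated_known: list[MarkerDef] = []

    # -- cohort -----------------------------------------------------------

    def _per_node(self, node: str) -> int:
        spn = self.config.samples_per_node
        if isinstance(spn, Mapping):
            return int(spn.get(node, 0))
        return int(spn)

    def _assign_samples(self) -> None:
        i = 0
        for node in sorted(self.tree.nodes):
            for _ in range(self._per_node(node)):
                name = f"S{i:04d}"
                self.samples.append(name)
                self.true_node[name] = node
                i += 1
        if not self.samples:
            raise ConfigError("cohort is empty; increase samples_per_node")
        self.sample_pos = {s: j for j, s in enumerate(self.samples)}

    def _codes_for(self, carriers: frozenset[str] | set[str],
                   derived_is: str) -> np.ndarray:
        codes = np.zeros(len(self.samples), dtype=np.int8)
        for s in carriers:
            codes[self.sample_pos[s]] = 1
        if derived_is == "REF":
            codes = (1 - codes).astype(np.int8)
        return codes

    # -- primitive draws --------------------------------------------------

    def _new_position(self) -> int:
        while True:
            pos = int(self.rng.integers(1_000_000, 21_000_000))
            if pos not in self.used_positions:
                self.used_positions.add(pos)
                return pos

    def _random_indel_alleles(self) -> tuple[str, str]:
        anchor = _BASES[int(self.rng.integers(4))]
        length = int(self.rng.integers(1, 6))
        seq = "".join(_BASES[int(b)] for b in self.rng.integers(0, 4, size=length))
        if self.rng.random() < 0.5:
            return anchor + seq, anchor  # deletion
        return anchor, anchor + seq      # insertion

    def _focal_nodes(self) -> list[str]:
        return sorted(self.tree.descendants(self.config.focal_clade))

    def _pick(self, items: list[str]) -> str:
        if not items:
            raise ConfigError("no eligible tree node for requested category")
        return items[int(self.rng.integers(len(items)))]

    # -- category constructions -------------------------------------------

    def _plant(self, carriers: set[str] | frozenset[str], category: str,
               intended: str | None, derived_is: str = "ALT") -> None:
        ref, alt = self._random_indel_alleles()
        if derived_is == "REF":
            ref, alt = alt, ref
        self.records.append(_Planted(
            pos=self._new_position(), id=None, ref=ref, alt=alt,
            codes=self._codes_for(carriers, derived_is),
            category=category, intended_clade=intended, derived_is=derived_is,
        ))

    def _carriers_clade_perfect(self) -> tuple[frozenset[str], str]:
        eligible = [n for n in self._focal_nodes() if self.clade_sets[n]]
        for _ in range(_MAX_TRIES):
            node = self._pick(eligible)
            carriers = self.clade_sets[node]
            lca = self.tree.lca({self.true_node[s] for s in carriers})
            if lca == node:
                return carriers, node
        raise ConfigError("cannot construct a clade_perfect variant on this tree")

    def plant_clade_perfect(self, n: int) -> None:
        for _ in range(n):
            carriers, node = self._carriers_clade_perfect()
            derived_is = ("REF" if self.rng.random() < self.config.ref_orient_fraction
                          else "ALT")
            self._plant(carriers, "clade_perfect", node, derived_is)

    def plant_incomplete(self, n: int) -> None:
        eligible = [node for node in self._focal_nodes()
                    if len(self.clade_sets[node]) >= 2]
        for _ in range(n):
            for _ in range(_MAX_TRIES):
                node = self._pick(eligible)
                members = sorted(self.clade_sets[node])
                drop = members[int(self.rng.integers(len(members)))]
                carriers = frozenset(members) - {drop}
                if carriers and carriers not in self.exact_sets:
                    self._plant(carriers, "incomplete", node)
                    break
            else:
                raise ConfigError("cannot construct an incomplete variant")

    def plant_leaky(self, n: int) -> None:
        focal_nodes = [node for node in self._focal_nodes() if self.clade_sets[node]]
        for _ in range(n):
            for _ in range(_MAX_TRIES):
                node = self._pick(focal_nodes)
                outside = sorted(set(self.samples) - self.clade_sets[node])
                if not outside:
                    raise ConfigError("leaky category needs samples outside the clade")
                extra = outside[int(self.rng.integers(len(outside)))]
                carriers = self.clade_sets[node] | {extra}
                if carriers not in self.exact_sets:
                    self._plant(carriers, "leaky", node)
                    break
            else:
                raise ConfigError("cannot construct a leaky variant")

    def plant_homoplasic(self, n: int) -> None:
        focal_nodes = [node for node in self._focal_nodes() if self.clade_sets[node]]
        for _ in range(n):
            for _ in range(_MAX_TRIES):
                a = self._pick(focal_nodes)
                b = self._pick(focal_nodes)
                desc_a, desc_b = self.tree.descendants(a), self.tree.descendants(b)
                if a in desc_b or b in desc_a:
                    continue
                carriers = self.clade_sets[a] | self.clade_sets[b]
                lca = self.tree.lca({a, b})
                if len(self.clade_sets[lca]) > len(carriers) and \
                        carriers not in self.exact_sets:
                    self._plant(carriers, "homoplasic", lca)
                    break
            else:
                raise ConfigError("cannot construct a homoplasic variant "
                                  "(tree too small or no disjoint clades)")

    def plant_duplicate_known(self, n: int) -> None:
        known = list(self.config.known)
        if not known and n > 0:
            # synthesize known markers so the category stays usable on random trees
            eligible = [nd for nd in self._focal_nodes() if self.clade_sets[nd]]
            for i in range(min(n, max(1, len(eligible)))):
                ref, alt = self._random_indel_alleles()
                known.append(MarkerDef(
                    name=f"K{i}", haplogroup=self._pick(eligible),
                    position=self._new_position(), ancestral=ref, derived=alt))
            self.generated_known = known
        for i in range(n):
            marker = known[i % len(known)]
            if marker.haplogroup not in self.tree.nodes:
                raise ConfigError(
                    f"known marker {marker.name} defines node absent from the tree")
            carriers = self.clade_sets[marker.haplogroup]
            if not carriers:
                raise ConfigError(
                    f"known marker {marker.name}: clade {marker.haplogroup} is empty")
            self.records.append(_Planted(
                pos=marker.position, id=None, ref=marker.ancestral,
                alt=marker.derived, codes=self._codes_for(carriers, "ALT"),
                category="duplicate_known", intended_clade=marker.haplogroup,
                derived_is="ALT",
            ))

    def plant_outside_focal(self, n: int) -> None:
        focal_desc = self.tree.descendants(self.config.focal_clade)
        outside_nodes = [node for node in sorted(self.tree.nodes)
                         if node not in focal_desc and node != self.tree.root
                         and self.clade_sets[node]]
        focal_samples = self.clade_sets[self.config.focal_clade]
        for _ in range(n):
            node = self._pick(outside_nodes)
            carriers = self.clade_sets[node]
            complement = set(self.samples) - carriers
            if complement <= focal_samples:
                raise ConfigError(
                    "outside_focal needs non-focal samples outside the planted "
                    "clade (assign samples to the root or another outgroup)")
            self._plant(carriers, "outside_focal", node)

    def plant_snp_decoys(self, n: int) -> None:
        for _ in range(n):
            carriers, node = self._carriers_clade_perfect()
            ref = _BASES[int(self.rng.integers(4))]
            alt = _BASES[(_BASES.index(ref) + 1 + int(self.rng.integers(3))) % 4]
            self.records.append(_Planted(
                pos=self._new_position(), id=None, ref=ref, alt=alt,
                codes=self._codes_for(carriers, "ALT"),
                category="snp_decoy", intended_clade=node, derived_is="ALT",
            ))

    def plant_branch_snps(self) -> None:
        for node in sorted(self.tree.nodes):
            if node == self.tree.root:
                continue
            for j in range(self.config.snps_per_branch):
                pos = self._new_position()
                ref = _BASES[int(self.rng.integers(4))]
                alt = _BASES[(_BASES.index(ref) + 1 + int(self.rng.integers(3))) % 4]
                marker = MarkerDef(name=f"SNP_{node}_{j}", haplogroup=node,
                                   position=pos, ancestral=ref, derived=alt)
                self.tree.add_marker(marker)
                self.records.append(_Planted(
                    pos=pos, id=marker.name, ref=ref, alt=alt,
                    codes=self._codes_for(self.clade_sets[node], "ALT"),
                    category="branch_snp", intended_clade=node, derived_is="ALT",
                ))

    def plant_explicit(self, entries) -> None:
        """Plant explicit clade-perfect indels: (id, pos, ref, alt, clade) tuples."""
        for rsid, pos, ref, alt, clade in entries:
            if any(r.pos == pos for r in self.records):
                raise ConfigError(f"position {pos} planted twice")
            carriers = self.clade_sets[clade]
            if not carriers:
                raise ConfigError(f"explicit variant {rsid}: clade {clade} is empty")
            self.used_positions.add(pos)
            self.records.append(_Planted(
                pos=pos, id=rsid, ref=ref, alt=alt,
                codes=self._codes_for(carriers, "ALT"),
                category="clade_perfect", intended_clade=clade, derived_is="ALT",
            ))

    # -- output -----------------------------------------------------------

    def build(self) -> SimResult:
        cfg = self.config
        self.plant_branch_snps()
        self.plant_clade_perfect(cfg.clade_perfect)
        self.plant_incomplete(cfg.incomplete)
        self.plant_leaky(cfg.leaky)
        self.plant_homoplasic(cfg.homoplasic)
        self.plant_duplicate_known(cfg.duplicate_known)
        self.plant_outside_focal(cfg.outside_focal)
        self.plant_snp_decoys(cfg.snp_decoys)
        return self._finish()

    def _finish(self) -> SimResult:
        cfg = self.config
        self.records.sort(key=lambda r: r.pos)
        noise_total = cfg.missing_rate + cfg.het_rate
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={cfg.chrom}>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples),
        ]
        truth_rows = []
        for rec in self.records:
            gts = [str(int(c)) for c in rec.codes]
            if noise_total > 0:
                draws = self.rng.random(len(gts))
                for j, u in enumerate(draws):
                    if u < cfg.missing_rate:
                        gts[j] = "."
                    elif u < noise_total:
                        gts[j] = "0/1"
            lines.append(
                f"{cfg.chrom}\t{rec.pos}\t{rec.id or '.'}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
            )
            if rec.category != "branch_snp":
                truth_rows.append((
                    f"{cfg.chrom}:{rec.pos}:{rec.ref}:{rec.alt}",
                    rec.category, rec.intended_clade or "", rec.derived_is,
                ))
        truth = pd.DataFrame(
            truth_rows, columns=["variant_key", "category", "intended_clade",
                                 "derived_is"],
        )
        calls_truth = pd.DataFrame(
            [(s, self.true_node[s]) for s in self.samples],
            columns=["sample", "true_node"],
        )
        known = list(cfg.known) if cfg.known else list(self.generated_known)
        return SimResult(tree=self.tree, samples=self.samples,
                         vcf_text="\n".join(lines) + "\n", truth=truth,
                         calls_truth=calls_truth, known=known)


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate a seeded cohort (VCF text + truth tables) per the config."""
    return _Simulator(config).build()


REPLAY_SEED = 20230502


def table1_replay_fixture(seed: int = REPLAY_SEED,
                          samples_per_node: int = 3) -> SimResult:
    """Cohort on the packaged O-M175 tree with the 22-InDel panel planted
    clade-perfect on its printed subclades, plus decoys in every violating
    category and exact copies of the nine known tree-defining InDels."""
    known = known_indel_markers()
    config = SimConfig(
        seed=seed,
        tree=om175_tree(with_markers=False),
        samples_per_node=samples_per_node,
        clade_perfect=0,
        incomplete=6, leaky=5, homoplasic=4,
        duplicate_known=len(known), outside_focal=3, snp_decoys=5,
        known=known,
    )
    sim = _Simulator(config)
    sim.plant_branch_snps()
    sim.plant_explicit(
        (e.rsid, e.position, *parse_mutation(e.mutation), e.clade)
        for e in PANEL_TABLE
    )
    sim.plant_incomplete(config.incomplete)
    sim.plant_leaky(config.leaky)
    sim.plant_homoplasic(config.homoplasic)
    sim.plant_duplicate_known(config.duplicate_known)
    sim.plant_outside_focal(config.outside_focal)
    sim.plant_snp_decoys(config.snp_decoys)
    return sim._finish()


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
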