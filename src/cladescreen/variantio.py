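"""Multi-sample VCF intake and the haploid genotype matrix.

Only the GT subfield is consulted. Cells are tri-state: 0 (reference
allele), 1 (alternate allele) or :data:`MISSING`. Heterozygous diploid
encodings are collapsed to MISSING because a hemizygous chrY locus cannot
be heterozygous — such calls indicate mapping artifacts, not genotypes.

Input is assumed left-normalized; indels whose REF/ALT share no leading
anchor base are retained but flagged in the build stats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import ContractError, ParseError, ValidationError

logger = logging.getLogger(__name__)

MISSING = -1

_ACGT = frozenset("ACGT")

VARIANT_CLASSES = ("snp", "biallelic_indel", "multiallelic", "mnp", "symbolic_or_other")

VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    id: str | None
    ref: str
    alts: list[str]
    calls: list[str]

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alts[0])


def classify_variant(ref: str, alts: Sequence[str]) -> str:
    """Partition a site into one of :data:`VARIANT_CLASSES`.

    ``biallelic_indel`` requires exactly one ALT, both alleles plain ACGT
    strings, and a length change; everything with more than one ALT is
    ``multiallelic`` regardless of allele content.
    """
    if not ref or not alts or any(not a for a in alts):
        raise ContractError("empty allele string")
    if len(alts) > 1:
        return "multiallelic"
    alt = alts[0]
    if not (_ACGT.issuperset(ref) and _ACGT.issuperset(alt)):
        return "symbolic_or_other"
    if len(ref) == len(alt):
        return "snp" if len(ref) == 1 else "mnp"
    return "biallelic_indel"


def collapse_genotype(gt: str) -> int:
    """Collapse a raw GT string over a bi-allelic record to {0, 1, MISSING}.

    Haploid "0"/"1" and homozygous "0/0", "1|1" map to the allele index;
    any '.' allele and any heterozygous combination map to MISSING.
    """
    gt = gt.strip()
    alleles = gt.replace("|", "/").split("/")
    parsed: list[int] = []
    for allele in alleles:
        if allele == ".":
            return MISSING
        try:
            idx = int(allele)
        except ValueError:
            raise ContractError(f"unparseable GT field {gt!r}") from None
        if idx not in (0, 1):
            raise ContractError(f"allele index {idx} on a bi-allelic record (GT {gt!r})")
        parsed.append(idx)
    if len(set(parsed)) != 1:
        return MISSING  # heterozygous: impossible on hemizygous chrY
    return parsed[0]


@dataclass
class BuildStats:
    seen: int = 0
    retained: int = 0
    masked: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)
    unanchored: list[VariantKey] = field(default_factory=list)


@dataclass
class GenotypeMatrix:
    """Retained variants x samples, values in {0, 1, MISSING}."""

    variants: list[VariantKey]
    ids: list[str | None]
    samples: list[str]
    calls: np.ndarray
    stats: BuildStats = field(default_factory=BuildStats)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValidationError("matrix shape does not match variant/sample lists")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    def to_tsv(self) -> str:
        header = "variant_key\tid\t" + "\t".join(self.samples)
        lines = [header]
        for i, key in enumerate(self.variants):
            cells = ["." if c == MISSING else str(int(c)) for c in self.calls[i]]
            keystr = f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"
            lines.append(f"{keystr}\t{self.ids[i] or '.'}\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def read_vcf(path: str) -> tuple[list[str], list[VariantRecord]]:
    """Read a (plain or bgzipped) VCF into raw records with GT strings."""
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    records: list[VariantRecord] = []
    for rec in vf:
        alts = list(rec.alts) if rec.alts else ["."]
        calls = []
        for sample in samples:
            gt = rec.samples[sample].get("GT")
            if gt is None or all(a is None for a in gt):
                calls.append(".")
                continue
            sep = "|" if rec.samples[sample].phased else "/"
            calls.append(sep.join("." if a is None else str(a) for a in gt))
        records.append(
            VariantRecord(chrom=rec.chrom, pos=rec.pos, id=rec.id,
                          ref=rec.ref, alts=alts, calls=calls)
        )
    vf.close()
    return samples, records


def load_bed(text: str) -> list[tuple[int, int]]:
    """Parse BED intervals (0-based half-open); contig column is ignored."""
    intervals = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"BED line {lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"BED line {lineno}: bad coordinates") from None
        intervals.append((start, end))
    return intervals


def build_matrix(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    keep_class: str | set[str] = "biallelic_indel",
    region_mask: list[tuple[int, int]] | None = None,
) -> GenotypeMatrix:
    """Filter a record stream down to `keep_class` sites and code the genotypes.

    Order-preserving and deterministic. With a mask supplied the input must
    be position-sorted (checked); masking drops records whose POS falls in
    any 0-based half-open interval.
    """
    keep = {keep_class} if isinstance(keep_class, str) else set(keep_class)
    unknown = keep - set(VARIANT_CLASSES)
    if unknown:
        raise ContractError(f"unknown variant classes {sorted(unknown)}")
    stats = BuildStats(class_counts={c: 0 for c in VARIANT_CLASSES})
    variants: list[VariantKey] = []
    ids: list[str | None] = []
    rows: list[np.ndarray] = []
    samples = list(samples)
    contig: str | None = None
    last_pos = 0
    for rec in records:
        stats.seen += 1
        if contig is None:
            contig = rec.chrom
        elif rec.chrom != contig:
            raise ValidationError(f"records span contigs {contig} and {rec.chrom}")
        if len(rec.calls) != len(samples):
            raise ValidationError(
                f"record {rec.chrom}:{rec.pos} has {len(rec.calls)} sample "
                f"columns, expected {len(samples)}"
            )
        if region_mask is not None:
            if rec.pos < last_pos:
                raise ValidationError("input must be position-sorted when masking")
            last_pos = rec.pos
        cls = classify_variant(rec.ref, rec.alts)
        stats.class_counts[cls] += 1
        if cls not in keep:
            continue
        if region_mask is not None and any(s < rec.pos <= e for s, e in region_mask):
            stats.masked += 1
            continue
        alt = rec.alts[0]
        if len(rec.ref) != len(alt) and rec.ref[0] != alt[0]:
            stats.unanchored.append(rec.key)
        row = np.fromiter((collapse_genotype(g) for g in rec.calls), dtype=np.int8,
                          count=len(samples))
        variants.append(rec.key)
        ids.append(rec.id)
        rows.append(row)
    stats.retained = len(variants)
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    logger.info(
        "build_matrix: %d seen, %d retained, %d masked (%s)",
        stats.seen, stats.retained, stats.masked, stats.class_counts,
    )
    if stats.unanchored:
        logger.warning("%d retained indels lack a shared anchor base", len(stats.unanchored))
    return GenotypeMatrix(variants=variants, ids=ids, samples=samples,
                          calls=calls, stats=stats)
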