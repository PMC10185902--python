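# cladescreen

Discover clade-exact (phylogenetically informative) InDels on the male-specific
Y chromosome. Given a multi-sample chrY VCF, a labeled haplogroup tree (Newick
with internal node labels) and a marker index, the pipeline:

1. collapses genotypes to a haploid 0/1/missing matrix (het calls on the
   hemizygous chromosome are treated as no-calls),
2. assigns every sample to a haplogroup by greedy descent on derived-state
   defining markers,
3. computes per-clade derived-allele frequencies by direct counting,
4. restricts to bi-allelic InDels whose variation is confined to a focal clade
   (default `O`), supporting both REF- and ALT-derived orientations,
5. accepts a variant when its derived carriers coincide exactly with one
   clade's membership (derived in **all** clade members, in **no one** else),
   proposing the clade as the carriers' lowest common ancestor,
6. deduplicates candidates against markers that already define tree nodes.

A seeded simulator plants variants in controlled categories (clade-perfect,
incomplete, leaky, homoplasic, duplicates of known markers, outside-focal,
SNP decoys) with configurable missing/heterozygous-call noise and emits VCF
plus truth tables, so every stage is testable without external data. A
packaged O-M175 fixture replays a 22-InDel reference panel end to end.

## CLI

```sh
cladescreen simulate --seed 7 --out-dir sim --clade-perfect 5 --leaky 3
cladescreen assign  --vcf sim/cohort.vcf --tree sim/tree.nwk --markers sim/markers.tsv --out-dir out
cladescreen screen  --vcf sim/cohort.vcf --tree sim/tree.nwk --markers sim/markers.tsv \
                    --known sim/known.tsv --focal O --out-dir out
cladescreen replay-table1 --out-dir replay
cladescreen validate --vcf sim/cohort.vcf --tree sim/tree.nwk --markers sim/markers.tsv \
                     --candidates out/candidates.tsv --calls out/calls.tsv --out-dir out
```

`screen` writes `calls.tsv`, `candidates.tsv`, `frequencies.tsv` and
`summary.json` (stage counters: records seen → bi-allelic InDels →
focal-restricted → clade-exact → novel). Logging goes to stderr; results only
to files. Exit codes: 0 ok, 2 usage, 3 parse, 4 validation, 5 configuration,
6 contract violation.

Screen options may also come from a flat YAML config (`--config`), with CLI
flags taking precedence: keys `focal_clade`, `min_call_fraction`,
`strict_missing`.

## File formats

* VCF v4.2 (plain or bgzipped), GT subfield only; haploid or diploid-encoded.
* Newick topology with labeled internal nodes; branch lengths ignored.
* Marker index TSV: `name  haplogroup  position  ancestral  derived`
  (anchored ACGT alleles, 1-based positions).
* Optional BED (0-based half-open) region mask for the screen.
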