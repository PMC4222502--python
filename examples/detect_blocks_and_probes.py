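"""Detect conserved synteny blocks and pick FISH probe targets.

Builds a small two-species ortholog table from a pair of marker-level
genomes that differ by one inversion, detects maximal constant-chromosome
gene runs, and applies the probe-end rule: both ends of blocks larger than
3 Mb, one mid-block gene otherwise.
"""

import karyorec as kr

# two genomes over 4 conserved markers; B carries one inversion
genome_a = kr.SignedGenome("speciesA", (("m1", "m2", "m3", "m4"),))
genome_b = kr.SignedGenome("speciesB", (("m1", "-m3", "-m2", "m4"),))

table = kr.make_ortholog_table(genome_a, genome_b, genes_per_marker=4, marker_length_mb=5.0)
print(f"ortholog table: {len(table)} genes over {len(genome_a.markers)} markers")

blocks = kr.detect_blocks(table, min_span_kb=100)
print(f"\nconserved blocks along {table.species_a}:")
for b in blocks:
    print(f"  {b.id}: {b.chrom_a}:{b.start_a}-{b.end_a} -> {b.chrom_b}, "
          f"{b.span_mb:.2f} Mb, {len(b.genes)} genes, order conserved: {b.order_conserved}")

summary = kr.summarize_blocks(blocks)
print("\nper-chromosome summary (spans in species-A Mb):")
print(summary.to_string(index=False))

targets = kr.select_probe_targets(blocks, large_threshold_mb=3.0, table=table)
print("\nprobe targets (>3 Mb blocks get both ends, smaller ones a mid gene):")
for t in targets:
    print(f"  {t.block_id}: {t.gene_id} ({t.role})")
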